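"""REP statistic, sweep selection and missing-RA filling."""

import numpy as np
import pandas as pd
import pytest

from myoscreen import (
    ConfigError,
    absolute_error_rate,
    apply_missingness,
    build_imputation_frame,
    fill_missing,
    fitting_goodness,
    rep_score,
    select_imputation_model,
    select_p_from_sweep,
)
from myoscreen.imputation import SplitPlan
from myoscreen.reference_tables import imputation_sweep_table


class TestFittingGoodness:
    def test_identity_prediction_scores_one(self, rng):
        x = rng.standard_normal(20)
        assert fitting_goodness(x, x) == pytest.approx(1.0)

    def test_mean_prediction_scores_zero(self, rng):
        x = rng.standard_normal(20)
        assert fitting_goodness(x, np.full(20, x.mean())) == pytest.approx(0.0)

    def test_three_point_hand_example(self):
        """Spread ratio about the data mean: ((1-2)^2+(3-2)^2+(5-2)^2) / 2."""
        assert fitting_goodness([1, 2, 3], [1, 3, 5]) == pytest.approx(5.5)

    def test_constant_actual_rejected(self):
        with pytest.raises(ConfigError, match="constant"):
            fitting_goodness([2, 2, 2], [1, 2, 3])

    def test_overdispersed_predictions_can_exceed_one_and_warn(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="myoscreen.imputation"):
            r2 = fitting_goodness([0, 1], [-1, 2])
        assert r2 > 1.0
        assert "exceeds 1" in caplog.text


class TestErrorRate:
    def test_perfect_prediction_rate_zero(self, rng):
        x = rng.standard_normal(10)
        assert absolute_error_rate(x, x, 0.5) == 0.0

    def test_all_errors_at_or_beyond_tolerance_rate_one(self):
        assert absolute_error_rate([0, 0, 0], [1, 2, 0.5], 0.5) == 1.0

    def test_strict_bound_counts_only_errors_below_tolerance(self):
        actual = np.zeros(3)
        predicted = np.array([0.1, 0.5, 0.9])
        assert absolute_error_rate(actual, predicted, 0.5) == pytest.approx(2 / 3)

    def test_empty_input_rejected(self):
        with pytest.raises(ConfigError, match="empty"):
            absolute_error_rate([], [], 0.5)


class TestRepScore:
    def test_published_row_ratio(self):
        assert rep_score(0.789, 0.145).rep == pytest.approx(5.441, abs=5e-4)

    def test_zero_goodness_scores_zero(self):
        assert rep_score(0.0, 0.3).rep == 0.0

    def test_unit_error_rate_is_identity(self):
        assert rep_score(0.7, 1.0).rep == pytest.approx(0.7)

    def test_zero_error_rate_is_infinitely_good(self):
        assert rep_score(0.5, 0.0).rep == np.inf

    def test_negative_inputs_rejected(self):
        with pytest.raises(ConfigError):
            rep_score(-0.1, 0.5)


class TestSweepSelection:
    def test_published_sweep_selects_08(self):
        assert select_p_from_sweep(imputation_sweep_table()) == 0.8

    def test_single_row_grid_is_chosen(self):
        sweep = pd.DataFrame({"p": [0.5], "R2": [0.9], "r": [0.2]})
        assert select_p_from_sweep(sweep) == 0.5

    def test_tie_breaks_towards_larger_train_share(self):
        sweep = pd.DataFrame({"p": [0.2, 0.8], "R2": [0.8, 0.8], "r": [0.2, 0.2]})
        assert select_p_from_sweep(sweep) == 0.8

    def test_split_plan_is_disjoint_and_sized(self):
        ids = np.arange(100)
        plan = SplitPlan.make(ids, 0.8, seed=3)
        assert len(plan.train_ids) == 80
        assert set(plan.train_ids).isdisjoint(plan.test_ids)
        assert len(plan.train_ids) + len(plan.test_ids) == 100


@pytest.fixture(scope="module")
def selected(small_incomplete_cohort_module):
    table = small_incomplete_cohort_module
    return table, select_imputation_model(
        table, rounds=40, p_grid=(0.3, 0.6, 0.9), seed=21
    )


@pytest.fixture(scope="module")
def small_incomplete_cohort_module():
    from myoscreen import CohortConfig, generate_cohort, strong_effect_sizes

    cfg = CohortConfig(n_students=400, seed=11, effect_sizes=strong_effect_sizes())
    return apply_missingness(generate_cohort(cfg), cfg)


class TestSelectAndFill:
    def test_sweep_table_is_self_consistent(self, selected):
        _, sel = selected
        recomputed = sel.sweep["R2"] / sel.sweep["r"]
        assert np.allclose(sel.sweep["REP"], recomputed, atol=1e-12)

    def test_chosen_p_is_argmax_of_emitted_sweep(self, selected):
        _, sel = selected
        assert sel.proportion == select_p_from_sweep(sel.sweep)

    def test_fill_replaces_every_missing_ra_cell(self, selected):
        table, sel = selected
        filled = fill_missing(table, sel)
        assert not np.isnan(filled.value("RA")).any()
        # observed cells untouched
        obs = ~np.isnan(table.value("RA"))
        assert np.array_equal(filled.value("RA")[obs], table.value("RA")[obs])
        # audit flags match exactly the previously missing cells
        assert np.array_equal(filled.imputed["RA"], ~obs)
        assert filled.fill_report["filled"] == int((~obs).sum())

    def test_fill_on_complete_table_is_identity(self, small_cohort):
        table, _ = small_cohort
        sel = select_imputation_model(
            table, rounds=10, p_grid=(0.8,), seed=5
        )
        filled = fill_missing(table, sel)
        assert filled.equals(table)
        assert filled.fill_report == {"filled": 0, "skipped": 0}

    def test_duplicate_student_gets_the_model_prediction(self, selected):
        from myoscreen import gbrt_predict

        table, sel = selected
        t = table.copy()
        i = 0
        g = len(t.grades) - 1
        t.values["RA"][i, g] = np.nan
        filled = fill_missing(t, sel)
        _, _, X_mis, cells = build_imputation_frame(t, sel.predictors)
        idx = cells.index((i, g))
        expected = gbrt_predict(sel.model, X_mis.iloc[[idx]])[0]
        assert filled.value("RA")[i, g] == pytest.approx(expected)

    def test_grid_too_large_for_data_raises(self, small_incomplete_cohort_module):
        tiny = small_incomplete_cohort_module.subset_students(np.arange(3))
        with pytest.raises(ConfigError, match="skipped"):
            with pytest.warns(UserWarning):
                select_imputation_model(tiny, rounds=2, p_grid=(0.5,), min_split_size=1000)
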