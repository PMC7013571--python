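"""Screening statistics against brute-force oracles and the published
worked example."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from myoscreen import (
    ConfigError,
    FeatureSubset,
    MultivariateResult,
    UnivariateResult,
    multivariate_fit,
    select_final,
    select_preliminary,
    univariate_screen,
)
from myoscreen.reference_tables import (
    PUBLISHED_FINAL_SUBSET,
    multivariate_screen_table,
    univariate_screen_table,
)


def _uni(df, y, factors=None):
    return univariate_screen(pd.DataFrame(df), np.asarray(y, float), factors)


class TestUnivariate:
    def test_perfect_correlation(self):
        y = np.arange(10.0)
        res = _uni({"x": y}, y)[0]
        assert res.correlation == pytest.approx(1.0)
        assert res.p_value < 1e-30

    def test_zero_variance_factor_reports_null_result(self):
        y = np.arange(10.0)
        res = _uni({"x": np.ones(10)}, y)[0]
        assert res.correlation == 0.0 and res.p_value == 1.0

    def test_small_n_and_constant_target_raise(self):
        with pytest.raises(ConfigError, match="n >= 3"):
            _uni({"x": [1, 2]}, [1, 2])
        with pytest.raises(ConfigError, match="constant"):
            _uni({"x": [1, 2, 3]}, [5, 5, 5])

    def test_p_value_matches_exact_permutation_test(self):
        """n=5 toy data: the t-based p must agree with the exact
        permutation distribution of |r| over all 120 orderings."""
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([1.0, 2.0, 3.0, 4.0, 6.0])
        r_obs = abs(np.corrcoef(x, y)[0, 1])
        count = 0
        total = 0
        for perm in itertools.permutations(y):
            r = abs(np.corrcoef(x, perm)[0, 1])
            count += r >= r_obs - 1e-12
            total += 1
        p_exact = count / total
        res = _uni({"x": x}, y)[0]
        assert res.p_value == pytest.approx(p_exact, abs=0.02)

    def test_null_rejection_rate_is_calibrated(self, rng):
        """Independent factor vs binary target: rejection rate at alpha=0.05
        stays inside the binomial 99% CI over 200 replicates."""
        n, reps, alpha = 3000, 200, 0.05
        y = (rng.random(n) < 0.4).astype(float)
        hits = 0
        for _ in range(reps):
            x = rng.standard_normal(n)
            hits += _uni({"x": x}, y)[0].p_value < alpha
        se = np.sqrt(alpha * (1 - alpha) / reps)
        assert abs(hits / reps - alpha) < 2.576 * se + 1e-12


class TestSelectPreliminary:
    def test_published_univariate_table_all_pass_at_05(self):
        rows = univariate_screen_table()
        results = [UnivariateResult(r.factor, r.correlation, r.p_value)
                   for r in rows.itertuples()]
        subset = select_preliminary(results, alpha=0.05)
        assert len(subset) == 25

    def test_alpha_zero_selects_nothing(self):
        results = [UnivariateResult("x", 0.5, 1e-10)]
        with pytest.warns(UserWarning):
            subset = select_preliminary(results, alpha=0.0)
        assert len(subset) == 0

    def test_strict_inequality_at_boundary(self):
        results = [UnivariateResult(f, 0.1, p)
                   for f, p in [("a", 0.049), ("b", 0.05), ("c", 0.051)]]
        subset = select_preliminary(results, alpha=0.05)
        assert subset.factors == ["a"]

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20),
           st.floats(0.01, 0.99), st.floats(0.01, 0.99))
    def test_enlarging_alpha_never_shrinks_selection(self, ps, a1, a2):
        lo, hi = sorted([a1, a2])
        results = [UnivariateResult(f"f{i}", 0.0, p) for i, p in enumerate(ps)]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            small = select_preliminary(results, lo).factors
            big = select_preliminary(results, hi).factors
        assert set(small) <= set(big)


class TestMultivariate:
    def test_single_factor_p_equals_univariate_p(self, rng):
        x = rng.standard_normal(50)
        y = 0.5 * x + rng.standard_normal(50)
        subset = FeatureSubset(["x"], {"x": "univariate"})
        multi = multivariate_fit({"x": x}, subset, y)[0]
        uni = _uni({"x": x}, y)[0]
        assert multi.p_value == pytest.approx(uni.p_value, abs=1e-9)

    def test_exact_linear_recovery(self, rng):
        x1 = rng.standard_normal(40)
        x2 = rng.standard_normal(40)
        y = 2 * x1 - 3 * x2
        subset = FeatureSubset(["x1", "x2"], {})
        res = {m.factor: m for m in multivariate_fit({"x1": x1, "x2": x2}, subset, y)}
        assert res["x1"].coefficient == pytest.approx(2.0, abs=1e-9)
        assert res["x2"].coefficient == pytest.approx(-3.0, abs=1e-9)
        assert res["x1"].p_value < 1e-12

    def test_coefficients_match_normal_equations_oracle(self, rng):
        X = rng.standard_normal((10, 3))
        y = rng.standard_normal(10)
        design = np.column_stack([np.ones(10), X])
        beta = np.linalg.inv(design.T @ design) @ design.T @ y
        subset = FeatureSubset(["a", "b", "c"], {})
        res = multivariate_fit(
            {"a": X[:, 0], "b": X[:, 1], "c": X[:, 2]}, subset, y
        )
        for j, m in enumerate(res):
            assert m.coefficient == pytest.approx(beta[j + 1], abs=1e-9)
            assert m.t_stat == pytest.approx(m.coefficient / m.std_err, rel=1e-9)

    def test_collinear_column_dropped_with_warning(self, rng, caplog):
        x = rng.standard_normal(30)
        y = x + rng.standard_normal(30)
        subset = FeatureSubset(["x", "x2"], {})
        import logging
        with caplog.at_level(logging.WARNING, logger="myoscreen.screening"):
            res = multivariate_fit({"x": x, "x2": 2 * x}, subset, y)
        assert [m.factor for m in res] == ["x"]
        assert "collinear" in caplog.text


class TestSelectFinal:
    def test_published_table_reproduces_the_15_factor_subset(self):
        rows = multivariate_screen_table()
        results = [
            MultivariateResult(r.factor, r.coefficient, r.std_err, r.t_stat, r.p_value)
            for r in rows.itertuples()
        ]
        subset = select_final(results, alpha=0.05, forced=["RA"])
        assert set(subset.factors) == set(PUBLISHED_FINAL_SUBSET)
        assert len(subset) == 15
        assert subset.provenance["RA"] == "forced"

    def test_forced_only_when_no_survivors(self):
        subset = select_final([], alpha=0.05, forced=["RA"])
        assert subset.factors == ["RA"]
        assert subset.provenance["RA"] == "forced"

    def test_forced_factor_already_significant_appears_once(self):
        results = [MultivariateResult("RA", 1.0, 0.1, 10.0, 1e-8)]
        subset = select_final(results, alpha=0.05, forced=["RA"])
        assert subset.factors == ["RA"]
        assert subset.provenance["RA"] == "multivariate"
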