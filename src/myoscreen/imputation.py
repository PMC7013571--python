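"""Missing-diopter imputation via GBRT with REP-based model selection.

The observed RA cells of the incomplete cohort form the complete subset D;
the missing ones the target subset M. D is split train/test at a proportion
p, a boosted-tree regressor is fitted on the training part, and the test
part is scored with the REP statistic

    REP = R^2 / r,

where the fitting goodness R^2 is the ratio of prediction spread to data
spread about the data mean,

    R^2 = sum_i (f(x_i) - xbar)^2 / sum_i (x_i - xbar)^2,   xbar = mean(x),

(a non-standard definition, kept exactly as published — it can exceed 1 for
over-dispersed predictions, which is logged) and the absolute error rate r
is the fraction of predictions missing the truth by at least the tolerance
y (strict |error| < y counts as a hit). The proportion p maximizing REP
wins, ties going to the larger training share, and its model fills M.

Predictors for each RA cell: the grade, the student's grade-1 RA (always
observed), the nearest earlier observed RA with its grade gap, and the
student's observed-mean value of each predictor factor.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import ConfigError, MissingDataError
from .gbrt import GbrtModel, gbrt_fit, gbrt_predict
from .synthetic_cohort import CohortTable

logger = logging.getLogger(__name__)

__all__ = [
    "RepScore",
    "SplitPlan",
    "ImputationSelection",
    "fitting_goodness",
    "absolute_error_rate",
    "rep_score",
    "select_p_from_sweep",
    "build_imputation_frame",
    "select_imputation_model",
    "fill_missing",
    "DEFAULT_P_GRID",
    "DEFAULT_TOLERANCE_D",
]

#: Train-share sweep, matching the published nine-row validation table.
DEFAULT_P_GRID = tuple(round(0.1 * k, 1) for k in range(1, 10))

#: Half a diopter: the clinically meaningful error tolerance for refraction.
DEFAULT_TOLERANCE_D = 0.5

_BASE_FEATURES = ["grade", "ra_g1", "ra_prev", "gap_prev"]


@dataclass(frozen=True)
class RepScore:
    """Bundle of fitting goodness, error rate, tolerance and their ratio."""

    r_squared: float
    error_rate: float
    tolerance: float | None
    rep: float


@dataclass(frozen=True)
class SplitPlan:
    """Seeded train/test partition of sample ids at proportion p."""

    proportion: float
    seed: int
    train_ids: np.ndarray
    test_ids: np.ndarray

    @classmethod
    def make(cls, ids: np.ndarray, proportion: float, seed: int) -> "SplitPlan":
        if not (0.0 < proportion < 1.0):
            raise ConfigError(f"split proportion must lie in (0, 1), got {proportion}")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(ids))
        n_train = int(round(proportion * len(ids)))
        n_train = min(max(n_train, 1), len(ids) - 1)
        return cls(proportion, seed, ids[perm[:n_train]], ids[perm[n_train:]])


def fitting_goodness(actual, predicted) -> float:
    """Spread-ratio fitting goodness about the data mean (see module doc).

    Equals 1 when predictions reproduce the data exactly and 0 when they
    collapse to the data mean; values above 1 (over-dispersed predictions)
    are possible and logged.
    """
    x = np.asarray(actual, dtype=float)
    f = np.asarray(predicted, dtype=float)
    if len(x) != len(f):
        raise ConfigError("actual and predicted must have equal length")
    if len(x) < 2:
        raise ConfigError("fitting goodness needs n >= 2")
    xbar = x.mean()
    denom = ((x - xbar) ** 2).sum()
    if denom == 0:
        raise ConfigError("actual values are constant; fitting goodness undefined")
    r2 = float(((f - xbar) ** 2).sum() / denom)
    if r2 > 1.0:
        logger.warning("fitting goodness %.4f exceeds 1 (over-dispersed predictions)", r2)
    return r2


def absolute_error_rate(actual, predicted, tolerance: float) -> float:
    """Fraction of predictions whose absolute error is NOT below ``tolerance``.

    r = 1 - n/m with m the sample count and n the number of samples whose
    |actual - predicted| < tolerance (strict).
    """
    if tolerance <= 0:
        raise ConfigError("tolerance must be > 0")
    x = np.asarray(actual, dtype=float)
    f = np.asarray(predicted, dtype=float)
    if len(x) == 0:
        raise ConfigError("absolute error rate undefined on empty vectors")
    if len(x) != len(f):
        raise ConfigError("actual and predicted must have equal length")
    hits = int((np.abs(x - f) < tolerance).sum())
    return 1.0 - hits / len(x)


def rep_score(r_squared: float, error_rate: float, tolerance: float | None = None) -> RepScore:
    """REP = R^2 / r; a zero error rate is unbeatable and scores +inf."""
    if r_squared < 0 or error_rate < 0:
        raise ConfigError("rep_score inputs must be nonnegative")
    if error_rate > 1:
        raise ConfigError("error_rate must lie in [0, 1]")
    rep = float("inf") if error_rate == 0 else r_squared / error_rate
    return RepScore(float(r_squared), float(error_rate), tolerance, float(rep))


def select_p_from_sweep(sweep: pd.DataFrame) -> float:
    """Argmax-REP train proportion from a sweep table with columns p, R2, r.

    Recomputes REP row-wise from R2 and r; ties (and ties at +inf) break
    towards the larger training share.
    """
    if len(sweep) == 0:
        raise ConfigError("empty sweep table")
    reps = [
        rep_score(row.R2, row.r).rep for row in sweep.itertuples()
    ]
    order = sorted(
        range(len(sweep)),
        key=lambda i: (reps[i], sweep["p"].iloc[i]),
    )
    return float(sweep["p"].iloc[order[-1]])


# ---------------------------------------------------------------------------
# cohort-level machinery
# ---------------------------------------------------------------------------

def _student_factor_means(table: CohortTable, factors: list[str]) -> np.ndarray:
    cols = []
    for name in factors:
        v = table.value(name)
        with np.errstate(invalid="ignore"):
            m = np.nanmean(v, axis=1)
        cols.append(m)
    return np.column_stack(cols) if cols else np.empty((table.n_students, 0))


def default_predictor_factors(table: CohortTable) -> list[str]:
    return [n for n in table.factor_names if n != "RA"]


def build_imputation_frame(
    table: CohortTable, predictors: list[str] | None = None
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame, list[tuple[int, int]]]:
    """Row-per-RA-cell design for grades above the first.

    Returns ``(X_obs, y_obs, X_mis, mis_cells)`` where the observed rows
    (RA present) train and validate the regressor and the missing rows are
    the fill targets; ``mis_cells`` lists their (student_index, grade_index)
    coordinates. Rows whose factor features are all-missing come back with
    NaNs and are the caller's responsibility.
    """
    predictors = predictors if predictors is not None else default_predictor_factors(table)
    ra = table.value("RA")
    n, g = ra.shape
    if np.isnan(ra[:, 0]).any():
        raise MissingDataError("grade-1 RA must be fully observed")
    fmeans = _student_factor_means(table, predictors)
    names = _BASE_FEATURES + [f"mean_{p}" for p in predictors]

    rows, targets, cells, observed = [], [], [], []
    grades = table.grades
    for j in range(1, g):
        col = ra[:, j]
        # nearest earlier observed RA per student, scanning left from j
        prev_val = np.full(n, np.nan)
        prev_gap = np.full(n, np.nan)
        need = np.ones(n, dtype=bool)
        for k in range(j - 1, -1, -1):
            hit = need & ~np.isnan(ra[:, k])
            prev_val[hit] = ra[hit, k]
            prev_gap[hit] = grades[j] - grades[k]
            need &= ~hit
        base = np.column_stack(
            [np.full(n, grades[j]), ra[:, 0], prev_val, prev_gap]
        )
        X = np.hstack([base, fmeans])
        rows.append(X)
        targets.append(col)
        cells.extend((i, j) for i in range(n))
        observed.append(~np.isnan(col))

    X_all = np.vstack(rows)
    y_all = np.concatenate(targets)
    obs = np.concatenate(observed)
    cells = np.array(cells)
    X_frame = pd.DataFrame(X_all, columns=names)
    X_obs = X_frame[obs].reset_index(drop=True)
    X_mis = X_frame[~obs].reset_index(drop=True)
    mis_cells = [tuple(c) for c in cells[~obs]]
    return X_obs, y_all[obs], X_mis, mis_cells


@dataclass
class ImputationSelection:
    """Outcome of the train-share sweep: winning model and the sweep table."""

    model: GbrtModel
    proportion: float
    sweep: pd.DataFrame
    tolerance: float
    predictors: list[str] = field(default_factory=list)


def select_imputation_model(
    table_or_frame,
    target=None,
    p_grid=DEFAULT_P_GRID,
    tolerance: float = DEFAULT_TOLERANCE_D,
    rounds: int = 100,
    shrinkage: float = 0.1,
    max_depth: int = 3,
    min_leaf: int = 5,
    seed: int = 0,
    predictors: list[str] | None = None,
    min_split_size: int = 10,
) -> ImputationSelection:
    """Sweep train proportions, score each candidate with REP on its test
    split, and return the REP-maximizing model.

    Accepts either an incomplete ``CohortTable`` (the observed-RA design is
    built internally) or an explicit complete ``(features, target)`` pair.
    Proportions whose train or test part would undercut the minimum sizes
    are skipped with a warning; if every proportion is skipped this is an
    error.
    """
    if isinstance(table_or_frame, CohortTable):
        predictors = predictors if predictors is not None else default_predictor_factors(table_or_frame)
        X_obs, y_obs, _, _ = build_imputation_frame(table_or_frame, predictors)
    else:
        X_obs = pd.DataFrame(table_or_frame)
        y_obs = np.asarray(target, dtype=float)
        predictors = predictors or []
    ok = ~(X_obs.isna().any(axis=1).to_numpy() | np.isnan(y_obs))
    X_obs, y_obs = X_obs[ok].reset_index(drop=True), y_obs[ok]

    ids = np.arange(len(y_obs))
    records = []
    candidates: dict[float, GbrtModel] = {}
    for p in p_grid:
        plan = SplitPlan.make(ids, p, seed)
        if len(plan.train_ids) < max(2 * min_leaf, min_split_size) or len(plan.test_ids) < min_split_size:
            warnings.warn(f"skipping p={p}: split below minimum size", stacklevel=2)
            continue
        model = gbrt_fit(
            X_obs.iloc[plan.train_ids], y_obs[plan.train_ids],
            rounds=rounds, shrinkage=shrinkage, max_depth=max_depth, min_leaf=min_leaf,
        )
        pred = gbrt_predict(model, X_obs.iloc[plan.test_ids])
        truth = y_obs[plan.test_ids]
        r2 = fitting_goodness(truth, pred)
        r = absolute_error_rate(truth, pred, tolerance)
        score = rep_score(r2, r, tolerance)
        records.append({"p": p, "R2": r2, "r": r, "REP": score.rep})
        candidates[p] = model
    if not records:
        raise ConfigError("every proportion in p_grid was skipped; data too small")
    sweep = pd.DataFrame(records)
    chosen = select_p_from_sweep(sweep)
    model = candidates[chosen]
    model.feature_names = list(X_obs.columns)
    return ImputationSelection(model, chosen, sweep, tolerance, list(predictors))


def fill_missing(table: CohortTable, model: GbrtModel | ImputationSelection) -> CohortTable:
    """Fill every missing RA cell with the regressor's prediction.

    Observed cells are untouched; filled cells are flagged in the table's
    ``imputed`` mask (and the ``imputed`` audit column of the long CSV).
    Cells whose predictor row is incomplete (a factor never observed for
    that student) stay missing, are logged, and are counted in the
    attached ``fill_report``.
    """
    if isinstance(model, ImputationSelection):
        predictors = model.predictors
        model = model.model
    else:
        predictors = None
        if model.feature_names:
            predictors = [c[5:] for c in model.feature_names if c.startswith("mean_")]
    out = table.copy()
    _, _, X_mis, mis_cells = build_imputation_frame(out, predictors)
    out.imputed["RA"] = np.zeros_like(out.value("RA"), dtype=bool)
    if len(X_mis) == 0:
        out.fill_report = {"filled": 0, "skipped": 0}
        return out
    usable = ~X_mis.isna().any(axis=1).to_numpy()
    preds = gbrt_predict(model, X_mis[usable])
    ra = out.values["RA"]
    k = 0
    filled = 0
    for row, (i, j) in zip(usable, mis_cells):
        if not row:
            continue
        ra[i, j] = preds[k]
        out.imputed["RA"][i, j] = True
        k += 1
        filled += 1
    skipped = int((~usable).sum())
    if skipped:
        logger.warning("fill_missing: %d cells left missing (incomplete predictors)", skipped)
    out.fill_report = {"filled": filled, "skipped": skipped}
    return out
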