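"""Data curation: cleaning, longitudinal reduction, normalization.

Each factor is collapsed to one value per student according to its kind:

* diopter (RA)            -> mean annual progression over grades 1-5,
* behavioural frequencies -> sum over grades 1-5,
* continuous measurements -> mean over grades 1-5,
* objective attributes    -> the raw static value.

The resulting per-student matrix is min-max normalized to [0, 1] with
statistics learned on training rows only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import ConfigError, MissingDataError
from .synthetic_cohort import CohortTable

logger = logging.getLogger(__name__)

__all__ = [
    "CleaningRules",
    "FeatureMatrix",
    "clean_records",
    "annual_progress_feature",
    "sum_feature",
    "mean_feature",
    "reduce_factor",
    "student_features",
    "build_feature_matrix",
]


@dataclass
class CleaningRules:
    """Admissible value ranges per factor and whole-student exclusions.

    ``ranges`` maps factor -> (lo, hi); out-of-range cells become missing.
    ``exclude_students`` drops every record of the listed students (e.g.
    congenital amblyopia or ocular defects flagged at intake).
    """

    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    exclude_students: frozenset[str] = frozenset()


def clean_records(table: CohortTable, rules: CleaningRules) -> CohortTable:
    """Apply range rules and student exclusions; counts are logged."""
    keep = ~np.isin(table.student_ids, list(rules.exclude_students))
    out = table.subset_students(keep)
    dropped = int((~keep).sum())
    censored = 0
    for name, (lo, hi) in rules.ranges.items():
        if name not in out.values:
            continue
        arr = out.values[name]
        bad = (~np.isnan(arr)) & ((arr < lo) | (arr > hi))
        censored += int(bad.sum())
        arr = arr.copy()
        arr[bad] = np.nan
        out.values[name] = arr
    logger.info(
        "clean_records: dropped %d students, censored %d out-of-range cells",
        dropped, censored,
    )
    return out


# ---------------------------------------------------------------------------
# per-student longitudinal reductions
# ---------------------------------------------------------------------------

def annual_progress_feature(series) -> float:
    """Mean annual change of an RA series over grades 1..5.

    Averages consecutive-grade differences RA(g+1) - RA(g) over the pairs
    where both grades are observed; with a complete series this telescopes
    to (RA5 - RA1) / 4. If no adjacent pair is observed but at least two
    grades are, falls back to the overall slope (last - first) / span.
    Negative values mean myopic progression.
    """
    x = np.asarray(series, dtype=float)
    obs = ~np.isnan(x)
    if obs.sum() < 2:
        raise MissingDataError(
            f"annual progress needs >= 2 observed grades, got {int(obs.sum())}"
        )
    pair = obs[:-1] & obs[1:]
    if pair.any():
        diffs = x[1:][pair] - x[:-1][pair]
        return float(diffs.mean())
    idx = np.nonzero(obs)[0]
    return float((x[idx[-1]] - x[idx[0]]) / (idx[-1] - idx[0]))


def sum_feature(series) -> float:
    """Sum of grade 1..5 values; missing entries are a contract violation."""
    x = np.asarray(series, dtype=float)
    miss = np.nonzero(np.isnan(x))[0]
    if len(miss):
        raise MissingDataError(
            f"sum_feature: missing values at grades {[int(g) for g in miss + 1]}"
        )
    return float(x.sum())


def mean_feature(series) -> float:
    """Mean of grade 1..5 values; missing entries are a contract violation."""
    x = np.asarray(series, dtype=float)
    miss = np.nonzero(np.isnan(x))[0]
    if len(miss):
        raise MissingDataError(
            f"mean_feature: missing values at grades {[int(g) for g in miss + 1]}"
        )
    return float(x.mean())


def reduce_factor(
    values: np.ndarray, rule: str, allow_missing: bool = False
) -> np.ndarray:
    """Vectorized reduction of an (n_students, n_grades) block to one value
    per student.

    ``values`` must already be restricted to the grades the rule should see
    (grades 1-5 for the prediction features). With ``allow_missing`` the
    sum rule rescales the observed mean (sum = observed_mean * n_grades) and
    students with too few observations come back NaN instead of raising.
    """
    v = np.asarray(values, dtype=float)
    n, g = v.shape
    obs = ~np.isnan(v)
    nobs = obs.sum(axis=1)
    with np.errstate(invalid="ignore"):
        if rule == "passthrough":
            out = v[:, 0].copy()
            if allow_missing:  # static factor: any observed grade will do
                for j in range(1, g):
                    fill = np.isnan(out)
                    out[fill] = v[fill, j]
        elif rule == "sum":
            if allow_missing:
                m = np.where(nobs > 0, np.nansum(v, axis=1) / np.maximum(nobs, 1), np.nan)
                out = m * g
            else:
                if not obs.all():
                    raise MissingDataError("sum reduction requires complete series")
                out = v.sum(axis=1)
        elif rule == "mean":
            if allow_missing:
                out = np.where(nobs > 0, np.nansum(v, axis=1) / np.maximum(nobs, 1), np.nan)
            else:
                if not obs.all():
                    raise MissingDataError("mean reduction requires complete series")
                out = v.mean(axis=1)
        elif rule == "annual_progress":
            pair = obs[:, :-1] & obs[:, 1:]
            diffs = v[:, 1:] - v[:, :-1]
            npairs = pair.sum(axis=1)
            summed = np.nansum(np.where(pair, diffs, 0.0), axis=1)
            out = np.where(npairs > 0, summed / np.maximum(npairs, 1), np.nan)
            # no adjacent pair but >= 2 observed: overall slope
            lone = (npairs == 0) & (nobs >= 2)
            if lone.any():
                idx = np.arange(g)
                for i in np.nonzero(lone)[0]:
                    w = np.nonzero(obs[i])[0]
                    out[i] = (v[i, w[-1]] - v[i, w[0]]) / (w[-1] - w[0])
            if not allow_missing and np.isnan(out).any():
                raise MissingDataError("annual progress requires >= 2 observed grades")
        else:
            raise ConfigError(f"unknown transform rule {rule!r}")
    return out


def student_features(
    table: CohortTable,
    factors: list[str] | None = None,
    feature_grades: tuple[int, int] = (1, 5),
    allow_missing: bool = False,
) -> pd.DataFrame:
    """One reduced value per student per factor (rows indexed by student_id).

    Only grades within ``feature_grades`` feed the reduction, so the
    top-grade outcome never leaks into the features.
    """
    factors = factors if factors is not None else table.factor_names
    lo, hi = feature_grades
    cols = np.nonzero((table.grades >= lo) & (table.grades <= hi))[0]
    data = {}
    for name in factors:
        d = table.descriptors[name]
        data[name] = reduce_factor(
            table.value(name)[:, cols], d.transform_rule, allow_missing=allow_missing
        )
    return pd.DataFrame(data, index=pd.Index(table.student_ids, name="student_id"))


# ---------------------------------------------------------------------------
# feature matrix with train-only min-max normalization
# ---------------------------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Per-student model-ready features, min-max normalized to [0, 1].

    ``normalization_params`` holds the per-feature (min, max) learned on the
    training rows; degenerate features (min == max) map to 0 everywhere.
    """

    student_ids: np.ndarray
    feature_names: list[str]
    values: np.ndarray
    label: np.ndarray
    normalization_params: dict[str, tuple[float, float]]
    train_mask: np.ndarray

    @property
    def n(self) -> int:
        return len(self.student_ids)

    def denormalize(self) -> np.ndarray:
        raw = np.empty_like(self.values)
        for j, name in enumerate(self.feature_names):
            lo, hi = self.normalization_params[name]
            raw[:, j] = self.values[:, j] * (hi - lo) + lo if hi > lo else lo
        return raw

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, columns=self.feature_names,
            index=pd.Index(self.student_ids, name="student_id"),
        )
        df["label"] = self.label
        return df


def build_feature_matrix(
    table: CohortTable,
    factors: list[str],
    labels: pd.Series,
    train_ids: np.ndarray | None = None,
    feature_grades: tuple[int, int] = (1, 5),
    allow_partial: bool = False,
) -> FeatureMatrix:
    """Assemble the normalized per-student feature matrix.

    ``factors`` is the selected subset, each reduced by its own rule over
    ``feature_grades``. ``labels`` must cover every student in the table.
    Normalization statistics come from ``train_ids`` rows only (default:
    all rows). ``allow_partial`` forwards to the reductions so residual
    non-RA missingness is tolerated via observed-mean rescaling; students
    whose reduction is still undefined are dropped with a log entry.
    """
    feats = student_features(
        table, factors, feature_grades=feature_grades, allow_missing=allow_partial
    )
    y = labels.reindex(feats.index)
    if y.isna().any():
        raise MissingDataError(
            f"labels missing for {int(y.isna().sum())} students"
        )
    ok = ~feats.isna().any(axis=1)
    if not ok.all():
        logger.warning(
            "build_feature_matrix: dropping %d students with undefined features",
            int((~ok).sum()),
        )
        feats, y = feats[ok], y[ok]
    ids = feats.index.to_numpy(dtype=object)
    if train_ids is None:
        train_mask = np.ones(len(ids), dtype=bool)
    else:
        train_mask = np.isin(ids, np.asarray(train_ids, dtype=object))
    raw = feats.to_numpy(dtype=float)
    params: dict[str, tuple[float, float]] = {}
    norm = np.empty_like(raw)
    for j, name in enumerate(feats.columns):
        col = raw[train_mask, j]
        lo, hi = float(col.min()), float(col.max())
        params[name] = (lo, hi)
        norm[:, j] = (raw[:, j] - lo) / (hi - lo) if hi > lo else 0.0
    return FeatureMatrix(
        student_ids=ids,
        feature_names=list(feats.columns),
        values=norm,
        label=y.to_numpy(dtype=int),
        normalization_params=params,
        train_mask=train_mask,
    )
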