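"""Two-stage factor screening.

Stage 1 computes a Pearson (point-biserial when the target is binary)
correlation and its t-based two-sided p-value for every candidate factor;
factors with p below the significance level form the preliminary subset.
Stage 2 fits one ordinary-least-squares regression of the target on all
survivors jointly and keeps the factors whose coefficients remain
significant; domain-critical factors (the diopter history itself) can be
forced into the final subset.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._utils import ConfigError
from .synthetic_cohort import CohortTable
from .transform import student_features

logger = logging.getLogger(__name__)

__all__ = [
    "UnivariateResult",
    "MultivariateResult",
    "FeatureSubset",
    "univariate_screen",
    "select_preliminary",
    "multivariate_fit",
    "select_final",
]


@dataclass(frozen=True)
class UnivariateResult:
    factor: str
    correlation: float
    p_value: float


@dataclass(frozen=True)
class MultivariateResult:
    factor: str
    coefficient: float
    std_err: float
    t_stat: float
    p_value: float


@dataclass
class FeatureSubset:
    """Ordered selected factors with per-factor provenance
    (univariate / multivariate / forced)."""

    factors: list[str] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)

    def __contains__(self, name: str) -> bool:
        return name in self.provenance

    def __len__(self) -> int:
        return len(self.factors)

    def add(self, name: str, source: str) -> None:
        if name in self.provenance:
            return
        self.factors.append(name)
        self.provenance[name] = source

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"factor": self.factors,
             "provenance": [self.provenance[f] for f in self.factors]}
        )


def _as_feature_frame(table, target, factors=None) -> tuple[pd.DataFrame, np.ndarray]:
    """Accept either a CohortTable (reduced per-student via the transform
    rules, label-bearing students only) or a ready DataFrame/array pair."""
    if isinstance(table, CohortTable):
        feats = student_features(table, factors, allow_missing=True)
        if isinstance(target, pd.Series):
            feats = feats.reindex(target.index)
        y = np.asarray(target, dtype=float)
        return feats, y
    feats = pd.DataFrame(table)
    if factors is not None:
        feats = feats[factors]
    return feats, np.asarray(target, dtype=float)


def univariate_screen(table, target, factors: list[str] | None = None) -> list[UnivariateResult]:
    """Per-factor correlation with the target and its two-sided p-value.

    Uses the Pearson statistic on pairwise-complete observations, which is
    the point-biserial correlation when the target is 0/1. Zero-variance
    factors are reported with correlation 0 and p = 1. Requires n >= 3 and
    a non-constant target.
    """
    feats, y = _as_feature_frame(table, target, factors)
    if len(y) < 3:
        raise ConfigError(f"univariate screen needs n >= 3, got n = {len(y)}")
    if np.nanstd(y) == 0:
        raise ConfigError("target is constant; correlation undefined")
    results = []
    for name in feats.columns:
        x = feats[name].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        xs, ys = x[ok], y[ok]
        if len(xs) < 3 or xs.std() == 0 or ys.std() == 0:
            results.append(UnivariateResult(name, 0.0, 1.0))
            continue
        r, p = stats.pearsonr(xs, ys)
        results.append(UnivariateResult(name, float(r), float(p)))
    return results


def select_preliminary(results: list[UnivariateResult], alpha: float) -> FeatureSubset:
    """Factors with p strictly below ``alpha``, original order preserved."""
    if not (0.0 < alpha < 1.0) and alpha != 0.0:
        raise ConfigError(f"alpha must lie in (0, 1), got {alpha}")
    subset = FeatureSubset()
    for res in results:
        if res.p_value < alpha:
            subset.add(res.factor, "univariate")
    if len(subset) == 0:
        warnings.warn("no factor survived the univariate screen", stacklevel=2)
    return subset


def multivariate_fit(table, subset: FeatureSubset, target) -> list[MultivariateResult]:
    """Joint OLS of the target on every preliminary factor.

    Rows with any missing value are dropped; collinear columns are detected
    by incremental rank and removed with a warning before fitting. Returns
    coefficient, standard error, t statistic and two-sided p per surviving
    factor (df = n - k - 1 via the intercept-bearing OLS fit).
    """
    feats, y = _as_feature_frame(table, target, subset.factors)
    ok = ~(feats.isna().any(axis=1).to_numpy() | np.isnan(y))
    feats, y = feats[ok], y[ok]
    n, k = feats.shape
    if n <= k + 1:
        raise ConfigError(f"multivariate fit needs n > k + 1 (n={n}, k={k})")
    X = feats.to_numpy(dtype=float)
    # drop collinear columns by incremental rank on the centered design
    keep: list[int] = []
    Xc = X - X.mean(axis=0)
    for j in range(k):
        cand = Xc[:, keep + [j]]
        if np.linalg.matrix_rank(cand) == len(keep) + 1:
            keep.append(j)
        else:
            logger.warning(
                "multivariate_fit: dropping collinear factor %s", feats.columns[j]
            )
    cols = [feats.columns[j] for j in keep]
    design = sm.add_constant(pd.DataFrame(X[:, keep], columns=cols), has_constant="add")
    fit = sm.OLS(y, design).fit()
    return [
        MultivariateResult(
            factor=c,
            coefficient=float(fit.params[c]),
            std_err=float(fit.bse[c]),
            t_stat=float(fit.tvalues[c]),
            p_value=float(fit.pvalues[c]),
        )
        for c in cols
    ]


def select_final(
    results: list[MultivariateResult],
    alpha: float,
    forced: list[str] | None = None,
) -> FeatureSubset:
    """Factors significant in the joint model, plus forced factors.

    Strict p < alpha as in the preliminary stage. Forced factors already
    selected on their own merits keep provenance ``multivariate``.
    """
    if not (0.0 < alpha < 1.0) and alpha != 0.0:
        raise ConfigError(f"alpha must lie in (0, 1), got {alpha}")
    subset = FeatureSubset()
    for res in results:
        if res.p_value < alpha:
            subset.add(res.factor, "multivariate")
    for name in forced or []:
        subset.add(name, "forced")
    return subset
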