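"""End-to-end orchestration: factor selection -> data curation -> model
construction.

One master seed deterministically derives a seed per stage, so the whole
run is reproducible and each stage can be re-run independently. The default
run mirrors the published procedure (screen and impute on the full table,
then cross-validate); ``nested=True`` instead repeats screening and
imputation inside every cross-validation fold, which is the leakage-free
variant.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._utils import ConfigError, derive_seed, sha256_file
from .synthetic_cohort import (
    CohortConfig,
    CohortTable,
    MYOPIA_THRESHOLD_D,
    apply_missingness,
    derive_myopia_label,
    generate_cohort,
)
from .screening import (
    FeatureSubset,
    multivariate_fit,
    select_final,
    select_preliminary,
    univariate_screen,
)
from .imputation import (
    DEFAULT_P_GRID,
    DEFAULT_TOLERANCE_D,
    ImputationSelection,
    fill_missing,
    select_imputation_model,
)
from .transform import FeatureMatrix, build_feature_matrix
from .modeling import ModelConfig, evaluate_classifier, run_baselines

__all__ = ["PipelineConfig", "RunManifest", "PipelineResult", "run_pipeline", "report"]


@dataclass
class PipelineConfig:
    """Master configuration; every stage knob in one place."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    cohort_csv: str | None = None
    metadata_csv: str | None = None
    alpha: float = 0.05
    forced: tuple[str, ...] = ("RA",)
    label_threshold: float = MYOPIA_THRESHOLD_D
    tolerance: float = DEFAULT_TOLERANCE_D
    p_grid: tuple[float, ...] = DEFAULT_P_GRID
    gbrt_rounds: int = 100
    gbrt_shrinkage: float = 0.1
    gbrt_max_depth: int = 3
    gbrt_min_leaf: int = 5
    model: ModelConfig = field(default_factory=ModelConfig)
    baselines: tuple[str, ...] | None = None
    nested: bool = False
    outdir: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, value in raw.items():
            if key == "cohort":
                for k, v in value.items():
                    if not hasattr(cfg.cohort, k):
                        raise ConfigError(f"unknown cohort field {k!r}")
                    setattr(cfg.cohort, k, tuple(v) if k == "grades" else v)
            elif key == "model":
                for k, v in value.items():
                    if not hasattr(cfg.model, k):
                        raise ConfigError(f"unknown model field {k!r}")
                    setattr(cfg.model, k, v)
            elif hasattr(cfg, key):
                if key in {"forced", "p_grid", "baselines"} and value is not None:
                    value = tuple(value)
                setattr(cfg, key, value)
            else:
                raise ConfigError(f"unknown pipeline field {key!r}")
        return cfg


@dataclass
class RunManifest:
    """Provenance of one run: seeds, timings, outputs, headline choices."""

    master_seed: int
    stage_seeds: dict[str, int] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)
    file_digests: dict[str, str] = field(default_factory=dict)
    selected_features: list[str] = field(default_factory=list)
    chosen_p: float | None = None
    label_prevalence: float | None = None
    warnings: list[str] = field(default_factory=list)
    metrics: dict[str, float] = field(default_factory=dict)

    def to_json(self, drop_timings: bool = False) -> str:
        data = asdict(self)
        if drop_timings:
            data.pop("timings")
        return json.dumps(data, indent=2, sort_keys=True, default=float)


@dataclass
class PipelineResult:
    manifest: RunManifest
    cohort: CohortTable
    univariate: pd.DataFrame
    multivariate: pd.DataFrame
    subset: FeatureSubset
    selection: ImputationSelection
    filled: CohortTable
    features: FeatureMatrix
    eval_report: object
    comparison: pd.DataFrame | None = None
    nested_cv: tuple[float, list[float]] | None = None


def _load_cohort(config: PipelineConfig) -> CohortTable:
    if config.cohort_csv is not None:
        return CohortTable.read_csv(config.cohort_csv, config.metadata_csv)
    sim_cfg = config.cohort
    sim_cfg.seed = derive_seed(config.seed, "simulate")
    table = generate_cohort(sim_cfg)
    return apply_missingness(table, sim_cfg)


def screen_cohort(
    table: CohortTable, alpha: float, forced, label_threshold: float
) -> tuple[pd.DataFrame, pd.DataFrame, FeatureSubset, pd.Series]:
    """Two-stage screening on complete-label students.

    Returns the stage tables, the final subset, and the complete-case
    labels used as the screening target.
    """
    ra_top = table.value("RA")[:, -1]
    cc = ~np.isnan(ra_top)
    if cc.sum() < 10:
        raise ConfigError("too few students with observed top-grade RA to screen")
    table_cc = table.subset_students(cc)
    labels = derive_myopia_label(table_cc, label_threshold)
    candidates = [f for f in table.factor_names if f != "RA"]
    uni = univariate_screen(table_cc, labels, factors=candidates)
    uni_df = pd.DataFrame([asdict(u) for u in uni])
    prelim = select_preliminary(uni, alpha)
    if len(prelim) == 0:
        return uni_df, pd.DataFrame(), select_final([], alpha, list(forced)), labels
    multi = multivariate_fit(table_cc, prelim, labels)
    multi_df = pd.DataFrame([asdict(m) for m in multi])
    final = select_final(multi, alpha, list(forced))
    return uni_df, multi_df, final, labels


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute screening -> imputation -> transform -> modeling.

    All intermediate tables are returned (and written under ``outdir`` when
    given, with their digests recorded in the manifest).
    """
    manifest = RunManifest(master_seed=config.seed)
    t0 = time.perf_counter()

    cohort = _load_cohort(config)
    manifest.stage_seeds["simulate"] = derive_seed(config.seed, "simulate")
    manifest.timings["load"] = time.perf_counter() - t0

    t = time.perf_counter()
    uni_df, multi_df, subset, _ = screen_cohort(
        cohort, config.alpha, config.forced, config.label_threshold
    )
    manifest.selected_features = list(subset.factors)
    manifest.timings["screen"] = time.perf_counter() - t

    t = time.perf_counter()
    impute_seed = derive_seed(config.seed, "impute")
    manifest.stage_seeds["impute"] = impute_seed
    predictors = [f for f in subset.factors if f != "RA"]
    selection = select_imputation_model(
        cohort,
        p_grid=config.p_grid,
        tolerance=config.tolerance,
        rounds=config.gbrt_rounds,
        shrinkage=config.gbrt_shrinkage,
        max_depth=config.gbrt_max_depth,
        min_leaf=config.gbrt_min_leaf,
        seed=impute_seed,
        predictors=predictors or None,
    )
    manifest.chosen_p = selection.proportion
    filled = fill_missing(cohort, selection)
    if filled.fill_report and filled.fill_report["skipped"]:
        manifest.warnings.append(
            f"{filled.fill_report['skipped']} RA cells left missing after fill"
        )
    manifest.timings["impute"] = time.perf_counter() - t

    t = time.perf_counter()
    labelable = ~np.isnan(filled.value("RA")[:, -1])
    if not labelable.all():
        manifest.warnings.append(
            f"dropping {int((~labelable).sum())} students without a grade-6 label"
        )
        filled_l = filled.subset_students(labelable)
    else:
        filled_l = filled
    labels = derive_myopia_label(filled_l, config.label_threshold)
    manifest.label_prevalence = float(labels.mean())
    features = build_feature_matrix(
        filled_l, subset.factors, labels, allow_partial=True
    )
    manifest.timings["transform"] = time.perf_counter() - t

    t = time.perf_counter()
    model_cfg = config.model
    model_cfg.seed = derive_seed(config.seed, "model")
    manifest.stage_seeds["model"] = model_cfg.seed
    eval_report = evaluate_classifier(features, model_cfg)
    manifest.metrics = eval_report.to_dict()
    comparison = None
    if config.baselines is not None:
        comparison = run_baselines(features, model_cfg, list(config.baselines) or None)
    nested = None
    if config.nested:
        nested = nested_cv(cohort, config)
        manifest.metrics["nested_cv_mean"] = nested[0]
    manifest.timings["model"] = time.perf_counter() - t

    result = PipelineResult(
        manifest, cohort, uni_df, multi_df, subset, selection, filled,
        features, eval_report, comparison, nested,
    )
    if config.outdir is not None:
        _write_outputs(result, config)
    return result


def nested_cv(table: CohortTable, config: PipelineConfig) -> tuple[float, list[float]]:
    """Leakage-free cross-validation: screening and imputation are refit on
    each fold's training students only; folds cover the students whose true
    label is observed."""
    from sklearn.model_selection import StratifiedKFold
    from .modeling import _svm  # same estimator as the main harness

    ra_top = table.value("RA")[:, -1]
    cc = np.nonzero(~np.isnan(ra_top))[0]
    cc_table = table.subset_students(cc)
    y_all = derive_myopia_label(cc_table, config.label_threshold).to_numpy()
    seed = derive_seed(config.seed, "nested")
    skf = StratifiedKFold(n_splits=config.model.cv_folds, shuffle=True, random_state=seed)
    scores = []
    for tr, te in skf.split(np.zeros(len(y_all)), y_all):
        train_tab = cc_table.subset_students(tr)
        _, _, subset, _ = screen_cohort(
            train_tab, config.alpha, config.forced, config.label_threshold
        )
        predictors = [f for f in subset.factors if f != "RA"]
        selection = select_imputation_model(
            train_tab, p_grid=config.p_grid, tolerance=config.tolerance,
            rounds=config.gbrt_rounds, shrinkage=config.gbrt_shrinkage,
            max_depth=config.gbrt_max_depth, min_leaf=config.gbrt_min_leaf,
            seed=seed, predictors=predictors or None,
        )
        filled = fill_missing(cc_table, selection)
        labels = derive_myopia_label(filled, config.label_threshold)
        train_ids = cc_table.student_ids[tr]
        feats = build_feature_matrix(
            filled, subset.factors, labels, train_ids=train_ids, allow_partial=True
        )
        tr_mask = feats.train_mask
        est = _svm(config.model)
        est.fit(feats.values[tr_mask], feats.label[tr_mask])
        acc = float((est.predict(feats.values[~tr_mask]) == feats.label[~tr_mask]).mean())
        scores.append(acc)
    return float(np.mean(scores)), scores


def _write_outputs(result: PipelineResult, config: PipelineConfig) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m = result.manifest

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        m.file_digests[name] = sha256_file(path)

    emit("univariate.csv", lambda p: result.univariate.to_csv(p, index=False))
    emit("multivariate.csv", lambda p: result.multivariate.to_csv(p, index=False))
    emit("subset.txt", lambda p: p.write_text("\n".join(result.subset.factors) + "\n"))
    emit("rep_sweep.csv", lambda p: result.selection.sweep.to_csv(p, index=False))
    emit("features.csv", lambda p: result.features.frame().to_csv(p))
    if result.eval_report.roc_points is not None:
        emit("roc_points.csv", lambda p: pd.DataFrame(
            result.eval_report.roc_points, columns=["fpr", "tpr"]
        ).to_csv(p, index=False))
    if result.comparison is not None:
        emit("comparison.csv", lambda p: result.comparison.to_csv(p, index=False))
    emit("report.txt", lambda p: p.write_text(report(result)))
    (outdir / "manifest.json").write_text(m.to_json())


def report(result: PipelineResult) -> str:
    """Human-readable run summary (sweep, subset, metrics, warnings)."""
    m = result.manifest
    lines = [
        "Myopia prediction pipeline - run summary",
        "=" * 42,
        f"master seed: {m.master_seed}",
        f"label prevalence (myopic grade-6): {m.label_prevalence:.3f}"
        if m.label_prevalence is not None else "label prevalence: n/a",
        "",
        "Selected feature subset:",
    ]
    for f in result.subset.factors:
        lines.append(f"  {f:10s} [{result.subset.provenance[f]}]")
    lines += ["", f"REP-selected train share p = {m.chosen_p}", "", "REP sweep:"]
    lines.append(result.selection.sweep.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
    r = result.eval_report
    lines += [
        "",
        "Linear-SVM evaluation (holdout / CV):",
        f"  accuracy    {r.accuracy:.3f}",
        f"  precision   {r.precision:.3f}",
        f"  sensitivity {r.sensitivity:.3f}",
        f"  specificity {r.specificity:.3f}",
        f"  f1          {r.f1:.3f}",
        f"  AUC         {r.auc:.3f}",
        f"  10-fold CV  {r.cv_mean:.3f}",
    ]
    if result.comparison is not None and len(result.comparison):
        lines += ["", "Baseline comparison:",
                  result.comparison.to_string(index=False)]
    if result.nested_cv is not None:
        lines += ["", f"Nested (leakage-free) CV accuracy: {result.nested_cv[0]:.3f}"]
    if m.warnings:
        lines += ["", "Warnings:"] + [f"  - {w}" for w in m.warnings]
    return "\n".join(lines) + "\n"
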