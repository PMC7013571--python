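"""Synthetic longitudinal myopia cohorts.

The real study cohort (primary-school students followed from grade 1 to
grade 6, with behavioural, ocular and refraction measurements) was never
deposited, so this module generates cohorts with the same documented shape
and statistical structure:

* one record per student per grade for ~26 named factors plus the diopter
  column ``RA`` (negative diopters = myopic);
* annual RA progression that is a linear-Gaussian function of standardized
  per-student factor traits, with configurable signed effect sizes whose
  default sign pattern mirrors the published multivariate screen (parental
  glasses, gender, indoor/outdoor activity, axial length, corneal curvature,
  white meat and eggs protective; adjustment ability, pulse, cola, red meat
  adverse);
* grade-biased missingness: grade-1 records complete, RA missingness ramping
  up with grade to a configurable maximum, other time-varying factors missing
  at a flat rate.

Everything is deterministic given ``CohortConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._utils import ConfigError, MissingDataError

__all__ = [
    "FactorDescriptor",
    "CohortConfig",
    "CohortTable",
    "default_factor_set",
    "default_effect_sizes",
    "strong_effect_sizes",
    "nuisance_factor_set",
    "generate_cohort",
    "apply_missingness",
    "derive_myopia_label",
    "RA_PLAUSIBLE_RANGE",
    "MYOPIA_THRESHOLD_D",
]

#: Plausible spherical-equivalent range in diopters; generated values are
#: clipped here and cleaning treats values outside it as outliers.
RA_PLAUSIBLE_RANGE = (-12.0, 8.0)

#: Default diagnostic cutoff: grade-6 RA at or below -0.5 D counts as myopic.
MYOPIA_THRESHOLD_D = -0.5

KIND_TO_RULE = {
    "objective": "passthrough",
    "categorical_behavioral": "sum",
    "continuous_ocular": "mean",
    "diopter": "annual_progress",
}


@dataclass(frozen=True)
class FactorDescriptor:
    """Metadata for one factor: its kind drives the longitudinal transform.

    Kinds
    -----
    objective
        Static per-student attributes (gender, number of myopic parents);
        the raw value is used directly (``passthrough``).
    categorical_behavioral
        Discrete behaviour frequencies; grades 1-5 are summed (``sum``).
    continuous_ocular
        Continuous physiological measurements; grades 1-5 are averaged
        (``mean``).
    diopter
        Refraction itself; reduced to mean annual progression
        (``annual_progress``).
    """

    name: str
    description: str
    kind: str
    transform_rule: str | None = None
    value_domain: tuple[float, float] | tuple[int, ...] | None = None

    def __post_init__(self):
        if self.kind not in KIND_TO_RULE:
            raise ConfigError(f"factor {self.name}: unknown kind {self.kind!r}")
        expected = KIND_TO_RULE[self.kind]
        if self.transform_rule is None:
            object.__setattr__(self, "transform_rule", expected)
        elif self.transform_rule != expected:
            raise ConfigError(
                f"factor {self.name}: kind {self.kind!r} requires transform_rule "
                f"{expected!r}, got {self.transform_rule!r}"
            )


def default_factor_set() -> list[FactorDescriptor]:
    """The 25 screened candidate factors plus RA.

    Value domains are plausible for a Chinese primary-school cohort:
    behaviour frequencies are small counts (days/week) or yes/no flags,
    ocular measurements use clinical units (mm for axial length, diopters
    for keratometry).
    """
    F = FactorDescriptor
    return [
        F("DAI", "No. of parents wearing glasses", "objective", value_domain=(0, 1, 2)),
        F("GENDER", "Gender (1 = male)", "objective", value_domain=(0, 1)),
        F("RPR", "Refraction before mydriasis (right eye)", "continuous_ocular", value_domain=(-10.0, 6.0)),
        F("JTR", "Close adjustment ability (right eye)", "continuous_ocular", value_domain=(0.0, 10.0)),
        F("YTR", "Remote adjustment ability (right eye)", "continuous_ocular", value_domain=(0.0, 10.0)),
        F("DRNBASE", "Distant vision (right eye)", "continuous_ocular", value_domain=(3.5, 5.5)),
        F("JG", "Amount of indoor activities", "categorical_behavioral", value_domain=tuple(range(8))),
        F("YW", "Amount of outdoor activities", "categorical_behavioral", value_domain=tuple(range(8))),
        F("AL", "Axial length (mm)", "continuous_ocular", value_domain=(20.0, 28.0)),
        F("K1", "Corneal curvature, left eye (D)", "continuous_ocular", value_domain=(38.0, 48.0)),
        F("K2", "Corneal curvature, right eye (D)", "continuous_ocular", value_domain=(38.0, 48.0)),
        F("PULSE", "Pulses per minute", "continuous_ocular", value_domain=(50.0, 130.0)),
        F("TUTOR1", "Participation in outdoor classes", "categorical_behavioral", value_domain=(0, 1)),
        F("TUTOR2", "Participation in indoor classes", "categorical_behavioral", value_domain=(0, 1)),
        F("ETEST", "Regular eye examination", "categorical_behavioral", value_domain=(0, 1)),
        F("MSMK", "Exposure to smoking", "categorical_behavioral", value_domain=(0, 1)),
        F("CELLP", "Plays cellphone", "categorical_behavioral", value_domain=(0, 1)),
        F("COSTM", "Writes with wrong posture", "categorical_behavioral", value_domain=(0, 1)),
        F("BED", "Reads in bed", "categorical_behavioral", value_domain=(0, 1)),
        F("COLA", "Frequency of drinking carbonated drinks", "categorical_behavioral", value_domain=tuple(range(8))),
        F("REDM", "Frequency of eating red meat", "categorical_behavioral", value_domain=tuple(range(8))),
        F("WHIM", "Frequency of eating white meat", "categorical_behavioral", value_domain=tuple(range(8))),
        F("EGG", "Frequency of eating eggs", "categorical_behavioral", value_domain=tuple(range(8))),
        F("MILK", "Frequency of drinking milk", "categorical_behavioral", value_domain=tuple(range(8))),
        F("VOLUME", "Daily amount of water drinking", "categorical_behavioral", value_domain=tuple(range(8))),
        F("RA", "Refraction / diopter (negative = myopic)", "diopter", value_domain=RA_PLAUSIBLE_RANGE),
    ]


def nuisance_factor_set(n: int) -> list[FactorDescriptor]:
    """``n`` additional zero-effect behavioural factors (the ~200-factor mode)."""
    return [
        FactorDescriptor(
            f"NUIS{i:03d}",
            f"Nuisance behavioural factor {i}",
            "categorical_behavioral",
            value_domain=tuple(range(8)),
        )
        for i in range(n)
    ]


# Signed effect of one latent-trait SD on annual RA change, in diopters/year.
# Positive = hyperopic shift (protective), negative = myopic shift (risk);
# signs mirror the published multivariate screen's direction pattern.
_DEFAULT_EFFECTS = {
    "DAI": +0.04, "GENDER": +0.03, "JG": +0.05, "YW": +0.04,
    "AL": +0.07, "K1": +0.05, "K2": +0.05, "WHIM": +0.03, "EGG": +0.04,
    "JTR": -0.06, "YTR": -0.10, "PULSE": -0.03, "COLA": -0.06, "REDM": -0.04,
}


def default_effect_sizes() -> dict[str, float]:
    """Default signed effect sizes (D/yr per factor SD), published sign pattern."""
    return dict(_DEFAULT_EFFECTS)


def strong_effect_sizes() -> dict[str, float]:
    """Planted-signal study condition: every effect at >= 0.3 noise-SD.

    With the default noise_sd of 0.25 D/yr this puts each planted factor at
    |effect| >= 0.075 D/yr per trait SD, keeping the default sign pattern;
    used by the screening-power, imputation-recovery and end-to-end
    properties.
    """
    return {
        "DAI": +0.075, "GENDER": +0.075, "JG": +0.09, "YW": +0.075,
        "AL": +0.12, "K1": +0.09, "K2": +0.09, "WHIM": +0.075, "EGG": +0.075,
        "JTR": -0.09, "YTR": -0.15, "PULSE": -0.075, "COLA": -0.12, "REDM": -0.075,
    }


@dataclass
class CohortConfig:
    """Study-condition knobs for the generator.

    Defaults reproduce the documented cohort: 3112 students, 57.8% male,
    grades 1-6, ~15% mean per-factor missingness ramping to 40% for grade-6
    RA. ``effect_sizes`` maps factor name to the signed effect (D/yr per
    trait SD) on annual RA change; ``noise_sd`` is the SD (diopters) of the
    per-transition progression noise.
    """

    n_students: int = 3112
    male_fraction: float = 0.578
    grades: tuple[int, int] = (1, 6)
    factor_set: list[FactorDescriptor] = field(default_factory=default_factor_set)
    effect_sizes: dict[str, float] = field(default_factory=default_effect_sizes)
    noise_sd: float = 0.25
    baseline_ra_mean: float = 0.5
    baseline_ra_sd: float = 0.5
    annual_drift: float = -0.15
    missing_rate_mean: float = 0.15
    missing_rate_max: float = 0.40
    seed: int = 0
    # within-student year-to-year jitter of factor values, in trait SDs
    factor_jitter: float = 0.3

    def validate(self) -> None:
        if self.n_students < 1:
            raise ConfigError("n_students must be >= 1")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigError("male_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.baseline_ra_sd < 0:
            raise ConfigError("baseline_ra_sd must be >= 0")
        if not (0.0 <= self.missing_rate_mean <= self.missing_rate_max <= 1.0):
            raise ConfigError(
                "missing rates must satisfy 0 <= missing_rate_mean <= missing_rate_max <= 1"
            )
        lo, hi = self.grades
        if hi <= lo:
            raise ConfigError("grades must be an inclusive range with at least two grades")
        names = [f.name for f in self.factor_set]
        if len(set(names)) != len(names):
            raise ConfigError("factor_set contains duplicate names")
        if "RA" not in names:
            raise ConfigError("factor_set must include the diopter factor RA")
        unknown = set(self.effect_sizes) - set(names)
        if unknown:
            raise ConfigError(f"effect_sizes reference unknown factors: {sorted(unknown)}")

    @property
    def grade_list(self) -> list[int]:
        return list(range(self.grades[0], self.grades[1] + 1))


class CohortTable:
    """Long-format student x grade x factor table with a missing-value mask.

    Internally stores one dense ``(n_students, n_grades)`` float array per
    factor (NaN = missing) for speed; long and wide DataFrame views and CSV
    round-trips are provided at the edges. ``imputed`` flags cells filled by
    the imputation stage.
    """

    def __init__(
        self,
        student_ids: Sequence[str],
        grades: Sequence[int],
        descriptors: Iterable[FactorDescriptor],
        values: Mapping[str, np.ndarray],
    ):
        self.student_ids = np.asarray(student_ids, dtype=object)
        self.grades = np.asarray(grades, dtype=int)
        self.descriptors = {d.name: d for d in descriptors}
        self.values: dict[str, np.ndarray] = {}
        shape = (len(self.student_ids), len(self.grades))
        for name, arr in values.items():
            if name not in self.descriptors:
                raise ConfigError(f"values given for undeclared factor {name!r}")
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ConfigError(
                    f"factor {name!r}: array shape {arr.shape} != {shape}"
                )
            self.values[name] = arr
        self.imputed: dict[str, np.ndarray] = {}
        self.fill_report: dict[str, int] | None = None

    # -- basic accessors ---------------------------------------------------
    @property
    def n_students(self) -> int:
        return len(self.student_ids)

    @property
    def factor_names(self) -> list[str]:
        return list(self.values.keys())

    def value(self, factor: str) -> np.ndarray:
        return self.values[factor]

    def grade_index(self, grade: int) -> int:
        idx = np.nonzero(self.grades == grade)[0]
        if len(idx) == 0:
            raise KeyError(f"grade {grade} not in table")
        return int(idx[0])

    def missing_fraction(self, factor: str, grade: int | None = None) -> float:
        arr = self.values[factor]
        if grade is not None:
            arr = arr[:, self.grade_index(grade)]
        return float(np.isnan(arr).mean())

    def copy(self) -> "CohortTable":
        out = CohortTable(
            self.student_ids.copy(),
            self.grades.copy(),
            list(self.descriptors.values()),
            {k: v.copy() for k, v in self.values.items()},
        )
        out.imputed = {k: v.copy() for k, v in self.imputed.items()}
        return out

    def subset_students(self, keep: np.ndarray) -> "CohortTable":
        """Row-subset by boolean mask or index array over students."""
        out = CohortTable(
            self.student_ids[keep],
            self.grades.copy(),
            list(self.descriptors.values()),
            {k: v[keep] for k, v in self.values.items()},
        )
        out.imputed = {k: v[keep] for k, v in self.imputed.items()}
        return out

    def equals(self, other: "CohortTable") -> bool:
        if list(self.student_ids) != list(other.student_ids):
            return False
        if list(self.grades) != list(other.grades):
            return False
        if set(self.values) != set(other.values):
            return False
        return all(
            np.array_equal(self.values[k], other.values[k], equal_nan=True)
            for k in self.values
        )

    # -- DataFrame / CSV views ---------------------------------------------
    def to_long(self) -> pd.DataFrame:
        """Tidy view: student_id, grade, factor, value (NaN = missing)."""
        frames = []
        n, g = len(self.student_ids), len(self.grades)
        for name, arr in self.values.items():
            df = pd.DataFrame(
                {
                    "student_id": np.repeat(self.student_ids, g),
                    "grade": np.tile(self.grades, n),
                    "factor": name,
                    "value": arr.ravel(),
                }
            )
            if name in self.imputed:
                df["imputed"] = self.imputed[name].ravel()
            else:
                df["imputed"] = False
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def to_wide(self) -> pd.DataFrame:
        """One row per student, columns ``FACTOR_g<grade>``."""
        cols = {}
        for name, arr in self.values.items():
            for j, grade in enumerate(self.grades):
                cols[f"{name}_g{grade}"] = arr[:, j]
        return pd.DataFrame(cols, index=pd.Index(self.student_ids, name="student_id"))

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"name": d.name, "kind": d.kind, "transform_rule": d.transform_rule,
                 "description": d.description}
                for d in self.descriptors.values()
                if d.name in self.values
            ]
        )

    def write_csv(self, path, metadata_path=None) -> None:
        # %.17g guarantees bit-exact float round trips through the text file
        self.to_long().to_csv(path, index=False, float_format="%.17g")
        if metadata_path is not None:
            self.metadata_frame().to_csv(metadata_path, index=False)

    @classmethod
    def from_long(
        cls, long_df: pd.DataFrame, metadata: pd.DataFrame | None = None
    ) -> "CohortTable":
        students = list(dict.fromkeys(long_df["student_id"]))
        grades = sorted(long_df["grade"].unique())
        factors = list(dict.fromkeys(long_df["factor"]))
        if metadata is not None:
            desc = [
                FactorDescriptor(
                    r["name"], r.get("description", r["name"]), r["kind"]
                )
                for r in metadata.to_dict("records")
            ]
        else:  # untyped fallback: treat RA as diopter, the rest as continuous
            desc = [
                FactorDescriptor(f, f, "diopter" if f == "RA" else "continuous_ocular")
                for f in factors
            ]
        pivot = long_df.pivot_table(
            index="student_id", columns=["factor", "grade"], values="value",
            dropna=False, aggfunc="first", observed=True,
        ).reindex(students)
        values = {}
        for f in factors:
            block = pivot[f].reindex(columns=grades)
            values[f] = block.to_numpy(dtype=float)
        return cls(students, grades, desc, values)

    @classmethod
    def read_csv(cls, path, metadata_path=None) -> "CohortTable":
        long_df = pd.read_csv(path, float_precision="round_trip")
        meta = pd.read_csv(metadata_path) if metadata_path is not None else None
        return cls.from_long(long_df, meta)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _standardized_gender(gender: np.ndarray, p: float) -> np.ndarray:
    sd = np.sqrt(p * (1 - p))
    if sd == 0:
        return np.zeros_like(gender, dtype=float)
    return (gender - p) / sd


def generate_cohort(config: CohortConfig) -> CohortTable:
    """Generate a complete (no missing cells) longitudinal cohort.

    Each student i carries a latent standardized trait u_ik per factor k;
    observed per-grade values are monotone mappings of the trait plus
    year-to-year jitter. Refraction follows a smooth per-student trajectory
    with an annual progression rate

        delta_i = annual_drift + sum_k effect_k * u_ik

    so the observed diopter at grade g is

        RA_ig = base_i + (g - 1) * delta_i + e_ig,

    with base_i ~ N(baseline_ra_mean, baseline_ra_sd^2) and independent
    per-visit measurement error e_ig ~ N(0, noise_sd^2). Positive effects
    push towards hyperopia (protective), negative towards myopia. With all
    effects zero the grade-6 outcome is independent of every feature the
    predictor sees, so a null cohort is genuinely unpredictable.
    Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_students
    grades = config.grade_list
    g = len(grades)
    ids = np.array([f"S{i:05d}" for i in range(n)], dtype=object)

    values: dict[str, np.ndarray] = {}
    traits: dict[str, np.ndarray] = {}

    gender = (rng.random(n) < config.male_fraction).astype(float)
    jit = config.factor_jitter

    for d in config.factor_set:
        if d.name == "RA":
            continue
        if d.name == "GENDER":
            u = _standardized_gender(gender, config.male_fraction)
            vals = np.tile(gender[:, None], (1, g))
        elif d.name == "DAI":
            # number of myopic parents: ordinal 0/1/2 from a latent normal
            z = rng.standard_normal(n)
            dai = np.digitize(z, [-0.1, 1.25]).astype(float)  # ~46%/43%/11%
            u = (dai - dai.mean()) / (dai.std() if dai.std() > 0 else 1.0)
            vals = np.tile(dai[:, None], (1, g))
        else:
            z = rng.standard_normal(n)
            u = z
            yearly = z[:, None] + jit * rng.standard_normal((n, g))
            if d.kind == "categorical_behavioral":
                dom = d.value_domain or tuple(range(8))
                if len(dom) == 2:  # yes/no flag, ~40% prevalence
                    vals = (yearly > 0.25).astype(float)
                else:
                    lo, hi = min(dom), max(dom)
                    center, spread = (lo + hi) / 2.0, (hi - lo) / 4.0
                    vals = np.clip(np.round(center + spread * yearly), lo, hi)
            else:  # continuous ocular measurement
                lo, hi = d.value_domain or (0.0, 10.0)
                center, spread = (lo + hi) / 2.0, (hi - lo) / 8.0
                vals = np.clip(center + spread * yearly, lo, hi)
        traits[d.name] = u
        values[d.name] = vals.astype(float)

    # annual progression: drift + planted effects on the latent traits
    delta = np.full(n, config.annual_drift)
    for name, eff in config.effect_sizes.items():
        if eff != 0.0 and name in traits:
            delta = delta + eff * traits[name]

    ra = np.empty((n, g))
    base = config.baseline_ra_mean + config.baseline_ra_sd * rng.standard_normal(n)
    for j in range(g):
        eps = config.noise_sd * rng.standard_normal(n) if config.noise_sd > 0 else 0.0
        ra[:, j] = base + (grades[j] - grades[0]) * delta + eps
    values["RA"] = np.clip(ra, *RA_PLAUSIBLE_RANGE)

    # preserve declared factor order, RA last only if declared last
    ordered = {d.name: values[d.name] for d in config.factor_set}
    return CohortTable(ids, grades, config.factor_set, ordered)


def apply_missingness(table: CohortTable, config: CohortConfig) -> CohortTable:
    """Knock out cells missing-at-random conditional on grade.

    Grade-1 records stay complete. RA missingness ramps linearly with grade
    up to ``missing_rate_max`` at the top grade (its per-grade mean is then
    ``missing_rate_max / 2``). Other time-varying factors use a flat rate on
    grades 2+, scaled so each factor's mean missing fraction over all grades
    equals ``missing_rate_mean``. Objective per-student factors (gender,
    parental glasses) are registration data and never missing.
    """
    if not (0.0 <= config.missing_rate_mean <= config.missing_rate_max <= 1.0):
        raise ConfigError(
            "missing rates must satisfy 0 <= missing_rate_mean <= missing_rate_max <= 1"
        )
    out = table.copy()
    rng = np.random.default_rng([config.seed, 7919])
    n = out.n_students
    grades = out.grades
    g = len(grades)
    span = g - 1 if g > 1 else 1
    flat = min(config.missing_rate_mean * g / span, 1.0)
    for name, arr in out.values.items():
        d = out.descriptors[name]
        if d.kind == "objective":
            continue
        if name == "RA":
            rates = config.missing_rate_max * (grades - grades[0]) / span
        else:
            rates = np.where(grades == grades[0], 0.0, flat)
        mask = rng.random((n, g)) < rates[None, :]
        arr = arr.copy()
        arr[mask] = np.nan
        out.values[name] = arr
    return out


def derive_myopia_label(
    table: CohortTable, threshold: float = MYOPIA_THRESHOLD_D
) -> pd.Series:
    """Binary myopia outcome: 1 iff top-grade RA <= threshold (inclusive).

    Requires the top-grade RA to be observed for every student (run after
    imputation, or subset to complete-label students first); otherwise
    raises listing the offending students.
    """
    ra = table.value("RA")[:, -1]
    missing = np.isnan(ra)
    if missing.any():
        bad = list(table.student_ids[missing][:10])
        raise MissingDataError(
            f"{missing.sum()} students lack top-grade RA (e.g. {bad}); "
            "impute or subset before labelling"
        )
    return pd.Series(
        (ra <= threshold).astype(int),
        index=pd.Index(table.student_ids, name="student_id"),
        name="myopia",
    )
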