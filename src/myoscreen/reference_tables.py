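"""Published summary tables from the original adolescent-myopia cohort study.

The raw cohort (primary schools, Henan province; 3112 students followed
from grade 1 to grade 6) was never deposited; the printed summary tables
are its only public trace and serve here as worked-example inputs — the
screening tables for the feature-selection rule, the train-share sweep for
the REP selection rule, and the baseline metric rows for internal-
consistency checks of the evaluation harness.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "univariate_screen_table",
    "multivariate_screen_table",
    "imputation_sweep_table",
    "baseline_metrics_table",
    "PUBLISHED_FINAL_SUBSET",
]

#: The study's final 15-factor feature subset (diopter history RA forced in).
PUBLISHED_FINAL_SUBSET = frozenset({
    "DAI", "GENDER", "JTR", "YTR", "JG", "YW", "AL", "K1", "K2",
    "PULSE", "COLA", "REDM", "WHIM", "EGG", "RA",
})

_UNIVARIATE = [
    # factor, correlation, p-value
    ("DAI", 0.061, 0.002),
    ("GENDER", 0.067, 8.317e-4),
    ("RPR", 0.091, 5.991e-6),
    ("JTR", 0.108, 0.001),
    ("YTR", 0.267, 1.354e-41),
    ("DRNBASE", 0.222, 4.496e-29),
    ("JG", 0.029, 0.001),
    ("YW", 0.030, 0.032),
    ("AL", 0.106, 1.546e-7),
    ("K1", 0.062, 0.002),
    ("K2", 0.043, 0.036),
    ("PULSE", 0.006, 0.008),
    ("TUTOR1", 0.282, 5.417e-42),
    ("TUTOR2", 0.203, 3.620e-22),
    ("ETEST", 0.344, 4.732e-63),
    ("MSMK", 0.397, 1.826e-82),
    ("CELLP", 0.229, 6.606e-28),
    ("COSTM", 0.092, 1.356e-5),
    ("BED", 0.261, 2.480e-36),
    ("COLA", 0.092, 1.330e-5),
    ("REDM", 0.037, 0.026),
    ("WHIM", 0.028, 0.044),
    ("EGG", 0.077, 2.285e-4),
    ("MILK", 0.077, 2.672e-4),
    ("VOLUME", 0.096, 4.681e-6),
]

_MULTIVARIATE = [
    # factor, coefficient, std err, t, p-value
    ("DAI", -0.0218, 0.033, -0.670, 0.042),
    ("GENDER", -0.0418, 0.047, -0.882, 0.015),
    ("RPR", -0.0160, 0.022, -0.735, 0.207),
    ("JTR", 0.0402, 0.060, 0.667, 0.005),
    ("YTR", 0.2077, 0.049, 4.245, 0.000),
    ("DRNBASE", -0.4191, 0.200, -2.099, 0.306),
    ("JG", -1.043, 1.13, -0.922, 0.035),
    ("YW", -0.0099, 0.014, -0.699, 0.048),
    ("AL", -0.0420, 0.073, -0.578, 0.003),
    ("K1", -0.2655, 0.578, -0.459, 0.046),
    ("K2", -0.2155, 0.495, -0.435, 0.036),
    ("PULSE", 0.0003, 0.002, 0.167, 0.008),
    ("TUTOR1", 0.0871, 0.047, 1.869, 0.062),
    ("TUTOR2", 0.0333, 0.044, 0.751, 0.453),
    ("ETEST", -0.0877, 0.043, -2.042, 0.401),
    ("MSMK", -0.3692, 0.266, -1.387, 0.166),
    ("CELLP", 0.0530, 0.047, 1.129, 0.259),
    ("COSTM", -0.0058, 0.028, -0.205, 0.838),
    ("BED", -0.0513, 0.031, -1.677, 0.094),
    ("COLA", 0.0041, 0.025, 0.163, 0.007),
    ("REDM", 0.0167, 0.022, 0.761, 0.044),
    ("WHIM", -0.0231, 0.027, -0.842, 0.040),
    ("EGG", -0.0054, 0.025, -0.214, 0.013),
    ("MILK", 0.0163, 0.031, 0.532, 0.595),
    ("VOLUME", -0.0041, 0.032, -0.130, 0.897),
]

_SWEEP = [
    # train share p, fitting goodness R2, absolute error rate r
    (0.9, 0.791, 0.165),
    (0.8, 0.789, 0.145),
    (0.7, 0.787, 0.178),
    (0.6, 0.755, 0.178),
    (0.5, 0.786, 0.178),
    (0.4, 0.776, 0.198),
    (0.3, 0.766, 0.202),
    (0.2, 0.743, 0.220),
    (0.1, 0.694, 0.258),
]

_BASELINES = [
    # method, accuracy, 10-fold CV, precision, sensitivity, f1, AUC, specificity
    ("SVM (study method)", 0.93, 0.92, 0.95, 0.94, 0.94, 0.98, 0.94),
    ("Logistic Regression", 0.89, 0.89, 0.82, 0.88, 0.85, 0.95, 0.88),
    ("Naive Bayes", 0.88, 0.84, 0.89, 0.92, 0.90, 0.93, 0.92),
    ("KNN", 0.60, 0.58, 0.66, 0.73, 0.69, 0.55, 0.73),
    ("Random Forest", 0.91, 0.90, 0.94, 0.91, 0.92, 0.97, 0.91),
    ("BP Neural Network", 0.92, 0.90, 0.95, 0.93, 0.94, 0.97, 0.93),
]


def univariate_screen_table() -> pd.DataFrame:
    return pd.DataFrame(_UNIVARIATE, columns=["factor", "correlation", "p_value"])


def multivariate_screen_table() -> pd.DataFrame:
    return pd.DataFrame(
        _MULTIVARIATE, columns=["factor", "coefficient", "std_err", "t_stat", "p_value"]
    )


def imputation_sweep_table() -> pd.DataFrame:
    return pd.DataFrame(_SWEEP, columns=["p", "R2", "r"])


def baseline_metrics_table() -> pd.DataFrame:
    return pd.DataFrame(
        _BASELINES,
        columns=["method", "accuracy", "cv10", "precision", "sensitivity",
                 "f1", "auc", "specificity"],
    )
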