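import numpy as np
import pytest

from myoscreen import (
    CohortConfig,
    apply_missingness,
    generate_cohort,
    strong_effect_sizes,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Complete 400-student cohort with strong planted effects."""
    cfg = CohortConfig(n_students=400, seed=11, effect_sizes=strong_effect_sizes())
    return generate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def small_incomplete_cohort(small_cohort):
    table, cfg = small_cohort
    return apply_missingness(table, cfg), cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
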