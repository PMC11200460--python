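import numpy as np
import pytest

from presympto.bands import DEFAULT_BANDS
from presympto.cohort import CohortConfig, generate_cohort
from presympto.features import assemble_observed_matrix, cohort_feature_table


SMALL_REGIONS = ("A", "B", "C", "D")


def small_config(**overrides) -> CohortConfig:
    """A four-region mini cohort: regions A and B carry a theta/delta effect."""
    defaults = dict(
        n_diseased=4,
        n_wild=3,
        regions=SMALL_REGIONS,
        informative_regions=("A", "B"),
        effect_sizes={r: {"delta": 4.0, "theta": 4.0} for r in ("A", "B")},
        sessions_per_mouse=1,
        session_duration=120.0,
        fs=256.0,
        missing_fraction=0.0,
        gain_jitter_sd=0.0,
        window_jitter_sd=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config(seed=42))


@pytest.fixture(scope="session")
def small_observed(small_cohort):
    table = cohort_feature_table(small_cohort)
    return assemble_observed_matrix(table, small_cohort.mask)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
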