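import pytest

from fpscope import default_registry, load_reference_summary
from fpscope.classify import build_profiles
from fpscope.simulate import default_simulation_config, simulate_cohort
from fpscope.stratify import REGION_ORDER, assign_strata


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def reference():
    return load_reference_summary()


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded 1,000-physician synthetic cohort (250 per stratum)."""
    cfg = default_simulation_config(
        seed=20170, n_physicians_by_region={r: 250 for r in REGION_ORDER}
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort_profiles(small_cohort, registry):
    profiles, count_result = build_profiles(
        small_cohort.claims, registry,
        [p.physician_id for p in small_cohort.physicians],
    )
    strata = assign_strata(small_cohort.physicians)
    return profiles, strata, count_result
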