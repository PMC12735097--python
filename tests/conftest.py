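import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from echinomet import (
    CohortConfig,
    bin_spectra,
    build_metabolite_library,
    normalize_total_area,
    simulate_cohort,
)

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    return build_metabolite_library()


@pytest.fixture(scope="session")
def default_cohort():
    """The default two-species cohort: 12 + 12 spectra, strong effects, seed 1."""
    return simulate_cohort(CohortConfig(seed=1))


@pytest.fixture(scope="session")
def fm_default(default_cohort):
    """Default cohort binned at 0.01 ppm and total-area normalized."""
    spectra, truth = default_cohort
    fm = bin_spectra(spectra, 0.01, labels=truth.labels)
    return normalize_total_area(fm)


@pytest.fixture(scope="session")
def small_cohort():
    """A cheap cohort for smoke-level checks (coarse axis, 5 + 5 samples)."""
    cfg = CohortConfig(n_per_class=5, ppm_axis=(0.0, 10.0, 4096), seed=7)
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def fm_small(small_cohort):
    spectra, truth = small_cohort
    return normalize_total_area(bin_spectra(spectra, 0.1, labels=truth.labels))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
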