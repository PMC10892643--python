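import numpy as np
import pytest

import linezopk as lz
from linezopk.nlme import FitConfig, PopEstimates


@pytest.fixture(scope="session")
def published():
    """Published population estimates, Omega repaired to PSD."""
    est, applied = lz.table3_estimates().repaired()
    assert applied  # the printed covariance implies |corr| > 1
    return est


@pytest.fixture(scope="session")
def q8h():
    return lz.DosingRegimen(dose=600.0, infusion_duration=0.5, interval=8.0)


@pytest.fixture(scope="session")
def q12h():
    return lz.DosingRegimen(dose=600.0, infusion_duration=0.5, interval=12.0)


@pytest.fixture(scope="session")
def typical():
    return lz.PKParams(clearance=5.9, volume=41.1)


@pytest.fixture(scope="session")
def init_estimates():
    return PopEstimates(5.0, 40.0, 0.3, 0.3, 0.0, 0.15)


@pytest.fixture(scope="session")
def fast_fit():
    return FitConfig(n_starts=1)


@pytest.fixture(scope="session")
def default_cohort():
    """One synthetic cohort of the study design at the published truth."""
    return lz.generate_cohort(lz.default_design(), lz.TruthSpec(seed=7))


@pytest.fixture(scope="session")
def big_sample(published):
    """5000 virtual patients from the published estimates."""
    return lz.sample_population(published, 5000, seed=12345)
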