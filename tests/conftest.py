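import numpy as np
import pytest
from hypothesis import settings

from ecstrace import TracerKineticParams
from ecstrace.cohort import GridSpec, default_times, render_image_series

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

BETA = 1e10        # signal units per mol/mm³
BASELINE = 100.0


@pytest.fixture(scope="session")
def pd_params() -> TracerKineticParams:
    """PD-group mean kinetics: the sharpest clearance contrast in the study."""
    return TracerKineticParams(d_eff=2.744e-4, k_clear=2.153e-4)


@pytest.fixture(scope="session")
def control_params() -> TracerKineticParams:
    return TracerKineticParams(d_eff=2.023e-4, k_clear=0.854e-4)


@pytest.fixture(scope="session")
def grid() -> GridSpec:
    return GridSpec()


@pytest.fixture(scope="session")
def times() -> np.ndarray:
    return default_times()


@pytest.fixture(scope="session")
def pd_series_clean(pd_params, grid, times):
    """Noise-free rendered series of the PD-mean animal (shared, read-only)."""
    return render_image_series(
        pd_params, grid, times, beta=BETA, baseline=BASELINE, noise_sd=0.0
    )


@pytest.fixture(scope="session")
def pd_noise_sd(pd_series_clean):
    """2% of the noise-free peak enhancement, in signal units."""
    return 0.02 * float((pd_series_clean.volumes - BASELINE).max())
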