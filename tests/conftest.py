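import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from metaflim import BiexpParams, TimeGrid, make_gaussian_irf

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

# standard two-photon TCSPC configuration: 80 MHz excitation, 12.5 ns
# window, 256 time bins
N_BINS = 256
REP_RATE = 80e6
BIN_WIDTH = (1.0 / REP_RATE) / N_BINS


@pytest.fixture(scope="session")
def grid() -> TimeGrid:
    return TimeGrid(N_BINS, BIN_WIDTH, REP_RATE)


@pytest.fixture(scope="session")
def irf(grid):
    """150 ps FWHM Gaussian IRF centered at 1 ns."""
    return make_gaussian_irf(grid, fwhm=150e-12, center=1.0e-9)


@pytest.fixture(scope="session")
def cellular_params() -> BiexpParams:
    """Typical in-vitro NAD(P)H decay (mean fitted values of the worked image)."""
    return BiexpParams(tau1=0.54e-9, tau2=2.81e-9, alpha1=2640.0, alpha2=1180.0)


def biexp_with_intensity_fraction(f2: float, tau1: float = 0.5e-9, tau2: float = 3.0e-9) -> BiexpParams:
    """Parameters whose bound intensity fraction is exactly f2."""
    alpha2 = f2 * tau1 / ((1.0 - f2) * tau2)
    return BiexpParams(tau1=tau1, tau2=tau2, alpha1=1.0, alpha2=alpha2)
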