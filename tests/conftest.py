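import pytest

from tdnirs import (
    BaselineState,
    IRFModel,
    TimeGrid,
    TwoLayerScenario,
    simulate_dtof_pair,
    synth_irf,
)

#: the standard TCSPC grid: 1024 channels of 12.22 ps
STANDARD_GRID = TimeGrid(bin_width=12.22, n_bins=1024)


@pytest.fixture(scope="session")
def grid():
    return STANDARD_GRID


@pytest.fixture(scope="session")
def irf(grid):
    """Deterministic synthetic IRF (Gaussian + 1% after-pulse at +1 ns)."""
    return synth_irf(IRFModel(), grid)


@pytest.fixture(scope="session")
def fig3_scenario(grid, irf):
    """Deep-layer step scenario: both layers mua = 0.1 cm^-1,
    musp = 10 cm^-1, L = 15 mm, n = 1.33, rho = 30 mm; truth
    dmua_sup = 0, dmua_deep = 0.05 cm^-1."""
    baseline = BaselineState(
        mua_sup=0.01, mua_deep=0.01, musp_sup=1.0, musp_deep=1.0,
        L=15.0, n=1.33, rho=30.0,
    )
    return TwoLayerScenario(
        baseline=baseline, dmua_sup=0.0, dmua_deep=0.005, irf=irf, grid=grid
    )


@pytest.fixture(scope="session")
def fig3_dtof_pair(fig3_scenario):
    return simulate_dtof_pair(fig3_scenario, ntot_baseline=5e6)
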