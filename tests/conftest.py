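import numpy as np
import pytest

from memperm import (
    GaussianTerm,
    LandscapeSpec,
    ThermoState,
    run_langevin_window,
    simulate_campaign,
)


@pytest.fixture(scope="session")
def thermo():
    return ThermoState(temperature=303.0)


@pytest.fixture(scope="session")
def flat_landscape():
    """W = 0 everywhere, constant D = 0.01 Å²/ps."""
    return LandscapeSpec(w_terms=(), d_terms=(), w_baseline=0.0, d_baseline=0.01)


@pytest.fixture(scope="session")
def ou_window(flat_landscape, thermo):
    """A long harmonically restrained window on flat W: an OU process with
    D = 0.01 Å²/ps, k = 2.5 kcal/(mol Å²) — closed-form variance and ACF."""
    return run_langevin_window(
        flat_landscape, thermo, center=0.0, force_constant=2.5,
        n_steps=1_000_000, dt=0.05, seed=42,
    )


@pytest.fixture(scope="session")
def well_landscape():
    """Single Gaussian well, constant D — a minimal recovery target."""
    return LandscapeSpec(
        w_terms=(GaussianTerm(-3.0, 4.0, 3.0),),
        d_terms=(),
        d_baseline=0.02,
        z_range=(-10.0, 20.0),
    )


@pytest.fixture(scope="session")
def well_campaign(well_landscape, thermo):
    """Nine windows across the single-Gaussian well; enough sampling for a
    sub-0.2 kcal/mol recovery without dominating the suite's runtime."""
    return simulate_campaign(
        well_landscape, thermo, n_windows=9, spacing=1.0, force_constant=2.5,
        n_steps=200_000, dt=0.05, seed=7, origin=0.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
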