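"""Shared fixtures: small grids, imaging schedules, synthetic designs."""

import numpy as np
import pandas as pd
import pytest

from chemofit import ModelParams, SpatialGrid, StudyDesign, simulate


@pytest.fixture(scope="session")
def control():
    """Control-condition ground truth (no target-induced cytokine release)."""
    from chemofit import control_params
    return control_params()


@pytest.fixture(scope="session")
def toxic():
    from chemofit import toxic_params
    return toxic_params()


@pytest.fixture(scope="session")
def imaging_times():
    """The study's imaging schedule: every 2 h out to 48 h."""
    return np.arange(0.0, 48.1, 2.0)


@pytest.fixture(scope="session")
def control_solution(control, imaging_times):
    """Reference control simulation on the default grid (shared: ~0.1 s)."""
    grid = SpatialGrid.for_params(control, 200)
    return simulate(control, grid, imaging_times)


@pytest.fixture(scope="session")
def generic_params():
    """A smooth parameter set with active degradation, for solver tests."""
    return ModelParams(
        D_rho_bar=0.01, D_alpha_bar=0.05, chi_bar=0.6, mu_rho=4.0,
        mu_alpha=4.0, xi=0.05, eta1=0.2, eta2=0.0, kappa=1e-4, nu=0.2,
        k=1.0, zeta=0.7, rho_tilde=50.0, x_t=0.5)


@pytest.fixture()
def particle_table():
    """A tiny hand-written particle table covering both conditions."""
    return pd.DataFrame({
        "experiment_id": ["e1"] * 5 + ["e2"] * 3,
        "condition": ["DP47"] * 5 + ["D66-ESK"] * 3,
        "time_h": [48.0] * 8,
        "x_um": [100.0, 100.0, 100.0, 30.0, 600.0, 200.0, 210.0, 340.0],
        "area_um2": [40.0, 40.0, 40.0, 120.0, 40.0, 40.0, 80.0, 130.0],
    })


@pytest.fixture(scope="session")
def small_design():
    """Scaled-down study design for fast synthetic-data tests."""
    return StudyDesign(n_control=2, n_toxic=2, horizon_h=24.0, n_cells=100,
                       seed=7)
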