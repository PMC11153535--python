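"""Shared fixtures.

The coupled flushing + scan experiments are expensive, so they run once per
session on the reduced desk grid (32 radial x 200 axial cells) and are
shared between the solver tests and the acceptance checks.
"""

from __future__ import annotations

import numpy as np
import pytest

import ivoct
from ivoct.fixtures import run_scheme
from ivoct.flush import (
    annular_poiseuille_velocity,
    annular_poiseuille_wall_shear,
    solve_flushing,
)
from ivoct.schedules import FlowWaveform

DESK_NR = 32
DESK_NZ = 200


@pytest.fixture(scope="session")
def base_config() -> ivoct.Config:
    cfg = ivoct.Config()
    cfg.validate()
    return cfg


@pytest.fixture(scope="session")
def continuous_run(base_config):
    """Coupled flush + scan for the default continuous scheme."""
    schemes = ivoct.default_schemes(base_config)
    return run_scheme(
        base_config,
        schemes["continuous"],
        fidelity="laminar_eddy",
        nr=DESK_NR,
        nz=DESK_NZ,
    )


@pytest.fixture(scope="session")
def intermittent_run(base_config):
    """Coupled flush + scan for the default intermittent scheme."""
    schemes = ivoct.default_schemes(base_config)
    return run_scheme(
        base_config,
        schemes["intermittent"],
        fidelity="laminar_eddy",
        nr=DESK_NR,
        nz=DESK_NZ,
    )


def _poiseuille_case(config, nr, nz, flow_ml_s=1.1, t_end=4.0):
    """Steady annular through-flow, laminar fidelity; returns error metrics."""
    steady = FlowWaveform(np.array([0.0, 100.0]), np.array([flow_ml_s, flow_ml_s]))
    res = solve_flushing(
        config,
        blood_waveform=steady,
        injection_waveform=None,
        fidelity="laminar",
        nr=nr,
        nz=nz,
        t_end=t_end,
        initial_haematocrit=config.constants.whole_blood_haematocrit,
    )
    g = res.grid
    j = int(np.argmin(np.abs(g.z_c - 0.070)))  # fully developed station
    w_num = 0.5 * (res.final_state.w[:, j] + res.final_state.w[:, j + 1])
    mu = ivoct.mixture_viscosity(
        config.constants.whole_blood_haematocrit, config.constants.plasma_viscosity
    )
    w_ref = annular_poiseuille_velocity(
        g.r_c, g.r_in, g.r_out, flow_ml_s * 1e-6, mu
    )
    vel_err = float(np.linalg.norm(w_num - w_ref) / np.linalg.norm(w_ref))
    tau_ref = annular_poiseuille_wall_shear(g.r_in, g.r_out, flow_ml_s * 1e-6, mu)
    tau_num = float(res.wall_shear[-1, j])
    shear_err = abs(abs(tau_num) - tau_ref) / tau_ref
    return {"velocity_l2": vel_err, "wall_shear_rel": shear_err, "result": res}


@pytest.fixture(scope="session")
def poiseuille_fine(base_config):
    return _poiseuille_case(base_config, nr=DESK_NR, nz=160)


@pytest.fixture(scope="session")
def poiseuille_coarse(base_config):
    return _poiseuille_case(base_config, nr=DESK_NR // 2, nz=80)
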