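"""Shared fixtures: materials, programs and session-scoped reference runs.

The heavier simulations (130-h programs at default resolution, long
isothermal runs used by the estimation pipeline) are session-scoped so that
several tests can interrogate a single trajectory.
"""

import time

import numpy as np
import pytest

import drysphere as ds

STARTUP = ds.AmbientConditions(T_inf=288.15, RH_inf=0.80, U_inf=0.1)
PRINTED_ARRHENIUS = ds.ArrheniusLaw(D0=4.00012e-5, E_over_Rg=-3872.63)


@pytest.fixture(scope="session")
def pear_c50():
    """Material of the continuous 50 degC experiment (X0=5.55, d0=5.24 cm)."""
    return ds.MaterialParams(X0=5.55, d0=0.0524)


@pytest.fixture(scope="session")
def program_c50():
    """Continuous convective drying at 50 degC, 130 h, with switch-on ramp."""
    return ds.CycleProgram(
        stages=(ds.Stage(130.0, 323.15, 0.15, 1.28, "C"),),
        startup=STARTUP,
    )


@pytest.fixture(scope="session")
def run_c50_full(pear_c50, program_c50):
    """Full non-isothermal continuous run at default resolution."""
    return ds.simulate(pear_c50, program_c50, ds.SolverSettings(variant="full"))


@pytest.fixture(scope="session")
def run_c50_lumped(pear_c50, program_c50):
    return ds.simulate(pear_c50, program_c50, ds.SolverSettings(variant="lumped"))


@pytest.fixture(scope="session")
def run_i40_5cyc():
    """130-h intermittent run (5 cycles at 40 degC + trailing convective
    stage) at default resolution, with its wall-clock time attached."""
    params = ds.MaterialParams(X0=5.37, d0=0.0530)
    program = ds.CycleProgram(
        stages=tuple(ds.standard_cycle(313.15, 1.28)),
        n_cycles=5,
        startup=STARTUP,
        extra_stages=(ds.Stage(10.0, 313.15, 0.15, 1.28, "C"),),
    )
    t0 = time.perf_counter()
    traj = ds.simulate(params, program, ds.SolverSettings(variant="full"))
    traj.wall_seconds = time.perf_counter() - t0
    return traj


def _rigid_isothermal_run(T, t_end_h):
    """Rigid-sphere isothermal drying to near-equilibrium (the regime the
    asymptotic-slope diffusivity estimate assumes)."""
    params = ds.MaterialParams(X0=5.64, d0=0.0530, alpha0=0.0,
                               diffusivity=PRINTED_ARRHENIUS)
    program = ds.CycleProgram(stages=(ds.Stage(t_end_h, T, 0.15, 1.28, "C"),))
    return ds.simulate(params, program, ds.SolverSettings(variant="isothermal"))


@pytest.fixture(scope="session")
def run_rigid_iso_40():
    return _rigid_isothermal_run(313.15, 700.0)


@pytest.fixture(scope="session")
def run_rigid_iso_50():
    return _rigid_isothermal_run(323.15, 500.0)
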