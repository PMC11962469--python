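"""Shared fixtures: a small fast chamber scene and the baseline chamber.

The *small scene* (24 flagella) keeps solver-level unit tests around a
second each; the *baseline* fixtures build the reference chamber (rho=1.5,
N=143, theta_a=30 deg, k*ell=3pi) once per session and are shared between
the physics unit tests and the acceptance tests.
"""

import numpy as np
import pytest

from choanopump.geometry import ChamberSpec, build_chamber_mesh, place_flagella
from choanopump.kinematics import WaveformParams
from choanopump.pipeline import simulate_period
from choanopump.stokes import ChamberSolver

BASELINE_SPEC = dict(subdivisions=2, reticulum_subdivisions=2, cone_segments=24)


@pytest.fixture(scope="session")
def small_scene():
    spec = ChamberSpec(
        n_flagella=24, subdivisions=2, reticulum_subdivisions=1, cone_segments=12
    )
    mesh = build_chamber_mesh(spec)
    layout = place_flagella(spec, seed=0)
    waveform = WaveformParams(n_nodes=8)
    solver = ChamberSolver(mesh, layout, waveform)
    return spec, mesh, layout, waveform, solver


@pytest.fixture(scope="session")
def small_solution(small_scene):
    *_, solver = small_scene
    return solver.solve(t=0.0)


@pytest.fixture(scope="session")
def baseline_scene():
    spec = ChamberSpec(**BASELINE_SPEC)
    mesh = build_chamber_mesh(spec)
    layout = place_flagella(spec, seed=0)
    waveform = WaveformParams(n_nodes=10)
    solver = ChamberSolver(mesh, layout, waveform)
    return spec, mesh, layout, waveform, solver


@pytest.fixture(scope="session")
def baseline_solution(baseline_scene):
    *_, solver = baseline_scene
    return solver.solve(t=0.0)


@pytest.fixture(scope="session")
def baseline_metrics(baseline_scene):
    """Period-averaged baseline pump metrics (10 uniform beat phases)."""
    spec, _, _, waveform, _ = baseline_scene
    return simulate_period(spec, waveform, seed=0, n_steps=10, pressure_spacing=0.1)
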