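"""Pump metrics: fluxes, pressures, work rate, efficiency, dP response."""

import numpy as np
import pandas as pd
import pytest

from choanopump.metrics import (
    PumpMetrics,
    delta_p_response,
    efficiency,
    max_pressure,
    outlet_flow_rate,
    pressure_grid,
    shifted_operating_point,
    time_ensemble_average,
    work_rate,
)
from choanopump.stokes import StokesSolution


def _zero_solution(mesh):
    pts = mesh.centroids[mesh.noslip_mask]
    n = len(pts)
    return StokesSolution(
        points=pts,
        forces=np.zeros((n, 3)),
        eps=np.full(n, 0.1),
        weights=np.ones(n),
        kind=np.full(n, -1),
        velocities=np.zeros((n, 3)),
    )


class TestOutletFlowRate:
    def test_zero_solution_pumps_nothing(self, small_scene):
        _, mesh, *_ = small_scene
        assert outlet_flow_rate(_zero_solution(mesh), mesh) == 0.0

    def test_positive_for_beating_chamber(self, baseline_scene, baseline_solution):
        # a well-covered chamber pumps outward at every beat phase; sparse
        # chambers may momentarily backflow, so the reference scene is used
        _, mesh, *_ = baseline_scene
        assert outlet_flow_rate(baseline_solution, mesh) > 0.0

    def test_outflow_balanced_by_wall_side_influx(self, baseline_scene, baseline_solution):
        """Apopyle outflow closes against the inward flux through the rest
        of the sphere (prosopyle holes plus residual inter-collocation wall
        flux), to sub-triangle quadrature accuracy."""
        spec, mesh, *_ = baseline_scene
        sol = baseline_solution
        Q = outlet_flow_rate(sol, mesh)
        holes = mesh.prosopyle_centers
        nrm = holes / np.linalg.norm(holes, axis=1, keepdims=True)
        u = sol.velocity(holes, check=False)
        influx = np.sum(np.einsum("ij,ij->i", u, nrm)) * mesh.prosopyle_area / len(holes)
        wallmask = mesh.region_mask("wall")
        tri = mesh.vertices[mesh.triangles[wallmask]]
        a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
        for sub in (
            (a + (a + b) / 2 + (a + c) / 2) / 3,
            ((a + b) / 2 + b + (b + c) / 2) / 3,
            ((a + c) / 2 + (b + c) / 2 + c) / 3,
            ((a + b) / 2 + (b + c) / 2 + (a + c) / 2) / 3,
        ):
            uw = sol.velocity(sub, check=False)
            influx += np.sum(
                np.einsum("ij,ij->i", uw, mesh.normals[wallmask]) * mesh.areas[wallmask] / 4
            )
        assert influx < 0  # net inflow on the wall side
        assert Q == pytest.approx(-influx, rel=0.2)


class TestPressure:
    def test_zero_solution_zero_pressure(self, small_scene):
        _, mesh, *_ = small_scene
        grid = pressure_grid(1.5, spacing=0.3)
        pc, pmax = max_pressure(_zero_solution(mesh), grid)
        assert pc == 0.0 and pmax == 0.0

    def test_core_pressurized(self, small_solution):
        grid = pressure_grid(1.5, spacing=0.15)
        pc, pmax = max_pressure(small_solution, grid)
        assert pmax >= pc
        assert pmax > 0

    def test_empty_sampling_rejected(self, small_solution):
        with pytest.raises(ValueError, match="sampling"):
            max_pressure(small_solution, np.zeros((0, 3)))


class TestWorkRate:
    def test_positive_dissipation(self, small_solution):
        assert work_rate(small_solution) > 0.0

    def test_drive_concentrated_near_tips(self, baseline_solution):
        """u.(-f) along the filament peaks in the distal third."""
        sol = baseline_solution
        mask = sol.flagella_mask
        power = np.einsum("ij,ij->i", sol.velocities[mask], sol.forces[mask])
        per_node = power.reshape(-1, 10).mean(axis=0)  # mean over flagella
        assert np.argmax(per_node) >= 7

    def test_quadratic_scaling_with_beat_speed(self, small_scene):
        """Q and P scale linearly with the boundary speed, W quadratically."""
        from choanopump.kinematics import states_for_layout

        spec, mesh, layout, waveform, solver = small_scene
        state = states_for_layout(layout, waveform, 0.0)
        grid = pressure_grid(spec.radius, spacing=0.2 * spec.radius)
        results = []
        for c in (1.0, 2.0):
            scaled = type(state)(state.positions, c * state.velocities, state.t, state.arc_weights)
            sol = solver.solve(t=0.0, state=scaled)
            results.append(
                (outlet_flow_rate(sol, mesh), max_pressure(sol, grid)[1], work_rate(sol))
            )
        (q1, p1, w1), (q2, p2, w2) = results
        assert q2 == pytest.approx(2 * q1, rel=1e-8)
        assert p2 == pytest.approx(2 * p1, rel=1e-8)
        assert w2 == pytest.approx(4 * w1, rel=1e-8)


class TestEfficiency:
    def test_no_flow_means_no_efficiency(self):
        assert efficiency(0.0, 1.0, 5.0) == 0.0

    def test_zero_work_rejected(self):
        with pytest.raises(ValueError, match="work"):
            efficiency(1.0, 1.0, 0.0)

    def test_invariant_under_time_unit_rescaling(self):
        # Q ~ 1/T, P ~ 1/T, W ~ 1/T^2: eta is dimensionless
        c = 3.7
        assert efficiency(0.07 * c, 4.7 * c, 300.0 * c**2) == pytest.approx(
            efficiency(0.07, 4.7, 300.0)
        )


class TestDeltaP:
    def test_zero_shift_identity(self):
        Qp, Pp, eta_p = shifted_operating_point(0.07, 4.7, 300.0, -0.01, 0.5, 0.0)
        assert (Qp, Pp) == (0.07, 4.7)
        assert eta_p == efficiency(0.07, 4.7, 300.0)

    def test_adverse_pressure_reduces_output(self, small_scene):
        spec, mesh, _, _, solver = small_scene
        C1, C2 = delta_p_response(solver, mesh)
        assert C1 < 0  # adverse pressure difference drives a return flow
        assert C2 > 0  # and pressurises the chamber interior

    def test_response_linear_in_dp(self):
        Q0, P0, W = 0.07, 4.7, 300.0
        C1, C2 = -0.012, 0.4
        Q1, P1, _ = shifted_operating_point(Q0, P0, W, C1, C2, 1.0)
        Q2, P2, _ = shifted_operating_point(Q0, P0, W, C1, C2, 2.0)
        assert Q1 - Q0 == pytest.approx(0.5 * (Q2 - Q0))
        assert P1 - P0 == pytest.approx(0.5 * (P2 - P0))


class TestAveraging:
    @staticmethod
    def _pm(rng, seed=0):
        n = 10
        return PumpMetrics(
            times=np.arange(n) / n,
            Q=0.07 + 0.005 * rng.standard_normal(n),
            Pc=3.0 + 0.1 * rng.standard_normal(n),
            Pmax=4.7 + 0.1 * rng.standard_normal(n),
            W=300.0 + rng.standard_normal(n),
            seed=seed,
        )

    def test_constant_series_average(self):
        n = 10
        pm = PumpMetrics(np.arange(n) / n, np.full(n, 0.07), np.full(n, 3.0), np.full(n, 4.7), np.full(n, 300.0))
        assert pm.Q_bar == pytest.approx(0.07) and pm.W_bar == pytest.approx(300.0)
        assert pm.eta == pytest.approx(0.07 * 4.7 / 300.0)

    def test_ensemble_table(self):
        rng = np.random.default_rng(0)
        runs = [self._pm(rng, seed=s) for s in range(3)]
        out = time_ensemble_average(runs)
        assert out["n_seeds"].iloc[0] == 3
        assert out["Q_bar"].iloc[0] == pytest.approx(np.mean([r.Q_bar for r in runs]))
        assert out["Q_bar_sd"].iloc[0] > 0

    def test_ensemble_mean_converges_with_seeds(self):
        """Monte-Carlo check: more seeds pull the mean toward the truth."""
        rng = np.random.default_rng(1)
        runs = [self._pm(rng, seed=s) for s in range(64)]
        few = time_ensemble_average(runs[:4])["Q_bar"].iloc[0]
        many = time_ensemble_average(runs)["Q_bar"].iloc[0]
        errs_few = [
            abs(time_ensemble_average(runs[i : i + 4])["Q_bar"].iloc[0] - 0.07)
            for i in range(0, 64, 4)
        ]
        assert abs(many - 0.07) < np.mean(errs_few)

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError, match="runs"):
            time_ensemble_average([])
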