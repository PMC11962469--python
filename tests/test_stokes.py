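"""Regularized-Stokeslet solver: kernel oracles, drag, conservation laws."""

import numpy as np
import pytest
import trimesh

from choanopump.kinematics import WaveformParams
from choanopump.stokes import (
    ResistanceSolver,
    _pair_eps,
    assemble_matrix,
    blake_velocity,
    solve_wall_flagellum,
    stokeslet_pressure,
    stokeslet_velocity,
    wall_attached_flux,
)


class TestKernelOracles:
    def test_velocity_matches_free_space_stokeslet(self):
        rng = np.random.default_rng(0)
        src = rng.normal(size=(1, 3))
        F = rng.normal(size=(1, 3))
        pts = src + rng.normal(size=(5, 3)) * 2.0
        u = stokeslet_velocity(pts, src, F, 1e-8)
        for p, ui in zip(pts, u):
            r = p - src[0]
            rn = np.linalg.norm(r)
            exact = (F[0] / rn + r * (F[0] @ r) / rn**3) / (8 * np.pi)
            assert np.abs(ui - exact).max() < 1e-6

    def test_pressure_matches_closed_form(self):
        # unit force along z, evaluated on its axis: p = 1/(16 pi) at r=2
        p = stokeslet_pressure(np.array([[0.0, 0.0, 2.0]]), np.zeros((1, 3)), np.array([[0.0, 0.0, 1.0]]), 1e-9)
        assert p[0] == pytest.approx(1.0 / (16 * np.pi), rel=1e-9)

    def test_linearity_in_forces(self):
        rng = np.random.default_rng(1)
        src, F = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        pts = rng.normal(size=(6, 3)) * 3.0
        u1 = stokeslet_velocity(pts, src, F, 0.1)
        u2 = stokeslet_velocity(pts, src, 2.0 * F, 0.1)
        assert np.allclose(u2, 2.0 * u1, atol=1e-14)

    def test_pressure_harmonic_away_from_forces(self):
        src = np.zeros((1, 3))
        F = np.array([[0.3, -0.2, 1.0]])
        x0 = np.array([0.5, 0.3, 0.9])
        h = 1e-3
        sten = [x0] + [x0 + s * h * e for e in np.eye(3) for s in (1, -1)]
        p = stokeslet_pressure(np.array(sten), src, F, 0.05)
        lap = (p[1:].sum() - 6 * p[0]) / h**2
        assert abs(lap) / (abs(p[0]) / np.linalg.norm(x0) ** 2) < 1e-3

    def test_evaluation_atop_a_node_rejected(self, small_solution):
        with pytest.raises(ValueError, match="coincides"):
            small_solution.velocity(small_solution.points[7])


class TestResistanceProblem:
    def test_mobility_matrix_symmetric(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(size=(15, 3))
        eps = rng.uniform(0.05, 0.2, 15)
        A = assemble_matrix(pts, pts, _pair_eps(eps, eps))
        assert np.abs(A - A.T).max() / np.abs(A).max() < 1e-6

    def test_immotile_flagella_carry_no_force(self, small_scene):
        *_, solver = small_scene
        sol = solver.solve(t=0.0, freeze=True)
        assert np.abs(sol.forces).max() < 1e-10

    def test_translating_sphere_drag(self):
        ico = trimesh.creation.icosphere(subdivisions=2, radius=1.0)
        m = trimesh.Trimesh(ico.vertices, ico.faces, process=False)
        tri = np.asarray(m.vertices)[np.asarray(m.faces)]
        edge = np.linalg.norm(
            np.stack([tri[:, 0] - tri[:, 1], tri[:, 1] - tri[:, 2], tri[:, 2] - tri[:, 0]]),
            axis=-1,
        ).mean(axis=0)
        rs = ResistanceSolver(m.triangles_center, 0.5 * edge, surface_weights=m.area_faces)
        U = np.tile([1.0, 0.0, 0.0], (len(m.faces), 1))
        sol = rs.solve(np.zeros((0, 3)), np.array([]), np.zeros((0, 3)), rhs_surface=U)
        drag = sol.forces.sum(axis=0)[0]
        assert drag == pytest.approx(6 * np.pi, rel=0.03)

    def test_boundary_condition_residual(self, small_solution):
        sol = small_solution
        A = assemble_matrix(sol.points, sol.points, _pair_eps(sol.eps, sol.eps))
        u = (A @ sol.forces.reshape(-1)).reshape(-1, 3)
        resid = np.abs(u - sol.velocities).max()
        assert resid < 1e-6 * max(1.0, np.abs(sol.velocities).max())

    def test_global_force_balance(self, baseline_solution):
        assert baseline_solution.force_balance_error() < 0.02

    def test_singular_system_reported(self):
        pts = np.zeros((2, 3))  # coincident points, identical rows
        rs = ResistanceSolver(np.zeros((0, 3)), np.array([]))
        with pytest.raises(np.linalg.LinAlgError):
            rs.solve(pts, 0.1, np.ones((2, 3)))


class TestFieldProperties:
    def test_far_field_decays_at_least_like_inverse_distance(self, baseline_solution):
        sol = baseline_solution
        radii = np.geomspace(7.5, 75.0, 6)  # 5R to 50R
        dirs = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]]) / np.array([1, 1, 1, np.sqrt(3)])[:, None]
        mags = []
        for r in radii:
            u = sol.velocity(r * dirs, check=False)
            mags.append(np.linalg.norm(u, axis=1).mean())
        slope = np.polyfit(np.log(radii), np.log(mags), 1)[0]
        assert slope <= -1.0

    def test_mass_conservation_through_enclosing_sphere(self, baseline_scene, baseline_solution):
        spec, mesh, *_ = baseline_scene
        from choanopump.metrics import outlet_flow_rate

        Q = outlet_flow_rate(baseline_solution, mesh)
        s = trimesh.creation.icosphere(subdivisions=3, radius=2 * spec.radius)
        sm = trimesh.Trimesh(s.vertices, s.faces, process=False)
        cen = sm.triangles_center
        nrm = cen / np.linalg.norm(cen, axis=1, keepdims=True)
        u = baseline_solution.velocity(cen, check=False)
        flux = np.sum(np.einsum("ij,ij->i", u, nrm) * sm.area_faces)
        assert abs(flux) < 0.01 * abs(Q)


class TestConvergenceAndExport:
    def test_outlet_flow_stable_under_wall_refinement(self, baseline_metrics):
        """Doubling the wall mesh moves the period-averaged outlet flow by
        about 10% (the discretization uncertainty of the filament
        representation dominates; see docs/methods.md)."""
        from choanopump.geometry import ChamberSpec
        from choanopump.kinematics import WaveformParams
        from choanopump.pipeline import simulate_period

        fine_spec = ChamberSpec(subdivisions=3, reticulum_subdivisions=2, cone_segments=24)
        fine = simulate_period(
            fine_spec, WaveformParams(n_nodes=10), seed=0, n_steps=10, pressure_spacing=0.1
        )
        assert fine.Q_bar == pytest.approx(baseline_metrics.Q_bar, rel=0.15)

    def test_field_slice_export(self, small_solution, tmp_path):
        from choanopump.stokes import export_field_slice_vtk

        path = tmp_path / "slice.vtk"
        export_field_slice_vtk(small_solution, path, half_width=3.0, spacing=0.5)
        lines = path.read_text().splitlines()
        assert lines[3] == "DATASET STRUCTURED_POINTS"
        assert "VECTORS velocity" in "\n".join(lines[:10])
        assert any(line.startswith("SCALARS pressure") for line in lines)


class TestHalfSpace:
    def test_no_slip_plane_exact_for_point_forces(self):
        rng = np.random.default_rng(3)
        src = rng.uniform(0.3, 1.5, (4, 3))
        F = rng.normal(size=(4, 3))
        wall = np.column_stack([rng.uniform(-3, 3, (25, 2)), np.zeros(25)])
        u = blake_velocity(wall, src, F, 1e-10)
        assert np.abs(u).max() < 1e-8

    def test_image_system_cancels_far_field(self):
        src = np.array([[0.0, 0.0, 0.5]])
        F = np.array([[1.0, 0.0, 0.0]])
        far = np.array([[60.0, 10.0, 30.0]])
        u_free = stokeslet_velocity(far, src, F, 1e-10)
        u_wall = blake_velocity(far, src, F, 1e-10)
        assert np.linalg.norm(u_wall) < 0.1 * np.linalg.norm(u_free)

    def test_wall_flagellum_slip_small(self):
        # finite-size blobs near their own images leave O(eps^2/h^2) slip
        # right at the base; away from it the wall must be almost exactly
        # no-slip
        sol = solve_wall_flagellum(WaveformParams(), 0.13)
        rng = np.random.default_rng(4)
        az = rng.uniform(0, 2 * np.pi, 20)
        rad = rng.uniform(0.5, 2.5, 20)
        wall = np.column_stack([rad * np.cos(az), rad * np.sin(az), np.zeros(20)])
        u = sol.velocity(wall, check=False)
        assert np.abs(u).max() < 1e-2 * np.abs(sol.velocities).max()

    def test_outgoing_flux_positive_and_order_correct(self):
        flux, per_plane, _ = wall_attached_flux(WaveformParams(n_nodes=10), n_steps=10)
        assert flux > 0
        assert (per_plane >= 0).all()
        assert 1e-3 < flux < 0.1  # order of magnitude of the wall-attached pump
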