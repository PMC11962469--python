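"""Zero-Reynolds-number resistance solver by the method of regularized Stokeslets.

The chamber surfaces (wall, reticulum, cone) and the flagellar centrelines
are represented by collocation points carrying unknown point forces smoothed
over a regularization length ``eps``: surface triangles contribute one point
at the centroid (eps tied to the local element size), flagellar nodes one
point each (eps tied to the node spacing, playing the role of the filament
radius in slender-body theory).  Prescribing zero velocity on the surfaces
and the beat velocities on the nodes gives a dense linear system

    u(x_i) = sum_j G_eps(x_i - x_j) F_j,

whose kernel is the Cortez-Fauci-Medovikov regularized Stokeslet

    8 pi mu u_i = F_j [ delta_ij (r^2 + 2 eps^2) + r_i r_j ] / (r^2+eps^2)^{3/2},

with the matching pressure kernel

    8 pi p = (F . r) (2 r^2 + 5 eps^2) / (r^2 + eps^2)^{5/2}.

Pairs use the mean of the two regularization lengths, which keeps the grand
mobility matrix exactly symmetric.  The resulting velocity field is
divergence-free everywhere, so volume fluxes through closed surfaces vanish
to quadrature accuracy.  For a flagellum attached to a plane no-slip wall
the image system of Blake (Stokeslet image, potential dipole and Stokeslet
doublet at the mirror point) replaces meshing the wall.

Everything is in model units: lengths in L, time in beat periods T, and
viscosity mu = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve, solve

__all__ = [
    "StokesSolution",
    "ResistanceSolver",
    "ChamberSolver",
    "stokeslet_velocity",
    "stokeslet_pressure",
    "blake_velocity",
    "assemble_matrix",
    "assemble_blake_matrix",
    "solve_wall_flagellum",
    "wall_attached_flux",
    "write_structured_vtk",
    "export_field_slice_vtk",
]

_CHUNK = 512


def _pair_eps(eps_t, eps_s):
    return 0.5 * (np.asarray(eps_t)[:, None] + np.asarray(eps_s)[None, :])


def assemble_matrix(targets, sources, eps_pair, mu=1.0, out=None):
    """Dense (3T, 3S) regularized-Stokeslet matrix with pairwise eps."""
    targets = np.asarray(targets, float)
    sources = np.asarray(sources, float)
    T, S = len(targets), len(sources)
    if out is None:
        out = np.empty((T, 3, S, 3))
    eye = np.eye(3)
    for lo in range(0, T, _CHUNK):
        hi = min(lo + _CHUNK, T)
        dx = targets[lo:hi, None, :] - sources[None, :, :]
        r2 = np.einsum("tsk,tsk->ts", dx, dx)
        e2 = eps_pair[lo:hi] ** 2
        denom = (r2 + e2) ** 1.5
        f1 = (r2 + 2.0 * e2) / denom
        f2 = 1.0 / denom
        out[lo:hi] = f1[:, None, :, None] * eye[None, :, None, :]
        out[lo:hi] += np.einsum("ts,tsi,tsj->tisj", f2, dx, dx)
    out *= 1.0 / (8.0 * np.pi * mu)
    return out.reshape(3 * T, 3 * S)


def stokeslet_velocity(targets, sources, forces, eps, mu=1.0):
    """Velocity at ``targets`` from regularized point forces at ``sources``.

    ``eps`` is a scalar or per-source array of regularization lengths.
    """
    targets = np.atleast_2d(np.asarray(targets, float))
    sources = np.atleast_2d(np.asarray(sources, float))
    forces = np.atleast_2d(np.asarray(forces, float))
    eps = np.broadcast_to(np.asarray(eps, float), (len(sources),))
    out = np.zeros((len(targets), 3))
    for lo in range(0, len(targets), _CHUNK):
        hi = min(lo + _CHUNK, len(targets))
        dx = targets[lo:hi, None, :] - sources[None, :, :]
        r2 = np.einsum("tsk,tsk->ts", dx, dx)
        e2 = eps[None, :] ** 2
        denom = (r2 + e2) ** 1.5
        f1 = (r2 + 2.0 * e2) / denom
        fdotr = np.einsum("tsk,sk->ts", dx, forces)
        out[lo:hi] = f1 @ forces + np.einsum("ts,tsk->tk", fdotr / denom, dx)
    return out / (8.0 * np.pi * mu)


def stokeslet_pressure(targets, sources, forces, eps):
    """Pressure at ``targets`` (zero at infinity) from regularized forces."""
    targets = np.atleast_2d(np.asarray(targets, float))
    sources = np.atleast_2d(np.asarray(sources, float))
    forces = np.atleast_2d(np.asarray(forces, float))
    eps = np.broadcast_to(np.asarray(eps, float), (len(sources),))
    out = np.zeros(len(targets))
    for lo in range(0, len(targets), _CHUNK):
        hi = min(lo + _CHUNK, len(targets))
        dx = targets[lo:hi, None, :] - sources[None, :, :]
        r2 = np.einsum("tsk,tsk->ts", dx, dx)
        e2 = eps[None, :] ** 2
        fdotr = np.einsum("tsk,sk->ts", dx, forces)
        out[lo:hi] = np.sum(fdotr * (2.0 * r2 + 5.0 * e2) / (r2 + e2) ** 2.5, axis=1)
    return out / (8.0 * np.pi)


def _blake_image_block(dx_img, h):
    """Image-system kernel (3x3 blocks) for sources at height h over z=0.

    ``dx_img`` is target minus mirrored source, shape (T, S, 3); returns the
    (T, S, 3, 3) tensor multiplying F/(8 pi mu): minus the image Stokeslet
    plus Blake's dipole/doublet correction.
    """
    R2 = np.einsum("tsk,tsk->ts", dx_img, dx_img)
    R = np.sqrt(R2)
    R3 = R * R2
    R5 = R3 * R2
    T, S, _ = dx_img.shape
    out = np.empty((T, S, 3, 3))
    eye = np.eye(3)
    # minus image Stokeslet
    for i in range(3):
        for j in range(3):
            out[:, :, i, j] = -(eye[i, j] / R + dx_img[:, :, i] * dx_img[:, :, j] / R3)
    # d phi_i / d R_l with phi_i = h R_i / R^3 - delta_i3 / R - R_i R_3 / R^3
    R_3 = dx_img[:, :, 2]
    for i in range(3):
        Ri = dx_img[:, :, i]
        for l in range(3):
            Rl = dx_img[:, :, l]
            dphi = h[None, :] * (eye[i, l] / R3 - 3.0 * Ri * Rl / R5)
            if i == 2:
                dphi = dphi + Rl / R3
            dphi = dphi - (eye[i, l] * R_3 + (1.0 if l == 2 else 0.0) * Ri) / R3
            dphi = dphi + 3.0 * Ri * R_3 * Rl / R5
            sign = -1.0 if l == 2 else 1.0
            out[:, :, i, l] += 2.0 * h[None, :] * sign * dphi
    return out


def blake_velocity(targets, sources, forces, eps, mu=1.0):
    """Velocity above a no-slip plane z=0 from regularized forces.

    Primary regularized Stokeslet plus the singular Blake image system; the
    residual slip on the wall is O(eps^2 / h^2) for sources at height h.
    """
    targets = np.atleast_2d(np.asarray(targets, float))
    sources = np.atleast_2d(np.asarray(sources, float))
    forces = np.atleast_2d(np.asarray(forces, float))
    u = stokeslet_velocity(targets, sources, forces, eps, mu=mu)
    mirror = sources.copy()
    mirror[:, 2] *= -1.0
    dx = targets[:, None, :] - mirror[None, :, :]
    block = _blake_image_block(dx, sources[:, 2])
    u += np.einsum("tsij,sj->ti", block, forces) / (8.0 * np.pi * mu)
    return u


def assemble_blake_matrix(targets, sources, eps_pair, mu=1.0):
    """Dense matrix of :func:`blake_velocity` (not symmetric)."""
    T, S = len(targets), len(sources)
    A = assemble_matrix(targets, sources, eps_pair, mu=mu).reshape(T, 3, S, 3)
    mirror = np.asarray(sources, float).copy()
    mirror[:, 2] *= -1.0
    dx = np.asarray(targets, float)[:, None, :] - mirror[None, :, :]
    block = _blake_image_block(dx, np.asarray(sources)[:, 2])
    A += block.transpose(0, 2, 1, 3) / (8.0 * np.pi * mu)
    return A.reshape(3 * T, 3 * S)


@dataclass
class StokesSolution:
    """Solved force distribution at one instant, with field evaluation.

    ``forces`` are the forces exerted on the fluid; for flagellar nodes the
    force density (force per unit arc length) is ``forces / weights``.
    """

    points: np.ndarray  # (n, 3) collocation points
    forces: np.ndarray  # (n, 3) force on the fluid
    eps: np.ndarray  # (n,)
    weights: np.ndarray  # (n,) quadrature weights (area / arc length / 1)
    kind: np.ndarray  # (n,) -1 surface, >=0 flagellum index
    t: float = 0.0
    mu: float = 1.0
    residual: float = 0.0
    half_space: bool = False
    velocities: np.ndarray | None = None  # prescribed velocity at each point

    @property
    def flagella_mask(self):
        return self.kind >= 0

    def force_density(self):
        return self.forces / self.weights[:, None]

    def velocity(self, points, check=True):
        points = np.atleast_2d(points)
        if check:
            self._check_clear(points)
        fn = blake_velocity if self.half_space else stokeslet_velocity
        return fn(points, self.points, self.forces, self.eps, mu=self.mu)

    def pressure(self, points, check=True):
        if self.half_space:
            raise NotImplementedError("pressure evaluation is free-space only")
        points = np.atleast_2d(points)
        if check:
            self._check_clear(points)
        return stokeslet_pressure(points, self.points, self.forces, self.eps)

    def _check_clear(self, points):
        for lo in range(0, len(points), _CHUNK):
            d2 = np.sum(
                (points[lo : lo + _CHUNK, None, :] - self.points[None, :, :]) ** 2,
                axis=-1,
            )
            dmin = np.sqrt(d2.min(axis=1))
            if np.any(dmin < 1e-12):
                raise ValueError("evaluation point coincides with a force point")

    def total_force(self):
        return self.forces.sum(axis=0)

    def force_balance_error(self):
        """|sum F| relative to the L1 norm of all forces."""
        l1 = np.abs(self.forces).sum()
        return float(np.linalg.norm(self.total_force()) / l1) if l1 else 0.0


class ResistanceSolver:
    """Resistance problem with a fixed no-slip point set and moving nodes.

    The surface-surface block is assembled and LU-factorised once; each call
    to :meth:`solve` only assembles the blocks that involve the instantaneous
    flagellar nodes and eliminates the surface unknowns by a Schur
    complement.  With no surface points this reduces to a plain dense solve.
    """

    def __init__(self, surface_points, surface_eps, surface_weights=None, mu=1.0):
        self.surface_points = np.atleast_2d(np.asarray(surface_points, float))
        if self.surface_points.size == 0:
            self.surface_points = np.zeros((0, 3))
        self.surface_eps = np.broadcast_to(
            np.asarray(surface_eps, float), (len(self.surface_points),)
        ).copy()
        self.surface_weights = (
            np.ones(len(self.surface_points))
            if surface_weights is None
            else np.asarray(surface_weights, float)
        )
        self.mu = mu
        if len(self.surface_points):
            A_ss = assemble_matrix(
                self.surface_points,
                self.surface_points,
                _pair_eps(self.surface_eps, self.surface_eps),
                mu=mu,
            )
            self._lu = lu_factor(A_ss)
        else:
            self._lu = None

    def solve(self, flag_points, flag_eps, flag_velocities, kind=None, t=0.0,
              rhs_surface=None, extra_forces=None):
        """Solve for point forces given prescribed node velocities.

        ``rhs_surface`` optionally prescribes a nonzero velocity on the
        surface points (flattened or (ns, 3)); ``extra_forces`` is an
        optional (points, forces, eps) triple of known forces whose induced
        velocity is subtracted from every boundary condition (used for the
        pressure-difference sub-problem).
        """
        flag_points = np.atleast_2d(np.asarray(flag_points, float))
        nf = len(flag_points)
        flag_eps = np.broadcast_to(np.asarray(flag_eps, float), (nf,)).copy()
        u_f = np.asarray(flag_velocities, float).reshape(nf * 3)
        ns = len(self.surface_points)
        u_s = np.zeros(ns * 3) if rhs_surface is None else np.asarray(rhs_surface, float).reshape(ns * 3)
        prescribed = np.concatenate([u_s, u_f]).reshape(-1, 3)
        if extra_forces is not None:
            ep, ef, ee = extra_forces
            if ns:
                u_s = u_s - stokeslet_velocity(self.surface_points, ep, ef, ee, mu=self.mu).reshape(-1)
            if nf:
                u_f = u_f - stokeslet_velocity(flag_points, ep, ef, ee, mu=self.mu).reshape(-1)

        if nf == 0:
            F_s = lu_solve(self._lu, u_s).reshape(ns, 3)
            F = F_s
            pts = self.surface_points
            eps = self.surface_eps
        elif ns == 0:
            A_ff = assemble_matrix(flag_points, flag_points, _pair_eps(flag_eps, flag_eps), mu=self.mu)
            F = solve(A_ff, u_f, assume_a="sym").reshape(nf, 3)
            pts = flag_points
            eps = flag_eps
        else:
            A_sf = assemble_matrix(
                self.surface_points, flag_points, _pair_eps(self.surface_eps, flag_eps), mu=self.mu
            )
            A_ff = assemble_matrix(flag_points, flag_points, _pair_eps(flag_eps, flag_eps), mu=self.mu)
            X = lu_solve(self._lu, A_sf)
            S = A_ff - A_sf.T @ X
            rhs = u_f - A_sf.T @ lu_solve(self._lu, u_s)
            F_f = solve(S, rhs)
            F_s = lu_solve(self._lu, u_s - A_sf @ F_f)
            F = np.vstack([F_s.reshape(ns, 3), F_f.reshape(nf, 3)])
            pts = np.vstack([self.surface_points, flag_points])
            eps = np.concatenate([self.surface_eps, flag_eps])

        weights = np.concatenate([self.surface_weights[:ns] if ns else np.zeros(0), np.ones(nf)])
        if nf == 0:
            weights = self.surface_weights.copy()
        if kind is None:
            kind = np.concatenate([np.full(len(pts) - nf, -1), np.zeros(nf)])
        sol = StokesSolution(
            points=pts, forces=F.reshape(-1, 3), eps=eps, weights=weights,
            kind=np.asarray(kind), t=t, mu=self.mu, velocities=prescribed,
        )
        if extra_forces is not None:
            ep, ef, ee = extra_forces
            sol.points = np.vstack([sol.points, ep])
            sol.forces = np.vstack([sol.forces, ef])
            sol.eps = np.concatenate([sol.eps, np.broadcast_to(ee, (len(ep),))])
            sol.weights = np.concatenate([sol.weights, np.ones(len(ep))])
            sol.kind = np.concatenate([sol.kind, np.full(len(ep), -2)])
            sol.velocities = np.vstack([sol.velocities, np.zeros((len(ep), 3))])
        return sol


def write_structured_vtk(path, origin, spacing, dims, velocity, pressure=None):
    """Write a regular grid of vectors (and optionally pressure) as legacy VTK.

    ``dims`` is (nx, ny, nz); ``velocity`` has shape (nx*ny*nz, 3) in
    x-fastest order, ``pressure`` (nx*ny*nz,).
    """
    nx, ny, nz = dims
    n = nx * ny * nz
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nchoanopump field slice\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write(f"ORIGIN {origin[0]:.9g} {origin[1]:.9g} {origin[2]:.9g}\n")
        fh.write(f"SPACING {spacing[0]:.9g} {spacing[1]:.9g} {spacing[2]:.9g}\n")
        fh.write(f"POINT_DATA {n}\nVECTORS velocity double\n")
        for v in velocity:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        if pressure is not None:
            fh.write("SCALARS pressure double 1\nLOOKUP_TABLE default\n")
            fh.write("\n".join(f"{p:.9g}" for p in pressure) + "\n")


def export_field_slice_vtk(sol, path, half_width, spacing, mask_distance=None):
    """Sample velocity and pressure on the mid-plane y = 0 and write VTK.

    The slice spans ``[-half_width, half_width]`` in x and z with the given
    grid ``spacing``; points closer than ``mask_distance`` (default: one
    regularization length) to any force point are zeroed.
    """
    ax = np.arange(-half_width, half_width + 0.5 * spacing, spacing)
    X, Z = np.meshgrid(ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), np.zeros(X.size), Z.ravel()])
    if mask_distance is None:
        mask_distance = float(np.max(sol.eps))
    near = np.zeros(len(pts), bool)
    for lo in range(0, len(pts), _CHUNK):
        d2 = np.min(
            np.sum((pts[lo : lo + _CHUNK, None, :] - sol.points[None, :, :]) ** 2, axis=-1),
            axis=1,
        )
        near[lo : lo + _CHUNK] = d2 < mask_distance**2
    u = sol.velocity(pts, check=False)
    u[near] = 0.0
    p = None
    if not sol.half_space:
        p = sol.pressure(pts, check=False)
        p[near] = 0.0
    # grid order: x fastest, then z; y is a single layer
    nx = len(ax)
    u_ordered = u.reshape(nx, nx, 3).transpose(1, 0, 2).reshape(-1, 3)
    p_ordered = None if p is None else p.reshape(nx, nx).T.reshape(-1)
    write_structured_vtk(
        path, (ax[0], 0.0, ax[0]), (spacing, 1.0, spacing), (nx, 1, nx),
        u_ordered, p_ordered,
    )


def solve_wall_flagellum(params, t, eps_factor=0.5, mu=1.0):
    """Resistance solve for one flagellum attached normal to a plane wall.

    The flagellum stands on the no-slip plane z = 0, beating toward +z, and
    the wall enters through the Blake image system rather than a mesh.  The
    clamped base node lies in the wall where any point force is screened
    (its column of the image kernel vanishes identically), so it is dropped
    from the unknowns.
    """
    from .kinematics import flagellum_state

    state = flagellum_state(
        np.zeros(3), np.array([0.0, 0.0, 1.0]), 0.0, 0.0, params, t
    )
    pts = state.positions[1:]
    vel = state.velocities[1:]
    spacing = params.length / (params.n_nodes - 1)
    eps = np.full(len(pts), eps_factor * spacing)
    A = assemble_blake_matrix(pts, pts, _pair_eps(eps, eps), mu=mu)
    F = solve(A, vel.reshape(-1)).reshape(-1, 3)
    return StokesSolution(
        points=pts, forces=F, eps=eps, weights=state.arc_weights[1:],
        kind=np.zeros(len(pts)), t=t, mu=mu, half_space=True,
        velocities=vel,
    )


def wall_attached_flux(
    params=None, n_steps=50, heights=None, r_max=6.0, n_r=48, n_az=24,
    eps_factor=0.5,
):
    """Time-averaged outgoing flux of a single wall-attached flagellum.

    The period-averaged velocity field is sampled on horizontal planes
    z = h; on each plane the outgoing flux is the integral of the positive
    part of u_z (total net flux vanishes by mass conservation against the
    wall).  Returns (flux, per-plane fluxes, heights), where the headline
    number is the maximum over planes -- the total recirculating volume
    rate the flagellum drives away from the wall.
    """
    from .kinematics import WaveformParams

    if params is None:
        params = WaveformParams()
    if heights is None:
        heights = np.linspace(0.2, 2.0, 10) * params.length
    r = (np.arange(n_r) + 0.5) * (r_max / n_r)
    az = np.arange(n_az) * (2.0 * np.pi / n_az)
    R, AZ = np.meshgrid(r, az, indexing="ij")
    disc = np.column_stack([(R * np.cos(AZ)).ravel(), (R * np.sin(AZ)).ravel()])
    dA = (r_max / n_r) * (2.0 * np.pi / n_az) * R.ravel()
    planes = [
        np.column_stack([disc, np.full(len(disc), h)]) for h in heights
    ]
    u_sum = [np.zeros(len(disc)) for _ in heights]
    for i in range(n_steps):
        sol = solve_wall_flagellum(params, i / n_steps, eps_factor=eps_factor)
        for j, pts in enumerate(planes):
            u_sum[j] += sol.velocity(pts, check=False)[:, 2]
    fluxes = np.array(
        [np.sum(np.clip(u / n_steps, 0.0, None) * dA) for u in u_sum]
    )
    return float(fluxes.max()), fluxes, np.asarray(heights)


class ChamberSolver:
    """Resistance solver bound to a chamber mesh and a flagellum layout."""

    def __init__(self, mesh, layout, params, eps_factor=0.5, mu=1.0):
        from .kinematics import states_for_layout

        self.mesh = mesh
        self.layout = layout
        self.params = params
        self.eps_factor = eps_factor
        self._states_for_layout = states_for_layout
        mask = mesh.noslip_mask
        pts = mesh.centroids[mask]
        tri = mesh.vertices[mesh.triangles[mask]]
        edge = np.linalg.norm(
            np.stack([tri[:, 0] - tri[:, 1], tri[:, 1] - tri[:, 2], tri[:, 2] - tri[:, 0]]),
            axis=-1,
        ).mean(axis=0)
        eps = eps_factor * edge  # 0.5 x local element spacing by default
        self._solver = ResistanceSolver(pts, eps, surface_weights=mesh.areas[mask], mu=mu)
        self.node_spacing = params.length / (params.n_nodes - 1)
        self.flag_eps = eps_factor * self.node_spacing

    def state(self, t):
        return self._states_for_layout(self.layout, self.params, t)

    def solve(self, t=0.0, state=None, extra_forces=None, freeze=False):
        """Resistance solution at time ``t``.

        ``freeze=True`` zeroes the node velocities (immotile flagella held
        rigid at the phase of ``t``), the configuration used by the
        pressure-difference sub-problem.
        """
        if state is None:
            state = self.state(t)
        N, n, _ = state.positions.shape
        pts = state.positions.reshape(N * n, 3)
        vel = np.zeros_like(pts) if freeze else state.velocities.reshape(N * n, 3)
        radii = np.linalg.norm(pts, axis=1)
        if radii.max() > self.mesh_radius + 1e-9:
            raise ValueError("flagellum crosses the chamber wall")
        kind = np.concatenate(
            [np.full(len(self._solver.surface_points), -1), np.repeat(np.arange(N), n)]
        )
        sol = self._solver.solve(
            pts, self.flag_eps, vel, kind=kind, t=t, extra_forces=extra_forces
        )
        ns = len(self._solver.surface_points)
        sol.weights[ns : ns + N * n] = np.tile(state.arc_weights, N)
        return sol

    @property
    def mesh_radius(self):
        return float(np.linalg.norm(self.mesh.vertices, axis=1).max())
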