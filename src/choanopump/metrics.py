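"""Dimensionless pumping metrics of a chamber solution.

For one instantaneous Stokes solution the module computes

* the outlet flow rate ``Q = integral of u . n over the apopyle cap``,
  rescaled by ``T / L^3`` (an identity in model units);
* chamber pressures: ``Pc`` at the centre and ``Pmax``, the maximum over a
  regular grid inside half the chamber radius (the high-pressure core sits
  near the centre), rescaled by ``T / mu``;
* the flagellar rate of working ``W = sum_i integral u . (-f) ds`` where
  ``f`` is the force of the fluid on the filament (so ``-f`` is the force
  the filament exerts on the fluid and ``W`` is the positive dissipation),
  rescaled by ``T^2 / (mu L^3)``;
* the mechanical pumping efficiency ``eta = Qbar * Pmax_bar / Wbar`` built
  from the time averages over one beat period.

An adverse pressure difference ``dP`` between the outlet and the inlets
shifts the operating point linearly: with immotile flagella held rigid, a
unit normal-stress jump across the apopyle cap drives a return flow whose
flux and centre pressure per unit ``dP`` give the coefficients ``C1 < 0``
and ``C2``, so ``Q' = Qbar + C1 dP`` and ``P' = Pmax_bar + C2 dP``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PumpMetrics",
    "outlet_flow_rate",
    "max_pressure",
    "work_rate",
    "efficiency",
    "pressure_grid",
    "delta_p_response",
    "shifted_operating_point",
    "time_ensemble_average",
]


@dataclass
class PumpMetrics:
    """Per-step time series over one beat period plus derived averages."""

    times: np.ndarray
    Q: np.ndarray
    Pc: np.ndarray
    Pmax: np.ndarray
    W: np.ndarray
    seed: int = 0
    meta: dict = field(default_factory=dict)

    @property
    def Q_bar(self):
        return float(np.mean(self.Q))

    @property
    def Pc_bar(self):
        return float(np.mean(self.Pc))

    @property
    def Pmax_bar(self):
        return float(np.mean(self.Pmax))

    @property
    def W_bar(self):
        return float(np.mean(self.W))

    @property
    def eta(self):
        return efficiency(self.Q_bar, self.Pmax_bar, self.W_bar)

    def to_frame(self):
        return pd.DataFrame(
            {"t": self.times, "Q": self.Q, "Pc": self.Pc, "Pmax": self.Pmax, "W": self.W}
        )

    def summary(self):
        out = {
            "Q_bar": self.Q_bar,
            "Pc_bar": self.Pc_bar,
            "Pmax_bar": self.Pmax_bar,
            "W_bar": self.W_bar,
            "eta": self.eta,
            "seed": self.seed,
        }
        out.update(self.meta)
        return out


def outlet_flow_rate(sol, mesh):
    """Rescaled outlet flow rate through the apopyle cap.

    One-point (centroid) quadrature of ``u . n`` over the cap triangles with
    their exact spherical areas and outward radial normals.
    """
    mask = mesh.region_mask("apopyle_surface")
    if not mask.any():
        raise ValueError("mesh has no apopyle flux surface")
    cen = mesh.centroids[mask]
    u = sol.velocity(cen, check=False)
    return float(np.sum(np.einsum("ij,ij->i", u, mesh.normals[mask]) * mesh.areas[mask]))


def pressure_grid(radius, spacing=None, fraction=0.5):
    """Regular Cartesian grid filling the ball of ``fraction * radius``."""
    if spacing is None:
        spacing = 0.05 * radius
    rmax = fraction * radius
    ax = np.arange(-rmax, rmax + 0.5 * spacing, spacing)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    return pts[np.linalg.norm(pts, axis=1) <= rmax]

def max_pressure(sol, grid, exclusion=None):
    """Centre pressure ``Pc`` and grid maximum ``Pmax`` of the solution.

    Grid points closer than ``exclusion`` to any flagellar node are
    discarded before taking the maximum.  The default is three
    regularization lengths (1.5 node spacings at the default blob size):
    within about one node spacing of the discretized centreline the
    pressure kernel reflects the discreteness of the force distribution,
    not the resolved chamber field.
    """
    pc = float(sol.pressure(np.zeros((1, 3)), check=False)[0])
    fmask = sol.flagella_mask
    pts = grid
    if fmask.any():
        if exclusion is None:
            exclusion = 3.0 * float(np.max(sol.eps[fmask]))
        nodes = sol.points[fmask]
        keep = np.ones(len(grid), bool)
        for lo in range(0, len(grid), 1024):
            d2 = np.min(
                np.sum((grid[lo : lo + 1024, None, :] - nodes[None, :, :]) ** 2, axis=-1),
                axis=1,
            )
            keep[lo : lo + 1024] = d2 > exclusion**2
        pts = grid[keep]
    if len(pts) == 0:
        raise ValueError("no pressure sampling points left after exclusions")
    p = sol.pressure(pts, check=False)
    return pc, float(p.max())


def work_rate(sol):
    """Rate of working of all flagella on the fluid (positive dissipation).

    The quadrature ``sum u . (-f) ds`` along each filament, with ``f`` the
    force density of the fluid on it, equals the dot product of the node
    velocities with the solved force-on-fluid at the nodes (the arc-length
    weights are already folded into the forces).
    """
    raise_if_no_flagella(sol)
    if sol.velocities is None:
        raise ValueError("solution does not carry node velocities")
    mask = sol.flagella_mask
    return float(np.einsum("ij,ij->", sol.velocities[mask], sol.forces[mask]))


def work_rate_from(velocities, forces_on_fluid):
    """W from explicit node velocities and forces on the fluid."""
    return float(np.einsum("ij,ij->", velocities, forces_on_fluid))


def raise_if_no_flagella(sol):
    if not sol.flagella_mask.any():
        raise ValueError("solution contains no flagellar nodes")


def efficiency(Q_bar, Pmax_bar, W_bar):
    """Mechanical pumping efficiency ``eta = Qbar Pmax_bar / Wbar``."""
    if W_bar < 0:
        raise ValueError("negative mean work rate")
    if W_bar == 0.0:
        raise ValueError("zero mean work rate: efficiency undefined")
    return Q_bar * Pmax_bar / W_bar


def delta_p_response(solver, mesh, t=0.0):
    """Linear response (C1, C2) to an adverse outlet-inlet pressure jump.

    The flagella are frozen at the phase of ``t`` and act as rigid
    obstacles; a unit normal-stress jump across the apopyle cap (a known
    inward force ``-n dS`` per cap element) drives a pressure-relief flow.
    ``C1`` is its apopyle flux and ``C2`` its centre pressure, per unit
    ``dP``; superposition then gives the shifted operating point
    ``Q' = Qbar + C1 dP``, ``P' = Pmax_bar + C2 dP``.
    """
    mask = mesh.region_mask("apopyle_surface")
    cap_pts = mesh.centroids[mask]
    cap_forces = -mesh.normals[mask] * mesh.areas[mask][:, None]
    cap_eps = 0.5 * np.sqrt(mesh.areas[mask])
    sol = solver.solve(t=t, freeze=True, extra_forces=(cap_pts, cap_forces, cap_eps))
    C1 = outlet_flow_rate(sol, mesh)
    C2 = float(sol.pressure(np.zeros((1, 3)), check=False)[0])
    return C1, C2


def shifted_operating_point(Q_bar, Pmax_bar, W_bar, C1, C2, delta_p):
    """(Q', P', eta') under an adverse pressure difference ``delta_p``."""
    Qp = Q_bar + C1 * delta_p
    Pp = Pmax_bar + C2 * delta_p
    return Qp, Pp, efficiency(Qp, Pp, W_bar)


def time_ensemble_average(runs):
    """Ensemble mean and SD of the period-averaged metrics across seeds.

    ``runs`` is a sequence of :class:`PumpMetrics`, one per seed.  Returns a
    one-row DataFrame with mean and SD columns for Q, Pc, Pmax, W and eta.
    """
    if not runs:
        raise ValueError("no completed runs")
    rows = pd.DataFrame([r.summary() for r in runs])
    out = {}
    for col in ("Q_bar", "Pc_bar", "Pmax_bar", "W_bar", "eta"):
        out[col] = rows[col].mean()
        out[col + "_sd"] = rows[col].std(ddof=1) if len(rows) > 1 else 0.0
    out["n_seeds"] = len(rows)
    return pd.DataFrame([out])
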