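"""Coarse-grained point-force model of a choanocyte chamber.

Each flagellum is collapsed to a single point force of magnitude ``f``
directed toward the chamber centre, placed on the sphere of radius ``R_f``
outside the outlet cap of half-angle ``theta_a``.  Free-space Stokeslet
kernels (no wall) isolate the purely geometric pressure effect of the
spherical arrangement: every inward force contributes ``f / (4 pi R_f^2)``
to the centre pressure, so

    p_c = N f / (4 pi R_f^2) = n f (1 + cos theta_a) / 2

at fixed surface density ``n = N / (2 pi R_f^2 (1 + cos theta_a))``.
Opening the outlet wider removes the forces that beat against the bulk flow
and the centre pressure falls as ``(1 + cos theta_a) / 2`` -- the mechanism
behind the monotonic pressure decrease with opening angle seen in the full
chamber simulations.  This module is a mechanism demonstrator, not a
quantitative surrogate for the resolved model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import fibonacci_zone_points
from .stokes import stokeslet_pressure, stokeslet_velocity

__all__ = ["PointForceChamber", "center_pressure", "analytic_center_pressure", "field_maps"]


@dataclass(frozen=True)
class PointForceChamber:
    """N inward point forces of magnitude f on a spherical shell."""

    n_forces: int = 143
    force_radius: float = 1.5
    force_magnitude: float = 1.0
    theta_a_deg: float = 30.0

    def __post_init__(self):
        if self.force_radius <= 0:
            raise ValueError("force radius must be positive")
        if not 0.0 <= self.theta_a_deg <= 90.0:
            raise ValueError("theta_a must lie in [0, 90] degrees")
        if self.n_forces < 1:
            raise ValueError("need at least one force")

    @property
    def theta_a(self):
        return np.radians(self.theta_a_deg)

    @property
    def surface_density(self):
        return self.n_forces / (
            2.0 * np.pi * self.force_radius**2 * (1.0 + np.cos(self.theta_a))
        )

    def positions(self):
        return self.force_radius * fibonacci_zone_points(self.n_forces, self.theta_a)

    def forces(self):
        pos = self.positions()
        return -self.force_magnitude * pos / np.linalg.norm(pos, axis=1, keepdims=True)


def center_pressure(chamber: PointForceChamber) -> float:
    """Centre pressure by superposition of the point-force pressure kernels."""
    return float(
        stokeslet_pressure(
            np.zeros((1, 3)), chamber.positions(), chamber.forces(), 0.0
        )[0]
    )


def analytic_center_pressure(chamber: PointForceChamber) -> float:
    """Closed form ``n f (1 + cos theta_a) / 2``."""
    return (
        chamber.surface_density
        * chamber.force_magnitude
        * (1.0 + np.cos(chamber.theta_a))
        / 2.0
    )


def field_maps(chamber: PointForceChamber, grid, min_distance=1e-6):
    """Superposed velocity and pressure of all point forces on ``grid``.

    Raises when a grid point sits atop a singularity (closer than
    ``min_distance``).
    """
    grid = np.atleast_2d(np.asarray(grid, float))
    pos = chamber.positions()
    for lo in range(0, len(grid), 1024):
        d2 = np.sum((grid[lo : lo + 1024, None, :] - pos[None, :, :]) ** 2, axis=-1)
        if d2.min() < min_distance**2:
            raise ValueError("grid point atop a point force")
    frc = chamber.forces()
    u = stokeslet_velocity(grid, pos, frc, 0.0)
    p = stokeslet_pressure(grid, pos, frc, 0.0)
    return u, p
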