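"""Morphometric relations for spherical choanocyte chambers.

The chamber is idealised as a sphere of diameter ``D`` with one large outlet
(the apopyle, a circular opening of diameter ``d``) and its inner wall tiled
by flagellated collar cells.  This module collects the geometric and
dimensional conversions that connect measurable quantities -- chamber and
apopyle diameters, cell counts, flagellar waveform dimensions -- to the
dimensionless parameters of the hydrodynamic model: the apopyle half-opening
angle ``theta_a``, the surface number density of flagella, the area coverage
fraction ``phi``, and the scaled wavenumber ``k*ell``.

All angles are in degrees at the API surface; lengths are micrometres unless
a function says otherwise.
"""

from __future__ import annotations

import math
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "HEX_PACKING_FRACTION",
    "opening_angle",
    "coverage_fraction",
    "flagellar_density",
    "wavenumber_from_waveform",
    "min_chamber_diameter",
    "flow_rate_to_physical",
    "pressure_to_physical",
    "load_chamber_table",
    "efficiency_band",
    "estimate_track_geometry",
]

#: Maximum packing fraction of circles on a plane (hexagonal close packing),
#: the natural upper reference for the coverage fraction phi.
HEX_PACKING_FRACTION = math.pi * math.sqrt(3.0) / 6.0


def opening_angle(chamber_diameter, apopyle_diameter=None, apopyle_area=None):
    """Apopyle half-opening angle theta_a (degrees) of a spherical chamber.

    The apopyle is treated as the chord circle of a spherical cap, so
    ``theta_a = arcsin(d / D)``.  When only the apopyle area ``S_a`` is
    reported, the diameter is recovered as ``d = 2 sqrt(S_a / pi)``.

    Parameters
    ----------
    chamber_diameter : float
        Chamber diameter ``D`` (um).
    apopyle_diameter : float, optional
        Apopyle diameter ``d`` (um).
    apopyle_area : float, optional
        Apopyle area (um^2), used when ``apopyle_diameter`` is None.
    """
    D = float(chamber_diameter)
    if apopyle_diameter is None:
        if apopyle_area is None:
            raise ValueError("provide apopyle_diameter or apopyle_area")
        apopyle_diameter = 2.0 * math.sqrt(float(apopyle_area) / math.pi)
    d = float(apopyle_diameter)
    if not 0.0 < d <= D:
        raise ValueError(f"apopyle diameter {d} must lie in (0, D={D}]")
    return math.degrees(math.asin(d / D))


def apopyle_diameter(chamber_diameter, theta_a_deg):
    """Inverse of :func:`opening_angle`: ``d = D sin(theta_a)``."""
    return float(chamber_diameter) * math.sin(math.radians(theta_a_deg))


def coverage_fraction(n_flagella, amplitude, radius, theta_a_deg):
    """Area fraction phi of flagellar beat envelopes on the chamber wall.

    Each flagellum of beat amplitude ``A`` claims a disc of area ``pi A^2``;
    the wall area available to cells (the sphere minus the apopyle cap) is
    ``2 pi R^2 (1 + cos theta_a)``, giving

        phi = N A^2 / (2 R^2 (1 + cos theta_a)).

    Inputs may be in any consistent length unit.
    """
    _check_positive(n_flagella=n_flagella, amplitude=amplitude, radius=radius)
    _check_angle(theta_a_deg)
    ca = math.cos(math.radians(theta_a_deg))
    return n_flagella * amplitude**2 / (2.0 * radius**2 * (1.0 + ca))


def flagellar_density(n_flagella, radius, theta_a_deg):
    """Number of flagella per unit wall area, ``N / (2 pi R^2 (1+cos theta_a))``."""
    _check_positive(n_flagella=n_flagella, radius=radius)
    _check_angle(theta_a_deg)
    ca = math.cos(math.radians(theta_a_deg))
    return n_flagella / (2.0 * math.pi * radius**2 * (1.0 + ca))


def wavenumber_from_waveform(ell, wavelength, ell_sd=None, wavelength_sd=None):
    """Scaled wavenumber k*ell, in units of pi, from waveform measurements.

    With projected flagellar length ``ell`` and wavelength ``lambda``,
    ``k ell / pi = 2 ell / lambda``.  If standard deviations are supplied the
    uncertainty is propagated to first order assuming independent errors.

    Returns
    -------
    float or (float, float)
        ``k*ell/pi``; with SDs supplied, a ``(value, sd)`` pair.
    """
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    value = 2.0 * ell / wavelength
    if ell_sd is None and wavelength_sd is None:
        return value
    ell_sd = ell_sd or 0.0
    wavelength_sd = wavelength_sd or 0.0
    var = (2.0 * ell_sd / wavelength) ** 2 + (
        2.0 * ell * wavelength_sd / wavelength**2
    ) ** 2
    return value, math.sqrt(var)


def min_chamber_diameter(
    n_flagella,
    amplitude,
    ell,
    theta_a_deg,
    criterion="analytic",
    safety=1.0,
):
    """Smallest chamber diameter (um) with non-overlapping flagellar envelopes.

    Flagella converge radially inward, so nearest-neighbour separation is
    tightest at the tips, which sit on the sphere of radius ``R - ell``.  The
    chamber must be large enough that tip separation is at least twice the
    beat amplitude ``A``.

    Two realisations of the criterion are provided:

    ``"analytic"`` (default)
        Ideal hexagonal packing of the tips on their spherical zone of area
        ``2 pi (R-ell)^2 (1 + cos theta_a)``; the lattice spacing
        ``sqrt(2 * area / (sqrt(3) N))`` must reach ``2 A``, which gives the
        closed form ``D = 2 (ell + A sqrt(sqrt(3) N / (pi (1+cos theta_a))))``.
    ``"layout"``
        Bisection on ``R`` with a brute-force pairwise distance check over the
        quasi-uniform spiral layout used by the simulations
        (:func:`choanopump.geometry.fibonacci_zone_points`), whose minimum
        spacing falls short of the hexagonal ideal by a lattice-dependent
        factor.

    Parameters are in micrometres; ``safety`` scales the required separation.
    """
    _check_positive(n_flagella=n_flagella, ell=ell)
    _check_angle(theta_a_deg)
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    required = 2.0 * amplitude * safety
    ca = math.cos(math.radians(theta_a_deg))
    if criterion == "analytic":
        tip_radius = amplitude * safety * math.sqrt(
            math.sqrt(3.0) * n_flagella / (math.pi * (1.0 + ca))
        )
        return 2.0 * (tip_radius + ell)
    if criterion != "layout":
        raise ValueError(f"unknown criterion {criterion!r}")

    from .geometry import fibonacci_zone_points

    theta_a = math.radians(theta_a_deg)
    dirs = fibonacci_zone_points(int(n_flagella), theta_a)

    def min_tip_spacing(R):
        tips = dirs * (R - ell)
        d2 = np.sum((tips[:, None, :] - tips[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        return math.sqrt(d2.min())

    lo = ell  # tips meet at the centre
    if required == 0.0 or min_tip_spacing(lo) >= required:
        return 2.0 * lo
    hi = lo + 10.0 * amplitude * math.sqrt(max(n_flagella, 1))
    while min_tip_spacing(hi) < required:  # pragma: no cover - generous start
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("no feasible chamber radius found")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if min_tip_spacing(mid) >= required:
            hi = mid
        else:
            lo = mid
    return 2.0 * hi


def flow_rate_to_physical(Q, flagellum_length_um, beat_frequency_hz):
    """Convert a dimensionless flow rate ``Q = Q* T / L^3`` to um^3/s."""
    _check_positive(L=flagellum_length_um, nu=beat_frequency_hz)
    return Q * flagellum_length_um**3 * beat_frequency_hz


def pressure_to_physical(P, beat_frequency_hz, viscosity_pa_s=1e-3):
    """Convert a dimensionless pressure ``P = P* T / mu`` to Pa."""
    _check_positive(nu=beat_frequency_hz, mu=viscosity_pa_s)
    return P * viscosity_pa_s * beat_frequency_hz


def load_chamber_table(derive=True):
    """Published chamber dimensions for 13 sponge species, as a DataFrame.

    With ``derive=True`` (default) adds columns computed here:
    ``theta_a_derived_deg`` from the diameters/areas, ``density_per_um2``
    (flagella per um^2 of available wall), and ``phi`` where an amplitude is
    known (only *E. muelleri*, with A = 1.58 um).
    """
    with resources.files("choanopump.data").joinpath(
        "chamber_dimensions.csv"
    ).open() as fh:
        table = pd.read_csv(fh)
    if not derive:
        return table
    derived = []
    for _, row in table.iterrows():
        d = row["apopyle_diameter_um"]
        area = row["apopyle_area_um2"]
        if pd.notna(d) or pd.notna(area):
            derived.append(
                opening_angle(
                    row["chamber_diameter_um"],
                    None if pd.isna(d) else d,
                    None if pd.isna(area) else area,
                )
            )
        else:  # pragma: no cover - table always has one of the two
            derived.append(np.nan)
    table["theta_a_derived_deg"] = derived
    table["density_per_um2"] = [
        flagellar_density(
            row["choanocytes_per_chamber"],
            row["chamber_diameter_um"] / 2.0,
            row["theta_a_deg"],
        )
        for _, row in table.iterrows()
    ]
    return table


def efficiency_band(sim_surface, species, threshold=0.9, n_interp=721):
    """Flag species whose opening angle lies in the near-optimal band.

    ``sim_surface`` holds simulated efficiency curves: columns ``density``
    (flagella per um^2), ``theta_a_deg`` and ``eta``.  For each density the
    band is the theta_a interval (linear interpolation) where eta is at least
    ``threshold`` times its maximum.  Each species row (columns
    ``theta_a_deg`` and ``density``) is matched to the nearest simulated
    density and flagged if its angle falls inside that band.

    Returns a DataFrame with ``band_lo_deg``, ``band_hi_deg``, ``in_band``.
    """
    sim = pd.DataFrame(sim_surface)
    bands = {}
    for dens, grp in sim.groupby("density"):
        grp = grp.sort_values("theta_a_deg")
        th = grp["theta_a_deg"].to_numpy(float)
        eta = grp["eta"].to_numpy(float)
        if len(th) < 2 or np.any(np.diff(th) <= 0):
            raise ValueError("degenerate simulated efficiency curve")
        fine = np.linspace(th[0], th[-1], n_interp)
        eta_f = np.interp(fine, th, eta)
        good = eta_f >= threshold * eta_f.max()
        bands[dens] = (fine[good].min(), fine[good].max())
    dens_grid = np.array(sorted(bands))
    out = pd.DataFrame(species).copy()
    lo, hi, flag = [], [], []
    for _, row in out.iterrows():
        nearest = dens_grid[np.argmin(np.abs(dens_grid - row["density"]))]
        b = bands[nearest]
        lo.append(b[0])
        hi.append(b[1])
        flag.append(b[0] <= row["theta_a_deg"] <= b[1])
    out["band_lo_deg"] = lo
    out["band_hi_deg"] = hi
    out["in_band"] = flag
    return out


def estimate_track_geometry(tracks):
    """Measure (ell, wavelength, amplitude) from flagellar node tracks.

    ``tracks`` is a tidy frame with columns ``flagellum``, ``node``, ``t``,
    ``x`` (axial, base at x=0) and ``y`` (lateral, beat plane).  Per frame,
    the projected length is the axial tip coordinate and the wavelength is
    twice the mean spacing of linear-interpolated zero crossings of y(x)
    (the amplitude envelope does not move the zeros).  The reported ``ell``
    is the minimum over the cycle -- the most compact configuration, which
    is the convention the waveform's defining shape uses -- while the
    wavelength is the median across frames.  The amplitude is the peak
    lateral excursion of the tip over the beat cycle, refined by a parabola
    through the extremal frames.
    """
    tracks = pd.DataFrame(tracks)
    ells, lams, amps = [], [], []
    for _, flag in tracks.groupby("flagellum"):
        tip_t, tip_y = [], []
        for t, frame in flag.groupby("t"):
            frame = frame.sort_values("node")
            x = frame["x"].to_numpy(float)
            y = frame["y"].to_numpy(float)
            ells.append(x[-1] - x[0])
            tip_t.append(t)
            tip_y.append(y[-1])
            # a proximal cutoff and a median over crossing spacings keep
            # measurement noise from minting spurious zeros where the
            # envelope amplitude is below the noise floor
            keep = x > 0.25 * x[-1]
            xk, yk = x[keep], y[keep]
            sign = np.sign(yk)
            idx = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
            if len(idx) >= 2:
                xc = xk[idx] - yk[idx] * (xk[idx + 1] - xk[idx]) / (yk[idx + 1] - yk[idx])
                lams.append(2.0 * np.median(np.diff(xc)))
        tip_t = np.asarray(tip_t)
        tip_y = np.abs(np.asarray(tip_y))
        if len(tip_y) >= 3:
            j = int(np.argmax(tip_y))
            jm, jp = (j - 1) % len(tip_y), (j + 1) % len(tip_y)
            dt = np.median(np.diff(np.sort(tip_t)))
            amps.append(
                _parabolic_peak(
                    np.array([-dt, 0.0, dt]), np.array([tip_y[jm], tip_y[j], tip_y[jp]])
                )
            )
        else:
            amps.append(float(tip_y.max()))
    if not lams:
        raise ValueError("tracks too short to contain a full half-wavelength")
    return {
        "ell": float(np.min(ells)),
        "wavelength": float(np.median(lams)),
        "amplitude": float(np.median(amps)),
    }


def _parabolic_peak(x3, y3):
    # vertex of the parabola through three points; falls back to the middle
    denom = (x3[0] - x3[1]) * (x3[0] - x3[2]) * (x3[1] - x3[2])
    if denom == 0:
        return y3[1]
    a = (x3[2] * (y3[1] - y3[0]) + x3[1] * (y3[0] - y3[2]) + x3[0] * (y3[2] - y3[1])) / denom
    b = (x3[2] ** 2 * (y3[0] - y3[1]) + x3[1] ** 2 * (y3[2] - y3[0]) + x3[0] ** 2 * (y3[1] - y3[2])) / denom
    if a >= 0:
        return y3[1]
    xv = -b / (2 * a)
    c = y3[1] - a * x3[1] ** 2 - b * x3[1]
    return a * xv**2 + b * xv + c


def _check_positive(**kwargs):
    for name, value in kwargs.items():
        if not value > 0:
            raise ValueError(f"{name} must be positive, got {value}")


def _check_angle(theta_a_deg):
    if not 0.0 < theta_a_deg <= 90.0:
        raise ValueError(f"theta_a must lie in (0, 90] degrees, got {theta_a_deg}")
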