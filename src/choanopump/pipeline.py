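"""Sweep runner: simulate chambers across parameter grids.

Reproduces the four study sweeps -- flagellum count ``N``, scaled chamber
radius ``rho = R/L``, scaled wavenumber ``k*ell`` and opening angle
``theta_a`` -- each summarised by the period-averaged outlet flow rate,
work rate, maximum pressure and efficiency, ensemble-averaged over seeds
that randomise beat phases and beat-plane orientations (the base lattice
and the mesh are seed-independent).

Sweeps over ``k*ell`` and ``theta_a`` hold the coverage fraction ``phi``
inside a stated band by adjusting ``N`` (the count closest to the band
midpoint); sweeps over ``rho`` hold the flagellar surface density fixed.

Resolution tiers set the mesh subdivision, nodes per flagellum and the
number of beat phases sampled per period.  Period averages use uniform
phase sampling, which converges spectrally for smooth periodic series, so
the reduced tiers sample fewer phases rather than truncating the period.
"""

from __future__ import annotations

import json
import traceback
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import ChamberSpec, build_chamber_mesh, place_flagella
from .kinematics import WaveformParams
from .metrics import (
    PumpMetrics,
    max_pressure,
    outlet_flow_rate,
    pressure_grid,
    work_rate,
)
from .stokes import ChamberSolver

__all__ = ["TIERS", "SweepConfig", "simulate_period", "run_single", "run_sweep", "report", "run_from_manifest", "phi_band_count"]

#: Resolution tiers: mesh subdivision level, nodes per flagellum, beat
#: phases sampled per period, pressure-grid spacing (fraction of R).
TIERS = {
    "tiny": dict(subdivisions=2, reticulum_subdivisions=1, n_nodes=8, n_steps=5, cone_segments=12, pressure_spacing=0.1),
    "coarse": dict(subdivisions=2, reticulum_subdivisions=2, n_nodes=10, n_steps=50, cone_segments=24, pressure_spacing=0.05),
    "paper": dict(subdivisions=3, reticulum_subdivisions=2, n_nodes=20, n_steps=50, cone_segments=32, pressure_spacing=0.05),
}


@dataclass(frozen=True)
class SweepConfig:
    """One sweep axis plus held-fixed parameters and ensemble settings."""

    axis: str  # "n_flagella" | "rho" | "k_ell" | "theta_a"
    values: tuple
    radius: float = 1.5
    theta_a_deg: float = 30.0
    n_flagella: int = 143
    k_ell: float = 3.0 * np.pi
    amplitude: float = 0.14
    phi_band: tuple | None = None  # (lo, hi): adjust N to the band midpoint
    hold_density: bool = False  # rho sweeps: scale N to keep density fixed
    seeds: tuple = (0, 1, 2)
    tier: str = "coarse"
    n_steps: int | None = None
    outdir: str | None = None
    allow_outside_ranges: bool = False

    _RANGES = {
        "n_flagella": (1, 359),
        "rho": (1.5, 3.0),
        "k_ell": (1.5 * np.pi, 6.0 * np.pi),
        "theta_a": (10.0, 90.0),
    }

    def __post_init__(self):
        if self.axis not in self._RANGES:
            raise ValueError(f"unknown sweep axis {self.axis!r}")
        lo, hi = self._RANGES[self.axis]
        if not self.allow_outside_ranges:
            for v in self.values:
                if not lo <= v <= hi:
                    raise ValueError(
                        f"{self.axis} value {v} outside the study range [{lo}, {hi}]"
                    )


def phi_band_count(phi, radius, theta_a_deg, amplitude):
    """Flagellum count N that puts the coverage fraction at ``phi``."""
    ca = np.cos(np.radians(theta_a_deg))
    return max(1, int(round(phi * 2.0 * radius**2 * (1.0 + ca) / amplitude**2)))


def simulate_period(
    spec: ChamberSpec,
    waveform: WaveformParams,
    seed: int = 0,
    n_steps: int = 50,
    pressure_spacing: float = 0.05,
    eps_factor: float = 0.5,
    prosopyle_seed: int = 0,
) -> PumpMetrics:
    """Solve the resistance problem over one beat period and collect metrics."""
    mesh = build_chamber_mesh(spec, prosopyle_seed=prosopyle_seed)
    layout = place_flagella(spec, seed=seed)
    solver = ChamberSolver(mesh, layout, waveform, eps_factor=eps_factor)
    grid = pressure_grid(spec.radius, spacing=pressure_spacing * spec.radius)
    times = np.arange(n_steps) / n_steps
    Q = np.empty(n_steps)
    Pc = np.empty(n_steps)
    Pmax = np.empty(n_steps)
    W = np.empty(n_steps)
    for i, t in enumerate(times):
        sol = solver.solve(t=t)
        Q[i] = outlet_flow_rate(sol, mesh)
        Pc[i], Pmax[i] = max_pressure(sol, grid)
        W[i] = work_rate(sol)
    return PumpMetrics(
        times=times, Q=Q, Pc=Pc, Pmax=Pmax, W=W, seed=seed,
        meta={"n_flagella": spec.n_flagella, "radius": spec.radius,
              "theta_a_deg": spec.theta_a_deg, "k_ell": waveform.k_ell,
              "phi": spec.n_flagella * spec.amplitude**2
              / (2 * spec.radius**2 * (1 + np.cos(spec.theta_a)))},
    )


def _point_setup(config: SweepConfig, value):
    """ChamberSpec and WaveformParams for one grid point of a sweep."""
    tier = TIERS[config.tier]
    radius = config.radius
    theta = config.theta_a_deg
    n = config.n_flagella
    k_ell = config.k_ell
    if config.axis == "n_flagella":
        n = int(value)
    elif config.axis == "rho":
        radius = float(value)
        if config.hold_density:
            ca = np.cos(np.radians(theta))
            density = config.n_flagella / (
                2 * np.pi * config.radius**2 * (1 + ca)
            )
            n = max(1, int(round(density * 2 * np.pi * radius**2 * (1 + ca))))
    elif config.axis == "k_ell":
        k_ell = float(value)
    elif config.axis == "theta_a":
        theta = float(value)
    if config.phi_band is not None:
        phi_mid = 0.5 * (config.phi_band[0] + config.phi_band[1])
        n = phi_band_count(phi_mid, radius, theta, config.amplitude)
    spec = ChamberSpec(
        radius=radius,
        theta_a_deg=theta,
        n_flagella=n,
        amplitude=config.amplitude,
        subdivisions=tier["subdivisions"],
        reticulum_subdivisions=tier["reticulum_subdivisions"],
        cone_segments=tier["cone_segments"],
    )
    waveform = WaveformParams(
        amplitude=config.amplitude, k_ell=k_ell, n_nodes=tier["n_nodes"]
    )
    return spec, waveform


def run_single(config: SweepConfig, value, seed):
    tier = TIERS[config.tier]
    spec, waveform = _point_setup(config, value)
    n_steps = config.n_steps or tier["n_steps"]
    return simulate_period(
        spec, waveform, seed=seed, n_steps=n_steps,
        pressure_spacing=tier["pressure_spacing"],
    )


def run_sweep(config: SweepConfig, progress=None) -> pd.DataFrame:
    """Run every grid point x seed; returns one tidy row per (point, seed).

    With an output directory the per-point results and a JSON manifest are
    written and completed points are skipped on re-runs; a failing grid
    point is recorded (column ``error``) without aborting the sweep.
    """
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        manifest = {"config": _config_dict(config), "version": __version__,
                    "numpy": np.__version__}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    rows = []
    for value in config.values:
        fname = outdir / f"point_{config.axis}_{value:g}.csv" if outdir else None
        if fname and fname.exists():
            rows.append(pd.read_csv(fname))
            continue
        point_rows = []
        for seed in config.seeds:
            row = {"axis": config.axis, "value": value, "seed": seed}
            try:
                pm = run_single(config, value, seed)
                row.update(pm.summary())
                row["error"] = ""
            except Exception as exc:  # noqa: BLE001 - per-point fault isolation
                row["error"] = f"{type(exc).__name__}: {exc}"
                traceback.print_exc()
            point_rows.append(row)
            if progress:
                progress(f"{config.axis}={value} seed={seed}: {row.get('Q_bar', 'failed')}")
        point = pd.DataFrame(point_rows)
        if fname:
            point.to_csv(fname, index=False, float_format="%.17g")
        rows.append(point)
    return pd.concat(rows, ignore_index=True)


def _config_dict(config):
    d = asdict(config)
    d["values"] = list(d["values"])
    d["seeds"] = list(d["seeds"])
    if d["phi_band"] is not None:
        d["phi_band"] = list(d["phi_band"])
    return d


def run_from_manifest(path):
    """Re-run a sweep from its JSON manifest (determinism contract)."""
    manifest = json.loads(Path(path).read_text())
    cfg = manifest["config"]
    cfg["values"] = tuple(cfg["values"])
    cfg["seeds"] = tuple(cfg["seeds"])
    if cfg["phi_band"] is not None:
        cfg["phi_band"] = tuple(cfg["phi_band"])
    return run_sweep(SweepConfig(**cfg))


def report(results: pd.DataFrame) -> dict:
    """Figure-ready ensemble tables, one per pumping metric vs the axis."""
    if len(results) == 0:
        raise ValueError("empty sweep results")
    ok = results[results["error"] == ""] if "error" in results else results
    if len(ok) == 0:
        raise ValueError("all sweep points failed")
    tables = {}
    for metric in ("Q_bar", "W_bar", "Pmax_bar", "eta"):
        grp = ok.groupby("value")[metric]
        tables[metric] = pd.DataFrame(
            {"mean": grp.mean(), "sd": grp.std(ddof=1).fillna(0.0), "n": grp.size()}
        ).reset_index()
    return tables
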