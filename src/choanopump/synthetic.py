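"""Synthetic study inputs: morphometric tables and flagellar node tracks.

No external data are needed anywhere in the package; this module generates
the two kinds of measurement-like input used by the tests and examples:

* per-chamber morphometric records emulating microscopy of *E. muelleri*
  chambers (chamber and apopyle diameters, cell counts, beat frequency,
  waveform dimensions), drawn from truncated normal distributions around
  the published means and SDs, with positivity and ``d < D`` enforced by
  rejection (the study reports only means and SDs, so the distributional
  shape is an assumption);
* noisy flagellar waveform tracks: beat-plane node positions over one
  period from the kinematics model plus isotropic positional noise,
  emulating waveforms extracted from high-speed imaging, used to test
  recovery of the projected length, wavelength and amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import morphometrics
from .kinematics import WaveformParams, _local_nodes

__all__ = ["SyntheticSpec", "generate_morphometry", "generate_waveform_tracks"]

#: Published E. muelleri means and SDs (um, Hz, counts).
_DEFAULTS = {
    "chamber_diameter_um": (34.7, 5.0),
    "apopyle_diameter_um": (18.1, 4.3),
    "n_choanocytes": (112.0, 31.0),
    "beat_frequency_hz": (26.1, 8.9),
    "amplitude_um": (1.58, 0.21),
    "ell_um": (9.83, 0.74),
    "wavelength_um": (5.98, 0.48),
    "flagellum_length_um": (12.9, 1.1),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Number of chambers, per-column (mean, SD) pairs, and a seed."""

    n_chambers: int = 100
    moments: dict = field(default_factory=lambda: dict(_DEFAULTS))
    seed: int = 0
    sd_scale: float = 1.0  # scales every SD (0 gives noiseless tables)

    def __post_init__(self):
        if self.n_chambers < 1:
            raise ValueError("need at least one chamber")
        if self.moments["apopyle_diameter_um"][0] >= self.moments["chamber_diameter_um"][0]:
            raise ValueError("mean apopyle diameter must be below the chamber diameter")


def _truncated_normal(rng, mean, sd, n, lower=0.0):
    if sd == 0.0:
        return np.full(n, mean)
    out = np.empty(n)
    todo = np.arange(n)
    while len(todo):
        draw = rng.normal(mean, sd, len(todo))
        good = draw > lower
        out[todo[good]] = draw[good]
        todo = todo[~good]
    return out


def generate_morphometry(spec: SyntheticSpec) -> pd.DataFrame:
    """Seeded per-chamber morphometric table with derived columns.

    Columns follow the chamber-dimensions schema plus the derived opening
    angle ``theta_a_deg`` (from the two diameters), the flagellar surface
    density and the coverage fraction ``phi``.  Rows violating ``d < D``
    are redrawn, so the joint distribution is a rejection-truncated normal.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_chambers
    cols = {}
    for name, (mean, sd) in spec.moments.items():
        cols[name] = _truncated_normal(rng, mean, sd * spec.sd_scale, n)
    # enforce d < D by redrawing offending apopyle diameters
    bad = cols["apopyle_diameter_um"] >= cols["chamber_diameter_um"]
    while bad.any():
        cols["apopyle_diameter_um"][bad] = _truncated_normal(
            rng,
            spec.moments["apopyle_diameter_um"][0],
            spec.moments["apopyle_diameter_um"][1] * spec.sd_scale,
            int(bad.sum()),
        )
        bad = cols["apopyle_diameter_um"] >= cols["chamber_diameter_um"]
    cols["n_choanocytes"] = np.maximum(np.round(cols["n_choanocytes"]), 1.0)
    table = pd.DataFrame(cols)
    table.insert(0, "chamber", np.arange(n))
    table["theta_a_deg"] = [
        morphometrics.opening_angle(D, d)
        for D, d in zip(table["chamber_diameter_um"], table["apopyle_diameter_um"])
    ]
    table["density_per_um2"] = [
        morphometrics.flagellar_density(N, D / 2.0, th)
        for N, D, th in zip(
            table["n_choanocytes"], table["chamber_diameter_um"], table["theta_a_deg"]
        )
    ]
    table["phi"] = [
        morphometrics.coverage_fraction(N, A, D / 2.0, th)
        for N, A, D, th in zip(
            table["n_choanocytes"],
            table["amplitude_um"],
            table["chamber_diameter_um"],
            table["theta_a_deg"],
        )
    ]
    return table


def generate_waveform_tracks(
    params: WaveformParams = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_frames: int = 50,
    n_flagella: int = 1,
) -> pd.DataFrame:
    """Beat-plane node tracks over one period with isotropic position noise.

    Returns a tidy frame (flagellum, node, t, x, y) in model units; ``x`` is
    the axial coordinate (base at 0), ``y`` the lateral beat coordinate.
    ``noise_sd`` is in units of L.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if params is None:
        params = WaveformParams()
    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) / n_frames  # one period, T = 1
    rows = []
    for fi in range(n_flagella):
        phase = 0.0 if n_flagella == 1 else rng.uniform(0.0, 2.0 * np.pi)
        for t in times:
            x, y = _local_nodes(params, phase - params.omega * t)
            rows.append(
                pd.DataFrame(
                    {
                        "flagellum": fi,
                        "node": np.arange(params.n_nodes),
                        "t": t,
                        "x": x[0] + rng.normal(0.0, noise_sd, params.n_nodes),
                        "y": y[0] + rng.normal(0.0, noise_sd, params.n_nodes),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)
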