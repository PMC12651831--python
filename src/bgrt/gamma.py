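"""Gamma-index comparison of measured and planned dose distributions.

The gamma index combines a dose-difference tolerance (percent of the
normalisation dose) and a distance-to-agreement tolerance (mm): for each
reference point r,

    gamma(r) = min over evaluated positions e of
               sqrt( (D_e(e) - D_r(r))^2 / dD^2  +  |e - r|^2 / dta^2 ),

and a point passes when gamma <= 1.  With global normalisation dD is
``dose_pct`` percent of the reference maximum; points below the low-dose
cut-off (percent of the reference maximum) are excluded from statistics.
The evaluated distribution is linearly interpolated on a sub-voxel candidate
lattice (step = dta / 10) out to a capped search radius (3 x dta).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as iter_product

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class DoseGrid:
    """2D or 3D non-negative dose field with isotropic grid spacing in mm."""

    values: np.ndarray
    spacing_mm: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim not in (2, 3):
            raise ValueError("dose grids must be 2D or 3D")
        if min(self.values.shape) < 2:
            raise ValueError("each axis needs at least 2 samples")
        if self.spacing_mm <= 0:
            raise ValueError("spacing must be positive")
        if np.any(self.values < 0):
            raise ValueError("dose must be non-negative")

    @classmethod
    def from_csv(cls, path, spacing_mm: float = 1.0) -> "DoseGrid":
        return cls(pd.read_csv(path, header=None).to_numpy(dtype=float), spacing_mm)

    def to_csv(self, path) -> None:
        if self.values.ndim != 2:
            raise ValueError("CSV export is limited to 2D grids")
        pd.DataFrame(self.values).to_csv(path, header=False, index=False)


@dataclass
class GammaParams:
    """Gamma criteria: dose tolerance %, DTA mm, low-dose cut, normalisation."""

    dose_pct: float = 3.0
    dta_mm: float = 2.0
    low_dose_cut_pct: float = 10.0
    normalization: str = "global"
    search_radius_factor: float = 3.0
    step_divisor: int = 10

    def __post_init__(self) -> None:
        if min(self.dose_pct, self.dta_mm, self.low_dose_cut_pct) <= 0:
            raise ValueError("gamma parameters must be positive")
        if self.normalization not in ("global", "local"):
            raise ValueError("normalization must be 'global' or 'local'")
        if self.search_radius_factor <= 0 or self.step_divisor < 1:
            raise ValueError("invalid search settings")


def _candidate_offsets(ndim: int, p: GammaParams) -> np.ndarray:
    """Sub-voxel displacement lattice (mm), sorted by distance from origin."""
    step = p.dta_mm / p.step_divisor
    radius = p.search_radius_factor * p.dta_mm
    n = int(np.floor(radius / step))
    axis = np.arange(-n, n + 1) * step
    grids = np.meshgrid(*([axis] * ndim), indexing="ij")
    offsets = np.stack([g.ravel() for g in grids], axis=1)
    dist2 = (offsets**2).sum(axis=1)
    keep = dist2 <= radius**2 + 1e-12
    offsets, dist2 = offsets[keep], dist2[keep]
    order = np.argsort(dist2, kind="stable")
    return offsets[order]


def gamma_map(ref: DoseGrid, ev: DoseGrid, p: GammaParams) -> np.ndarray:
    """Gamma index at every reference point above the low-dose cut-off.

    Returns an array shaped like the reference grid with NaN below the
    cut-off.  The evaluated grid must coincide with the reference grid
    (same shape and spacing); candidate positions falling outside the
    evaluated grid are skipped.
    """
    if ref.values.shape != ev.values.shape or abs(ref.spacing_mm - ev.spacing_mm) > 1e-9:
        raise ValueError("reference and evaluated grids must coincide")
    ref_max = ref.values.max()
    if ref_max <= 0:
        raise ValueError("reference dose is identically zero")
    cut = p.low_dose_cut_pct / 100.0 * ref_max
    eval_mask = ref.values >= cut
    if not eval_mask.any():
        raise ValueError("no reference points above the low-dose cut-off")

    ndim = ref.values.ndim
    coords = np.argwhere(eval_mask).astype(float)  # voxel units
    ref_dose = ref.values[eval_mask]
    if p.normalization == "global":
        denom = p.dose_pct / 100.0 * ref_max
        denom = np.full(ref_dose.shape, denom)
    else:
        denom = p.dose_pct / 100.0 * ref_dose

    offsets = _candidate_offsets(ndim, p)
    shape = np.asarray(ev.values.shape, dtype=float)
    best = np.full(ref_dose.shape, np.inf)
    for off in offsets:
        dist2_term = (off @ off) / p.dta_mm**2
        if dist2_term >= best.max():
            break  # offsets are sorted by distance; no point can improve
        pos = coords + off[None, :] / ref.spacing_mm
        inside = np.all((pos >= 0) & (pos <= shape - 1), axis=1)
        if not inside.any():
            continue
        sampled = ndimage.map_coordinates(ev.values, pos[inside].T, order=1)
        dd = (sampled - ref_dose[inside]) / denom[inside]
        cand = dd**2 + dist2_term
        b = best[inside]
        best[inside] = np.minimum(b, cand)
    gamma = np.full(ref.values.shape, np.nan)
    gamma[eval_mask] = np.sqrt(best)
    return gamma


def pass_rate(gamma: np.ndarray) -> float:
    """Percent of evaluated (non-NaN) points with gamma <= 1."""
    valid = np.isfinite(gamma)
    if not valid.any():
        raise ValueError("gamma map has no evaluated points")
    return 100.0 * float((gamma[valid] <= 1.0).mean())


def summarize_pass_rates(rates) -> dict:
    """Mean / SD / min / max of a collection of pass rates (percent)."""
    arr = np.asarray(list(rates), dtype=float)
    if arr.size == 0:
        raise ValueError("no pass rates given")
    return {
        "n": int(arr.size),
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "min": float(arr.min()),
        "max": float(arr.max()),
    }


#: Measured delivery-verification pass rates (%) for the 13 deliverable
#: configurations of the six-sphere phantom study, keyed by
#: (TBR, sphere diameter mm) and holding (3%/2 mm, 3%/3 mm) values.
#: Sub-centimetre spheres were never deliverable and are absent.
PHANTOM_DELIVERY_PASS_RATES = {
    (5, 16): (89.7, 93.8),
    (5, 20): (91.7, 96.0),
    (10, 13): (86.0, 96.4),
    (10, 16): (99.2, 100.0),
    (10, 20): (94.1, 97.6),
    (15, 11): (93.4, 99.7),
    (15, 13): (100.0, 100.0),
    (15, 16): (91.9, 98.0),
    (15, 20): (89.9, 96.1),
    (20, 11): (91.6, 97.7),
    (20, 13): (81.9, 95.7),
    (20, 16): (97.0, 100.0),
    (20, 20): (94.4, 97.6),
}
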