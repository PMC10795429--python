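"""Dose-comparison toolkit: depth-dose/lateral profiles, R80 and its
difference, per-voxel relative error, beam centre of mass, and the 3D
gamma index.

Conventions: the gamma dose criterion is global (a percentage of the
reference maximum), voxels below the low-dose threshold (default 10% of
the reference maximum) are excluded, and the neighbourhood search is an
exhaustive voxel-grid scan out to three distance-criteria with no
subvoxel interpolation. The centre of mass is the dose-weighted mean
coordinate (normalized by total dose); the voxel-count normalization is
available behind ``as_printed`` for comparison with conventions that
divide by N, but it is not translation-consistent and is not the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np


@dataclass
class DepthDoseProfile:
    """Transversally integrated dose versus depth."""

    depth_mm: np.ndarray
    dose: np.ndarray

    def __post_init__(self):
        self.depth_mm = np.asarray(self.depth_mm, float)
        self.dose = np.asarray(self.dose, float)
        if self.depth_mm.size != self.dose.size:
            raise ValueError("depth and dose lengths differ")
        if np.any(np.diff(self.depth_mm) <= 0):
            raise ValueError("depths must be strictly increasing")


@dataclass(frozen=True)
class GammaParams:
    dose_percent: float = 2.0     # % of the global reference maximum
    dta_mm: float = 2.0           # distance-to-agreement criterion
    low_dose_threshold: float = 0.10  # fraction of reference maximum

    def __post_init__(self):
        if self.dose_percent <= 0 or self.dta_mm <= 0 or self.low_dose_threshold <= 0:
            raise ValueError("gamma parameters must be positive")


def depth_dose(dose3d, spacing, axis=2):
    """Integrated depth-dose profile along ``axis`` (voxel-centre depths)."""
    dose3d = np.asarray(dose3d, float)
    other = tuple(a for a in range(dose3d.ndim) if a != axis)
    prof = dose3d.sum(axis=other)
    depths = (np.arange(prof.size) + 0.5) * spacing[axis]
    return DepthDoseProfile(depths, prof)


def lateral_profile(dose3d, spacing, depth_mm, axis=2, lateral_axis=0):
    """Lateral profile at the slice containing ``depth_mm``."""
    dose3d = np.asarray(dose3d, float)
    iz = int(depth_mm / spacing[axis])
    iz = min(max(iz, 0), dose3d.shape[axis] - 1)
    sl = np.take(dose3d, iz, axis=axis)
    sum_axis = 1 if lateral_axis == 0 else 0
    prof = sl.sum(axis=sum_axis)
    coords = (np.arange(prof.size) + 0.5) * spacing[lateral_axis]
    return coords, prof


def r80(profile: DepthDoseProfile):
    """Depth (mm) of the 80%-of-maximum crossing on the distal falloff,
    by linear interpolation between the bracketing samples."""
    d = profile.dose
    imax = int(np.argmax(d))
    target = 0.8 * d[imax]
    for i in range(imax, d.size - 1):
        if d[i] >= target > d[i + 1]:
            f = (d[i] - target) / (d[i] - d[i + 1])
            return float(profile.depth_mm[i]
                         + f * (profile.depth_mm[i + 1] - profile.depth_mm[i]))
    raise ValueError("no distal R80: falloff never crosses 80% of maximum")


def delta_r80(p1: DepthDoseProfile, p2: DepthDoseProfile):
    """Signed R80 difference R80(p1) - R80(p2) in mm."""
    return r80(p1) - r80(p2)


def rel_error(d1, d2, threshold=0.10):
    """Per-voxel relative error 2(d1-d2)/(d1+d2) and its mean over the
    region where the reference d1 exceeds ``threshold`` of its maximum.

    Voxels where both doses vanish are excluded (set to 0 in the map).
    """
    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    if d1.shape != d2.shape:
        raise ValueError("dose arrays must have identical shapes")
    s = d1 + d2
    with np.errstate(divide="ignore", invalid="ignore"):
        eps = np.where(s > 0, 2.0 * (d1 - d2) / np.where(s > 0, s, 1.0), 0.0)
    sel = (d1 > threshold * d1.max()) & (s > 0)
    mean = float(np.abs(eps[sel]).mean()) if np.any(sel) else 0.0
    return eps, mean


def com(dose, coords=None, axis=0, spacing=None, as_printed=False):
    """Dose-weighted centre of mass (mm) along ``axis``.

    ``coords`` are the voxel-centre positions along the axis; when
    omitted they are built from ``spacing``. With ``as_printed`` the sum
    is divided by the number of voxels instead of the total dose (a
    convention that is not translation-consistent; kept for comparison).
    """
    dose = np.asarray(dose, float)
    if dose.ndim > 1:
        other = tuple(a for a in range(dose.ndim) if a != axis)
        prof = dose.sum(axis=other)
    else:
        prof = dose
    if coords is None:
        if spacing is None:
            raise ValueError("provide coords or spacing")
        coords = (np.arange(prof.size) + 0.5) * spacing
    coords = np.asarray(coords, float)
    tot = prof.sum()
    if tot <= 0:
        raise ValueError("zero total dose")
    if as_printed:
        return float((coords * prof).sum() / prof.size)
    return float((coords * prof).sum() / tot)


def gamma_pass_rate(reference, evaluated, spacing, params: GammaParams,
                    local=False):
    """Global 3D gamma analysis.

    For every reference voxel above the low-dose threshold,
    gamma = min over evaluated voxels within 3*dta of
    sqrt((dd/(p*Dmax))^2 + (dr/dta)^2); a voxel passes when gamma <= 1.
    Returns (pass rate in percent, per-voxel gamma map with NaN outside
    the evaluated region).

    With ``local`` the dose criterion is a fraction of the local
    reference dose instead of the global maximum.
    """
    ref = np.asarray(reference, float)
    ev = np.asarray(evaluated, float)
    if ref.shape != ev.shape:
        raise ValueError("dose grids must be co-registered (same shape)")
    if ref.ndim == 1:
        ref = ref[:, None, None]
        ev = ev[:, None, None]
        spacing = (spacing[0] if hasattr(spacing, "__len__") else spacing,
                   1.0, 1.0)
    dmax = ref.max()
    if dmax <= 0:
        raise ValueError("reference dose is identically zero")
    dd_abs = params.dose_percent / 100.0 * dmax
    dta = params.dta_mm
    mask = ref >= params.low_dose_threshold * dmax

    radius = 3.0 * dta
    offsets = []
    nmax = [int(np.floor(radius / s)) for s in spacing[:ref.ndim]]
    for off in product(*(range(-n, n + 1) for n in nmax)):
        r2 = sum((o * s) ** 2 for o, s in zip(off, spacing))
        if r2 <= radius * radius:
            offsets.append((off, r2))
    offsets.sort(key=lambda t: t[1])

    gamma2 = np.full(ref.shape, np.inf)
    denom = (params.dose_percent / 100.0) * np.maximum(ref, 1e-300) \
        if local else dd_abs
    for off, r2 in offsets:
        shifted = _shift(ev, off)
        with np.errstate(invalid="ignore"):
            g2 = ((shifted - ref) / denom) ** 2 + r2 / dta**2
        g2 = np.where(np.isnan(shifted), np.inf, g2)
        np.minimum(gamma2, g2, out=gamma2)

    gamma = np.sqrt(gamma2)
    n_eval = int(mask.sum())
    n_pass = int((gamma[mask] <= 1.0).sum())
    rate = 100.0 * n_pass / n_eval if n_eval else 100.0
    gamma_map = np.where(mask, gamma, np.nan)
    return rate, gamma_map


def _shift(arr, off):
    """Shift with NaN fill (out-of-grid evaluated points contribute
    nothing to the minimum)."""
    out = np.full_like(arr, np.nan)
    src = [slice(None)] * arr.ndim
    dst = [slice(None)] * arr.ndim
    for ax, o in enumerate(off):
        n = arr.shape[ax]
        if abs(o) >= n:
            return out
        if o >= 0:
            dst[ax] = slice(0, n - o)
            src[ax] = slice(o, n)
        else:
            dst[ax] = slice(-o, n)
            src[ax] = slice(0, n + o)
    out[tuple(dst)] = arr[tuple(src)]
    return out
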