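"""Voxelized phantom geometry and exact ray/voxel-boundary queries.

Coordinates are phantom-local millimetres. Voxels are half-open boxes
[lower, upper) along each axis, indexed from zero; a point exactly on a
shared interior face belongs to the voxel on the upper side. The phantom
is persisted as raw little-endian arrays plus a JSON sidecar so tests and
runs are bit-exact across platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

PHANTOM_FORMAT_VERSION = 1

OUTSIDE = (-1, -1, -1)


@dataclass
class VoxelPhantom:
    dims: tuple                 # (nx, ny, nz)
    spacing: tuple              # (dx, dy, dz) mm
    material_index: np.ndarray  # (nx, ny, nz) int16
    density: np.ndarray         # (nx, ny, nz) float64, g/cm^3
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.dims = tuple(int(d) for d in self.dims)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(d < 1 for d in self.dims):
            raise ValueError("dims must each be >= 1")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")
        self.material_index = np.ascontiguousarray(self.material_index,
                                                   dtype=np.int16)
        self.density = np.ascontiguousarray(self.density, dtype=np.float64)
        if self.material_index.shape != self.dims or self.density.shape != self.dims:
            raise ValueError("array shapes must match dims")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")

    @property
    def extent(self):
        """Upper corner (mm), exclusive."""
        return tuple(o + n * s for o, n, s in
                     zip(self.origin, self.dims, self.spacing))

    @property
    def voxel_volume_cm3(self):
        dx, dy, dz = self.spacing
        return dx * dy * dz * 1e-3

    @classmethod
    def uniform(cls, dims, spacing, material_id, density, origin=(0.0, 0.0, 0.0)):
        mat = np.full(dims, material_id, dtype=np.int16)
        rho = np.full(dims, float(density))
        return cls(dims, spacing, mat, rho, origin)


@dataclass(frozen=True)
class MagneticField:
    """Uniform magnetic field over the phantom (Tesla)."""

    B: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        if not np.all(np.isfinite(self.B)):
            raise ValueError("field components must be finite")

    @property
    def vector(self):
        return np.asarray(self.B, dtype=float)


def locate(pos, phantom: VoxelPhantom):
    """Voxel index triple containing ``pos``, or OUTSIDE.

    Indices are floor-based with half-open intervals, so a point on an
    interior face belongs to the upper neighbour and a point exactly on
    the phantom's upper boundary is OUTSIDE.
    """
    idx = []
    for c, o, s, n in zip(pos, phantom.origin, phantom.spacing, phantom.dims):
        i = int(np.floor((c - o) / s))
        if i < 0 or i >= n:
            return OUTSIDE
        idx.append(i)
    return tuple(idx)


def distance_to_voxel_boundary(pos, direction, phantom: VoxelPhantom):
    """Distance (mm) from ``pos`` along unit vector ``direction`` to the
    first voxel face.

    ``pos`` must lie inside the phantom; the caller (the transport loop)
    is responsible for nudging the particle off the face it just crossed.
    """
    v = locate(pos, phantom)
    if v == OUTSIDE:
        raise ValueError(f"position {tuple(pos)} is outside the phantom "
                         "(transport bookkeeping bug)")
    best = np.inf
    for axis in range(3):
        d = direction[axis]
        if abs(d) < 1e-12:  # effectively parallel to this face pair
            continue
        o, s = phantom.origin[axis], phantom.spacing[axis]
        if d > 0:
            bound = o + (v[axis] + 1) * s
        else:
            bound = o + v[axis] * s
        t = (bound - pos[axis]) / d
        if t <= 0.0:  # numerically on the face; step a full voxel
            t += s / abs(d)
        best = min(best, t)
    if not np.isfinite(best):
        raise ValueError("direction vector is zero")
    return best


# ---------------------------------------------------------------------------
# Persistence: raw arrays + JSON sidecar
# ---------------------------------------------------------------------------

def save_phantom(phantom: VoxelPhantom, basepath):
    """Write ``<base>.json`` sidecar plus ``<base>.mat.raw`` (int16 LE) and
    ``<base>.rho.raw`` (float32 LE), C-order with x fastest-varying last."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    sidecar = {
        "format_version": PHANTOM_FORMAT_VERSION,
        "dims": list(phantom.dims),
        "spacing_mm": list(phantom.spacing),
        "origin_mm": list(phantom.origin),
        "material_dtype": "<i2",
        "density_dtype": "<f4",
        "order": "C",
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    phantom.material_index.astype("<i2").tofile(base.with_suffix(".mat.raw"))
    phantom.density.astype("<f4").tofile(base.with_suffix(".rho.raw"))


def save_volume(array, spacing, basepath, origin=(0.0, 0.0, 0.0)):
    """Write a scalar volume (dose, gamma map, ...) as ``<base>.json`` +
    ``<base>.f64.raw`` (float64 LE, C order)."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    arr = np.ascontiguousarray(array, dtype="<f8")
    sidecar = {
        "format_version": PHANTOM_FORMAT_VERSION,
        "dims": list(arr.shape),
        "spacing_mm": list(spacing),
        "origin_mm": list(origin),
        "dtype": "<f8",
        "order": "C",
    }
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    arr.tofile(base.with_suffix(".f64.raw"))


def load_volume(basepath):
    """Read a scalar volume; returns (array, spacing, origin)."""
    base = Path(basepath)
    sidecar = json.loads(base.with_suffix(".json").read_text())
    if sidecar.get("format_version") != PHANTOM_FORMAT_VERSION:
        raise ValueError(f"unsupported volume format version "
                         f"{sidecar.get('format_version')}")
    arr = np.fromfile(base.with_suffix(".f64.raw"),
                      dtype=sidecar["dtype"]).reshape(tuple(sidecar["dims"]))
    return arr, tuple(sidecar["spacing_mm"]), tuple(sidecar["origin_mm"])


def load_phantom(basepath) -> VoxelPhantom:
    base = Path(basepath)
    sidecar = json.loads(base.with_suffix(".json").read_text())
    if sidecar.get("format_version") != PHANTOM_FORMAT_VERSION:
        raise ValueError(f"unsupported phantom format version "
                         f"{sidecar.get('format_version')}")
    dims = tuple(sidecar["dims"])
    mat = np.fromfile(base.with_suffix(".mat.raw"),
                      dtype=sidecar["material_dtype"]).reshape(dims)
    rho = np.fromfile(base.with_suffix(".rho.raw"),
                      dtype=sidecar["density_dtype"]).reshape(dims).astype(np.float64)
    return VoxelPhantom(dims, tuple(sidecar["spacing_mm"]), mat, rho,
                        tuple(sidecar["origin_mm"]))
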