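"""Benchmark phantom presets.

All presets share the benchmark geometry: 10.2 x 10.2 x 30 cm^3 with
2 x 2 x 1 mm voxels (51 x 51 x 300), beam axis along z. The
inhomogeneous preset embeds a 5 x 5 x 5 cm^3 bone box and an equal lung
box in water, both starting at 50 mm depth and laterally separated
(side by side across x, one voxel apart). ``water_shifter`` adds a 20 mm
PMMA range-shifter slab at the entrance, which enables the 10 mm step
cap inside it.
"""

from __future__ import annotations

import numpy as np

from .geometry import VoxelPhantom
from .materials import build_default_registry

PRESET_DIMS = (51, 51, 300)
PRESET_SPACING = (2.0, 2.0, 1.0)

PRESET_NAMES = ("water", "bone", "tissue", "inhomogeneous", "water_shifter")


def build_phantom_preset(name: str) -> VoxelPhantom:
    _, materials, _ = build_default_registry()
    ids = {m.name: m for m in materials}
    water = ids["water"]

    def uniform(mat, rho):
        return VoxelPhantom.uniform(PRESET_DIMS, PRESET_SPACING, mat.id, rho)

    if name == "water":
        return uniform(water, 1.00)
    if name == "bone":
        return uniform(ids["cortical_bone"], 1.85)
    if name == "tissue":
        return uniform(ids["soft_tissue"], 1.15)
    if name == "inhomogeneous":
        ph = uniform(water, 1.00)
        bone, lung = ids["cortical_bone"], ids["lung"]
        z = slice(50, 100)        # 50 mm depth, 50 mm thick
        y = slice(13, 38)         # 25 voxels, centred
        ph.material_index[0:25, y, z] = bone.id
        ph.density[0:25, y, z] = 1.85
        ph.material_index[26:51, y, z] = lung.id
        ph.density[26:51, y, z] = 0.40
        return ph
    if name == "water_shifter":
        ph = uniform(water, 1.00)
        pmma = ids["pmma"]
        ph.material_index[:, :, 0:20] = pmma.id
        ph.density[:, :, 0:20] = pmma.default_density
        return ph
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
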