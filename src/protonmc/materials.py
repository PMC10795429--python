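"""Element/material registry, HU conversion, and physics-table generation.

The transport loop never evaluates a formula per step; it consumes tables
built here: restricted mass stopping power, cumulative range, the
macroscopic delta-production cross-section (mass-normalized), and
microscopic elastic/inelastic nuclear cross-sections per element, all on a
common grid of 600 evenly spaced kinetic energies from 0.5 to 300 MeV.

Mass-normalized quantities are density-independent: two materials sharing
an elemental composition share identical tables and differ only by the
density factor applied at lookup time.

The stopping-power generator is an analytic restricted Bethe-Bloch with
mean excitation energies combined by Bragg additivity; the density-effect
and shell corrections are omitted (see docs/methods.md).  Nuclear
cross-sections are smooth parameterized fits with physically reasonable
magnitudes and trends; the file schema allows dropping in externally
derived tables without code changes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import h5py
import numpy as np

from .constants import K_BETHE, M_E, M_P, N_A

log = logging.getLogger(__name__)

TABLE_FORMAT_VERSION = 1

# Energy grid: 600 evenly spaced kinetic energies, 0.5 to 300 MeV.
E_GRID_MIN = 0.5
E_GRID_MAX = 300.0
E_GRID_N = 600

#: Global delta-ray production threshold (MeV); collisions transferring
#: more than this are simulated discretely, softer ones continuously.
TECUT_DEFAULT = 0.1


# ---------------------------------------------------------------------------
# Registry types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Element:
    """A chemical element: Z, molar mass, mean excitation energy,
    and mass radiation length."""

    symbol: str
    Z: int
    A: float        # g/mol
    I: float        # eV
    X0_mass: float  # g/cm^2

    def __post_init__(self):
        if self.Z < 1 or self.A <= 0 or self.I <= 0:
            raise ValueError(f"invalid element {self.symbol}")


@dataclass(frozen=True)
class Material:
    id: int
    name: str
    default_density: float            # g/cm^3
    weights: dict = field(default_factory=dict)  # symbol -> mass fraction
    is_range_shifter: bool = False

    def __post_init__(self):
        s = sum(self.weights.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"material {self.name}: weights sum to {s}")
        if self.default_density <= 0:
            raise ValueError(f"material {self.name}: non-positive density")


@dataclass(frozen=True)
class HUConversionTable:
    """Piecewise-linear density ramp plus material bins over HU.

    ``density_anchors`` is a list of (HU, g/cm^3) pairs with strictly
    increasing HU and non-decreasing density; ``composition_bins`` is a
    list of (HU lower edge, material id), each bin extending to the next
    edge (the last to the table's upper span).
    """

    density_anchors: tuple
    composition_bins: tuple
    hu_min: float = -1024.0
    hu_max: float = 3000.0

    def __post_init__(self):
        hu = [a[0] for a in self.density_anchors]
        if any(b <= a for a, b in zip(hu, hu[1:])):
            raise ValueError("HU anchors must be strictly increasing")
        rho = [a[1] for a in self.density_anchors]
        if any(r < 0 for r in rho) or any(b < a for a, b in zip(rho, rho[1:])):
            raise ValueError("density ramp must be non-negative and non-decreasing")


def hu_to_material(hu: float, table: HUConversionTable):
    """Convert one Hounsfield unit to (density g/cm^3, material id).

    Out-of-span HU values are clamped to the nearest breakpoint with a
    logged warning.
    """
    if hu < table.hu_min or hu > table.hu_max:
        log.warning("HU %.1f outside [%g, %g]; clamping", hu, table.hu_min, table.hu_max)
        hu = min(max(hu, table.hu_min), table.hu_max)
    xs = np.array([a[0] for a in table.density_anchors])
    ys = np.array([a[1] for a in table.density_anchors])
    density = float(np.interp(hu, xs, ys))
    mat_id = table.composition_bins[0][1]
    for lo, mid in table.composition_bins:
        if hu >= lo:
            mat_id = mid
        else:
            break
    return density, mat_id


# ---------------------------------------------------------------------------
# Default registry: 13 elements, 24 materials
# ---------------------------------------------------------------------------

_ELEMENT_DATA = [
    # symbol  Z   A (g/mol)  I (eV)  X0 (g/cm^2)
    ("H",  1, 1.008, 19.2, 63.04),
    ("C",  6, 12.011, 78.0, 42.70),
    ("N",  7, 14.007, 82.0, 37.99),
    ("O",  8, 15.999, 95.0, 34.24),
    ("Na", 11, 22.990, 149.0, 27.74),
    ("Mg", 12, 24.305, 156.0, 25.03),
    ("P",  15, 30.974, 173.0, 21.21),
    ("S",  16, 32.06, 180.0, 19.50),
    ("Cl", 17, 35.45, 174.0, 19.28),
    ("Ar", 18, 39.948, 188.0, 19.55),
    ("K",  19, 39.098, 190.0, 17.32),
    ("Ca", 20, 40.078, 191.0, 16.14),
    ("Fe", 26, 55.845, 286.0, 13.84),
]

# Tissue compositions are standard-compilation-inspired mass fractions,
# renormalized exactly to 1 at build time.
_SOFT_TISSUE_W = {"H": .105, "C": .256, "N": .027, "O": .602, "Na": .001,
                  "P": .002, "S": .003, "Cl": .002, "K": .002}
_CORTICAL_BONE_W = {"H": .034, "C": .155, "N": .042, "O": .435, "Na": .001,
                    "Mg": .002, "P": .103, "S": .003, "Ca": .225}

_MATERIAL_DATA = [
    # name, density, weights, shifter
    ("air", 0.00120, {"N": .755, "O": .232, "Ar": .013}, False),
    ("lung", 0.40, {"H": .103, "C": .105, "N": .031, "O": .749, "Na": .002,
                    "P": .002, "S": .003, "Cl": .003, "K": .002}, False),
    ("lung_inflated", 0.26, {"H": .103, "C": .105, "N": .031, "O": .749, "Na": .002,
                             "P": .002, "S": .003, "Cl": .003, "K": .002}, False),
    ("adipose", 0.95, {"H": .114, "C": .598, "N": .007, "O": .278, "Na": .001,
                       "S": .001, "Cl": .001}, False),
    ("water", 1.00, {"H": 1.008 * 2, "O": 15.999}, False),  # stoichiometric H2O
    ("soft_tissue", 1.15, _SOFT_TISSUE_W, False),
    ("muscle", 1.05, {"H": .102, "C": .143, "N": .034, "O": .710, "Na": .001,
                      "P": .002, "S": .003, "Cl": .001, "K": .004}, False),
    ("skin", 1.09, {"H": .100, "C": .204, "N": .042, "O": .645, "Na": .002,
                    "P": .001, "S": .002, "Cl": .003, "K": .001}, False),
    ("blood", 1.06, {"H": .102, "C": .110, "N": .033, "O": .745, "Na": .001,
                     "P": .001, "S": .002, "Cl": .003, "K": .002, "Fe": .001}, False),
    ("liver", 1.06, {"H": .102, "C": .139, "N": .030, "O": .716, "Na": .002,
                     "P": .003, "S": .003, "Cl": .002, "K": .003}, False),
    ("brain", 1.04, {"H": .107, "C": .145, "N": .022, "O": .712, "Na": .002,
                     "P": .004, "S": .002, "Cl": .003, "K": .003}, False),
    ("eye_lens", 1.07, {"H": .096, "C": .195, "N": .057, "O": .646, "Na": .001,
                        "P": .001, "S": .003, "Cl": .001}, False),
    ("cartilage", 1.10, {"H": .096, "C": .099, "N": .022, "O": .744, "Na": .005,
                         "P": .022, "S": .009, "Cl": .003}, False),
    ("red_marrow", 1.03, {"H": .105, "C": .414, "N": .034, "O": .439, "P": .001,
                          "S": .002, "Cl": .002, "K": .002, "Fe": .001}, False),
    ("yellow_marrow", 0.98, {"H": .115, "C": .644, "N": .007, "O": .231,
                             "Na": .001, "S": .001, "Cl": .001}, False),
    ("spongiosa", 1.18, {"H": .085, "C": .404, "N": .028, "O": .367, "Na": .001,
                         "Mg": .001, "P": .034, "S": .002, "Cl": .002, "K": .001,
                         "Ca": .074, "Fe": .001}, False),
    ("cortical_bone", 1.85, _CORTICAL_BONE_W, False),
    ("pmma", 1.19, {"H": .0805, "C": .5998, "O": .3196}, True),  # range shifter
]


def _bone_mix(f: float) -> dict:
    """Mass-fraction mixture of cortical bone (fraction f) and soft tissue."""
    w = {}
    for sym in set(_CORTICAL_BONE_W) | set(_SOFT_TISSUE_W):
        w[sym] = f * _CORTICAL_BONE_W.get(sym, 0.0) + (1 - f) * _SOFT_TISSUE_W.get(sym, 0.0)
    return w

# HU-binned skeletal mixtures (Schneider-style bone segmentation).
_BONE_BINS = [
    ("bone_mix_15", 1.25, 0.15), ("bone_mix_30", 1.38, 0.30),
    ("bone_mix_45", 1.51, 0.45), ("bone_mix_60", 1.64, 0.60),
    ("bone_mix_75", 1.77, 0.75), ("bone_mix_90", 1.90, 0.90),
]


def _normalized(w: dict) -> dict:
    s = sum(w.values())
    out = {k: v / s for k, v in w.items()}
    # force exact unit sum despite rounding
    key = max(out, key=out.get)
    out[key] += 1.0 - sum(out.values())
    return out


def build_default_registry():
    """Return the predefined (elements, materials, hu_table).

    Exactly 13 elements and 24 materials; every material's weights
    reference registered elements and sum to one.
    """
    elements = [Element(*row) for row in _ELEMENT_DATA]
    symbols = {e.symbol for e in elements}

    rows = list(_MATERIAL_DATA) + [(n, d, _bone_mix(f), False) for n, d, f in _BONE_BINS]
    materials = []
    for i, (name, rho, w, shifter) in enumerate(rows):
        w = _normalized(w)
        unknown = set(w) - symbols
        if unknown:
            raise ValueError(f"material {name} references unknown elements {unknown}")
        materials.append(Material(i, name, rho, w, shifter))
    assert len(elements) == 13 and len(materials) == 24

    ids = {m.name: m.id for m in materials}
    hu_table = HUConversionTable(
        density_anchors=(
            (-1024.0, 0.00121), (-1000.0, 0.00121), (-950.0, 0.102),
            (-120.0, 0.95), (0.0, 1.00), (100.0, 1.10), (300.0, 1.25),
            (1600.0, 1.90), (3000.0, 2.60),
        ),
        composition_bins=(
            (-1024.0, ids["air"]), (-950.0, ids["lung"]),
            (-120.0, ids["adipose"]), (-20.0, ids["water"]),
            (20.0, ids["soft_tissue"]), (80.0, ids["muscle"]),
            (120.0, ids["cartilage"]), (300.0, ids["bone_mix_15"]),
            (500.0, ids["bone_mix_30"]), (700.0, ids["bone_mix_45"]),
            (900.0, ids["bone_mix_60"]), (1100.0, ids["bone_mix_75"]),
            (1300.0, ids["bone_mix_90"]), (1600.0, ids["cortical_bone"]),
        ),
    )
    return elements, materials, hu_table


# ---------------------------------------------------------------------------
# Electromagnetic formulae (table generators)
# ---------------------------------------------------------------------------

def kinematics(T):
    """Return (beta2, gamma, tmax) for a proton of kinetic energy T (MeV).

    tmax is the exact kinematic maximum energy transferable to a free
    electron in a single collision.
    """
    T = np.asarray(T, dtype=float)
    gamma = 1.0 + T / M_P
    beta2 = 1.0 - 1.0 / gamma**2
    ratio = M_E / M_P
    tmax = 2.0 * M_E * beta2 * gamma**2 / (1.0 + 2.0 * gamma * ratio + ratio**2)
    return beta2, gamma, tmax


def mass_stopping_power(weights, elements_by_symbol, T, tecut=None):
    """Bethe-Bloch mass stopping power (MeV cm^2/g) of a mixture.

    ``tecut`` restricts the collision spectrum to transfers below
    min(tecut, tmax); ``None`` gives the unrestricted stopping power.
    Density-effect and shell corrections are omitted.
    """
    beta2, gamma, tmax = kinematics(T)
    tup = tmax if tecut is None else np.minimum(tecut, tmax)
    L = np.zeros_like(np.asarray(T, dtype=float))
    for sym, w in weights.items():
        el = elements_by_symbol[sym]
        I_mev = el.I * 1e-6
        arg = 2.0 * M_E * beta2 * gamma**2 * tup / I_mev**2
        term = 0.5 * np.log(arg) - 0.5 * beta2 * (1.0 + tup / tmax)
        L = L + K_BETHE * (el.Z / el.A) / beta2 * w * term
    return L


def delta_production_xs_mass(weights, elements_by_symbol, T, tecut=TECUT_DEFAULT):
    """Mass-normalized macroscopic delta-production cross-section (cm^2/g).

    Integral of the Rutherford single-collision spectrum with the
    (1 - beta^2 T/Tmax) factor from tecut to the kinematic maximum; zero
    whenever the maximum transfer is below the threshold.
    """
    beta2, _, tmax = kinematics(T)
    zoa = sum(w * elements_by_symbol[s].Z / elements_by_symbol[s].A
              for s, w in weights.items())
    with np.errstate(divide="ignore", invalid="ignore"):
        integral = (1.0 / tecut - 1.0 / tmax
                    - beta2 / tmax * np.log(tmax / tecut))
    sig = 0.5 * K_BETHE * zoa / beta2 * integral
    return np.where(tmax > tecut, np.maximum(sig, 0.0), 0.0)


def bohr_variance_per_cm(weights, elements_by_symbol, T, tecut=TECUT_DEFAULT):
    """Variance of the sub-threshold continuous energy loss per unit
    rho*dx (MeV^2 cm^2/g).

    Second moment of the Rutherford spectrum up to min(tecut, tmax); with
    no restriction this reduces to the classical Bohr expression
    4 pi r_e^2 (m_e c^2)^2 n_e dx times the relativistic factor
    gamma^2 (1 - beta^2/2).
    """
    beta2, _, tmax = kinematics(T)
    tup = np.minimum(tecut, tmax)
    zoa = sum(w * elements_by_symbol[s].Z / elements_by_symbol[s].A
              for s, w in weights.items())
    return 0.5 * K_BETHE * zoa / beta2 * tup * (1.0 - beta2 * tup / (2.0 * tmax))


# ---------------------------------------------------------------------------
# Nuclear cross-section fits (microscopic, barn)
# ---------------------------------------------------------------------------

def sigma_elastic_barn(element: Element, T):
    """Microscopic elastic nuclear cross-section fit (barn).

    For hydrogen this is free p-p elastic scattering (falling roughly as a
    power of energy towards ~20 mb at 300 MeV); for heavier nuclei a
    geometric A^(2/3) scale with a smooth energy decline.  These are
    documented placeholder fits in the correct schema, not evaluated
    nuclear data.
    """
    T = np.asarray(T, dtype=float)
    if element.symbol == "H":
        sig_mb = 20.0 + 2.5e3 / np.maximum(T, 1.0) ** 0.9
    else:
        a23 = element.A ** (2.0 / 3.0)
        sig_mb = a23 * (18.0 + 320.0 / np.maximum(T, 1.0) ** 0.7)
    return sig_mb * 1e-3  # mb -> barn


def sigma_inelastic_barn(element: Element, T):
    """Microscopic inelastic nuclear cross-section fit (barn).

    Zero for hydrogen below the pion threshold; for heavier nuclei a
    threshold rise from ~7 MeV to a broad plateau scaled by A^(2/3).
    Placeholder fit, same caveat as the elastic one.
    """
    T = np.asarray(T, dtype=float)
    if element.symbol == "H":
        return np.zeros_like(T)
    a23 = element.A ** (2.0 / 3.0)
    thresh = 7.0
    rise = 1.0 - np.exp(-np.maximum(T - thresh, 0.0) / 12.0)
    hump = 1.0 + 0.6 * np.exp(-((T - 35.0) / 30.0) ** 2)
    sig_mb = 52.0 * a23 * rise * hump
    return np.where(T > thresh, sig_mb, 0.0) * 1e-3


# ---------------------------------------------------------------------------
# MaterialTableSet
# ---------------------------------------------------------------------------

class MaterialTableSet:
    """All per-material / per-element physics tables on the common grid.

    Arrays (float64):
      energy_grid    (n,)          kinetic energies, MeV
      L_mass         (nmat, n)     restricted mass stopping power, MeV cm^2/g
      range_mass     (nmat, n)     cumulative range, g/cm^2 (zero at grid start)
      sig_ion_mass   (nmat, n)     delta-production macroscopic xs / rho, cm^2/g
      sigma_el       (nelem, n)    microscopic elastic nuclear xs, barn
      sigma_inel     (nelem, n)    microscopic inelastic nuclear xs, barn
    """

    def __init__(self, elements, materials, tecut=TECUT_DEFAULT,
                 energy_grid=None, L_mass=None, range_mass=None,
                 sig_ion_mass=None, sigma_el=None, sigma_inel=None):
        self.elements = list(elements)
        self.materials = list(materials)
        self.tecut = float(tecut)
        by_sym = {e.symbol: e for e in self.elements}
        if energy_grid is None:
            energy_grid = np.linspace(E_GRID_MIN, E_GRID_MAX, E_GRID_N)
        self.energy_grid = np.asarray(energy_grid, dtype=float)
        n = self.energy_grid.size

        if L_mass is None:
            nmat = len(self.materials)
            nelem = len(self.elements)
            L_mass = np.empty((nmat, n))
            sig_ion_mass = np.empty((nmat, n))
            for m in self.materials:
                L_mass[m.id] = mass_stopping_power(m.weights, by_sym,
                                                   self.energy_grid, tecut)
                sig_ion_mass[m.id] = delta_production_xs_mass(
                    m.weights, by_sym, self.energy_grid, tecut)
            # cumulative range from the restricted stopping power
            inv_l = 1.0 / L_mass
            dt = np.diff(self.energy_grid)
            seg = 0.5 * (inv_l[:, 1:] + inv_l[:, :-1]) * dt
            range_mass = np.concatenate(
                [np.zeros((nmat, 1)), np.cumsum(seg, axis=1)], axis=1)
            sigma_el = np.empty((nelem, n))
            sigma_inel = np.empty((nelem, n))
            for k, el in enumerate(self.elements):
                sigma_el[k] = sigma_elastic_barn(el, self.energy_grid)
                sigma_inel[k] = sigma_inelastic_barn(el, self.energy_grid)

        self.L_mass = np.asarray(L_mass, dtype=float)
        self.range_mass = np.asarray(range_mass, dtype=float)
        self.sig_ion_mass = np.asarray(sig_ion_mass, dtype=float)
        self.sigma_el = np.asarray(sigma_el, dtype=float)
        self.sigma_inel = np.asarray(sigma_inel, dtype=float)
        self._by_sym = by_sym
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self):
        if np.any(self.L_mass <= 0):
            raise ValueError("L_mass must be strictly positive")
        for name, arr in [("range_mass", self.range_mass),
                          ("sig_ion_mass", self.sig_ion_mass),
                          ("sigma_el", self.sigma_el),
                          ("sigma_inel", self.sigma_inel)]:
            if np.any(arr < 0):
                raise ValueError(f"{name} has negative entries")
        if np.any(np.diff(self.range_mass, axis=1) <= 0):
            raise ValueError("range_mass must be strictly increasing")

    # -- lookups ---------------------------------------------------------
    def _check_T(self, T):
        g = self.energy_grid
        if T < g[0] or T > g[-1]:
            raise ValueError(f"T={T} MeV outside table grid "
                             f"[{g[0]}, {g[-1]}]; proton should have been terminated")

    def interp_linear(self, row, T):
        """Linear-in-T interpolation (stopping power, range)."""
        return float(np.interp(T, self.energy_grid, row))

    def interp_logT(self, row, T):
        """Linear-in-log(T) interpolation between grid nodes (cross-sections)."""
        g = self.energy_grid
        i = min(max(int(np.searchsorted(g, T) - 1), 0), g.size - 2)
        w = (np.log(T) - np.log(g[i])) / (np.log(g[i + 1]) - np.log(g[i]))
        return float(row[i] + w * (row[i + 1] - row[i]))

    def material(self, material_id) -> Material:
        return self.materials[material_id]


# ---------------------------------------------------------------------------
# Operations on tables
# ---------------------------------------------------------------------------

def restricted_stopping_power(material_id, T, tables: MaterialTableSet,
                              density=None):
    """Restricted linear stopping power L (MeV/cm) at kinetic energy T.

    ``density`` defaults to the material's default density.
    """
    tables._check_T(T)
    if density is None:
        density = tables.material(material_id).default_density
    return density * tables.interp_linear(tables.L_mass[material_id], T)


def residual_range(material_id, T, tables: MaterialTableSet, density=None):
    """Residual range (mm) of a proton of energy T in the material."""
    tables._check_T(T)
    if density is None:
        density = tables.material(material_id).default_density
    r_mass = tables.interp_linear(tables.range_mass[material_id], T)  # g/cm^2
    return r_mass / density * 10.0  # cm -> mm


def energy_after_pathlength(material_id, T, s, tables: MaterialTableSet,
                            density=None):
    """Energy after travelling a straight path s (mm); inverse of the
    cumulative range table.

    Returns (energy MeV, exhausted flag); if s meets or exceeds the
    residual range the energy floor of the grid is returned with
    ``exhausted=True``.
    """
    tables._check_T(T)
    if s < 0:
        raise ValueError("path length must be non-negative")
    if density is None:
        density = tables.material(material_id).default_density
    row = tables.range_mass[material_id]
    r_new = tables.interp_linear(row, T) - s * 0.1 * density
    if r_new <= 0.0:
        return tables.energy_grid[0], True
    return float(np.interp(r_new, row, tables.energy_grid)), False


def bohr_variance(material_id, T, dx, tables: MaterialTableSet,
                  tecut=None, density=None):
    """Variance (MeV^2) of the sub-threshold energy loss over a step dx (mm)."""
    if dx < 0:
        raise ValueError("dx must be non-negative")
    if tecut is None:
        tecut = tables.tecut
    if density is None:
        density = tables.material(material_id).default_density
    m = tables.material(material_id)
    per_cm = bohr_variance_per_cm(m.weights, tables._by_sym, T, tecut)
    return float(per_cm) * density * dx * 0.1


def macroscopic_nuclear_xs(material_id, density, T, channel,
                           tables: MaterialTableSet):
    """Macroscopic nuclear cross-section Sigma (1/mm) for one channel.

    Sigma = rho N_A sum_X (w_X / A_X) sigma_X(T), with sigma in barn.
    """
    tables._check_T(T)
    if channel == "elastic":
        micro = tables.sigma_el
    elif channel == "inelastic":
        micro = tables.sigma_inel
    else:
        raise ValueError(f"unknown channel {channel!r}")
    m = tables.material(material_id)
    total = 0.0
    for k, el in enumerate(tables.elements):
        w = m.weights.get(el.symbol, 0.0)
        if w == 0.0:
            continue
        sig_cm2 = tables.interp_logT(micro[k], T) * 1e-24
        total += w / el.A * sig_cm2
    return density * N_A * total * 0.1  # 1/cm -> 1/mm


# ---------------------------------------------------------------------------
# Persistence (HDF5 container with a JSON metadata block)
# ---------------------------------------------------------------------------

def save_tables(tables: MaterialTableSet, path):
    meta = {
        "format_version": TABLE_FORMAT_VERSION,
        "tecut": tables.tecut,
        "energy_grid": [float(tables.energy_grid[0]),
                        float(tables.energy_grid[-1]),
                        int(tables.energy_grid.size)],
        "generator": "protonmc analytic v1",
        "elements": [[e.symbol, e.Z, e.A, e.I, e.X0_mass] for e in tables.elements],
        "materials": [[m.id, m.name, m.default_density, m.weights,
                       m.is_range_shifter] for m in tables.materials],
    }
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = TABLE_FORMAT_VERSION
        f.attrs["meta_json"] = json.dumps(meta)
        for name in ("energy_grid", "L_mass", "range_mass", "sig_ion_mass",
                     "sigma_el", "sigma_inel"):
            f.create_dataset(name, data=getattr(tables, name))


def load_tables(path) -> MaterialTableSet:
    with h5py.File(path, "r") as f:
        version = int(f.attrs["format_version"])
        if version != TABLE_FORMAT_VERSION:
            raise ValueError(f"unsupported table format version {version}")
        meta = json.loads(f.attrs["meta_json"])
        elements = [Element(*row) for row in meta["elements"]]
        materials = [Material(i, n, d, w, rs) for i, n, d, w, rs in meta["materials"]]
        return MaterialTableSet(
            elements, materials, tecut=meta["tecut"],
            energy_grid=f["energy_grid"][()], L_mass=f["L_mass"][()],
            range_mass=f["range_mass"][()], sig_ion_mass=f["sig_ion_mass"][()],
            sigma_el=f["sigma_el"][()], sigma_inel=f["sigma_inel"][()])


def build_default_tables(tecut=TECUT_DEFAULT) -> MaterialTableSet:
    """Registry + tables in one call (the usual entry point)."""
    elements, materials, _ = build_default_registry()
    return MaterialTableSet(elements, materials, tecut=tecut)
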