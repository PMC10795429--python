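"""Class-II condensed-history proton transport.

Each step: sample per-channel distances to the next discrete interaction
(delta production, elastic and inelastic nuclear), compare with the
distance to the voxel boundary and the step cap (20% of residual range,
or a 10 mm cap inside range-shifter material), advance straight by the
minimum, apply continuous energy loss with Gaussian (Bohr) straggling,
multiple Coulomb scattering and the magnetic end-of-step deflection, and
dispatch the discrete event if one was selected. Protons are tracked
until they fall below the 0.5 MeV cutoff (local deposit) or leave the
phantom (escaped energy). Secondary protons go on a LIFO stack and are
transported identically; other charged secondaries deposit locally and
neutrals are discarded into the ledger.

The hot loop is compiled (``_kernels``); this module packs tables into
kernel-ready arrays and exposes the individual physics operations for
direct use and testing. Randomness is a counter-based stream per history
derived from (seed, history index), so results are independent of
execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .constants import M_P, QC
from .geometry import MagneticField, VoxelPhantom, locate
from .materials import MaterialTableSet, macroscopic_nuclear_xs
from .nuclear import NuclearEventDB

EVENT_NAMES = ("BOUNDARY", "RANGE_CAP", "IONIZATION", "ELASTIC", "INELASTIC")


@dataclass
class ProtonState:
    pos: np.ndarray
    dir: np.ndarray
    T: float
    is_primary: bool = True

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        self.dir = np.asarray(self.dir, dtype=float)
        n = np.linalg.norm(self.dir)
        if abs(n - 1.0) > 1e-9:
            raise ValueError(f"direction norm {n} != 1")
        if not (0.0 <= self.T <= 300.0):
            raise ValueError(f"kinetic energy {self.T} outside [0, 300] MeV")


@dataclass
class TransportConfig:
    tecut: float = 0.1          # delta-ray production threshold, MeV
    tmin: float = 0.5           # tracking cutoff, MeV
    range_fraction: float = 0.2  # max fractional residual-range loss per step
    shifter_step_cap: float = 10.0  # mm, inside range-shifter material
    max_step_mm: float = 1.0e300    # optional global step cap
    nudge_factor: float = 1e-6  # boundary nudge, fraction of min spacing
    es_mev: float = 17.5        # Rossi-Greisen scattering constant
    straggling: bool = True
    ms: bool = True
    delta: bool = True          # discrete delta-electron production
    nuclear: bool = True        # elastic + inelastic nuclear channels
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.range_fraction <= 1.0):
            raise ValueError("range_fraction must lie in (0, 1]")

    def em_only(self):
        """Copy with the nuclear channels disabled."""
        from dataclasses import replace
        return replace(self, nuclear=False)


@dataclass
class EnergyLedger:
    """Where one history's kinetic energy went (MeV)."""

    deposited: float = 0.0        # continuous + proton terminal deposits
    local_secondary: float = 0.0  # delta electrons, recoils, charged frags
    neutral_discarded: float = 0.0
    escaped: float = 0.0

    @property
    def total(self):
        return (self.deposited + self.local_secondary
                + self.neutral_discarded + self.escaped)

    def balance_error(self, T0):
        """Relative ledger imbalance against the initial energy."""
        return abs(T0 - self.total) / T0 if T0 > 0 else abs(self.total)


# ---------------------------------------------------------------------------
# Kernel data packing
# ---------------------------------------------------------------------------

class TransportKernelData:
    """Tables, nuclear DB and config flattened into kernel arrays."""

    def __init__(self, tables: MaterialTableSet, nucdb: NuclearEventDB,
                 config: TransportConfig | None = None):
        self.tables = tables
        self.nucdb = nucdb
        self.config = config or TransportConfig()

        g = tables.energy_grid
        self.t0 = float(g[0])
        self.h = float(g[1] - g[0])
        nmat = len(tables.materials)
        nelem = len(tables.elements)
        n = g.size

        self.l_mass = np.ascontiguousarray(tables.L_mass)
        self.range_mass = np.ascontiguousarray(tables.range_mass)
        self.sigion_mass = np.ascontiguousarray(tables.sig_ion_mass)

        # per-(material, element) mass-normalized macroscopic nuclear
        # cross-sections: multiply by density to get 1/mm
        from .constants import N_A
        self.elpart = np.zeros((nmat, nelem, n))
        self.inelpart = np.zeros((nmat, nelem, n))
        self.x0inv_mass = np.zeros(nmat)
        self.zoa = np.zeros(nmat)
        self.is_shifter = np.zeros(nmat, dtype=np.bool_)
        for m in tables.materials:
            for k, el in enumerate(tables.elements):
                w = m.weights.get(el.symbol, 0.0)
                if w == 0.0:
                    continue
                scale = N_A * w / el.A * 1e-24 * 0.1  # barn -> (1/mm)/rho
                self.elpart[m.id, k] = scale * tables.sigma_el[k]
                self.inelpart[m.id, k] = scale * tables.sigma_inel[k]
                self.x0inv_mass[m.id] += w / el.X0_mass
                self.zoa[m.id] += w * el.Z / el.A
            self.is_shifter[m.id] = m.is_range_shifter

        self.elem_is_h = np.array([e.symbol == "H" for e in tables.elements],
                                  dtype=np.bool_)
        # nuclear DB, reindexed to the table's element order
        idx = []
        for el in tables.elements:
            if el.symbol not in nucdb.element_symbols:
                raise KeyError(f"element {el.symbol!r} not in nuclear DB")
            idx.append(nucdb.element_symbols.index(el.symbol))
        idx = np.asarray(idx)
        self.eb0 = float(nucdb.ebins[0])
        self.ebstep = float(nucdb.ebins[1] - nucdb.ebins[0])
        self.nbins = int(nucdb.ebins.size)
        self.pmult_cum = np.ascontiguousarray(
            np.cumsum(nucdb.pmult[idx], axis=2))
        nb = self.nbins
        ne = nelem
        self.pjoint_cum = np.ascontiguousarray(
            np.cumsum(nucdb.pjoint[idx].reshape(ne, nb, -1), axis=2))
        self.el_cum = np.ascontiguousarray(
            np.cumsum(nucdb.el_joint[idx].reshape(ne, nb, -1), axis=2))
        self.efrac_edges = np.ascontiguousarray(nucdb.efrac_edges)
        self.mu_edges = np.ascontiguousarray(nucdb.mu_edges)
        self.elfrac_edges = np.ascontiguousarray(nucdb.el_frac_edges)
        self.neutral_frac = np.ascontiguousarray(nucdb.neutral_frac[idx])
        self.nmu = self.mu_edges.size - 1
        self.q_reaction = float(nucdb.q_reaction)
        self.db_floor = float(nucdb.ebins[0])

    def kernel_args(self, phantom: VoxelPhantom, bfield: MagneticField):
        c = self.config
        eps = c.nudge_factor * min(phantom.spacing)
        bx, by, bz = (float(v) for v in bfield.B)
        return (phantom.material_index, phantom.density,
                phantom.origin[0], phantom.origin[1], phantom.origin[2],
                phantom.spacing[0], phantom.spacing[1], phantom.spacing[2],
                bx, by, bz,
                self.t0, self.h, self.l_mass, self.range_mass,
                self.sigion_mass, self.elpart, self.inelpart,
                self.x0inv_mass, self.zoa, self.is_shifter,
                self.elem_is_h, self.eb0, self.ebstep, self.nbins,
                self.pmult_cum, self.pjoint_cum, self.el_cum,
                self.efrac_edges, self.mu_edges, self.elfrac_edges,
                self.neutral_frac, self.nmu, self.q_reaction, self.db_floor,
                c.tecut, c.tmin, c.range_fraction, c.shifter_step_cap,
                c.max_step_mm, eps, c.es_mev,
                c.straggling, c.ms, c.delta, c.nuclear)


# ---------------------------------------------------------------------------
# Elementary operations (thin wrappers over the compiled physics)
# ---------------------------------------------------------------------------

def _u01(rng):
    u = rng.random()
    while u <= 0.0:
        u = rng.random()
    return u


def sample_num_mfp(rng=None, eta=None):
    """Number of mean free paths to the next interaction: -log(eta),
    Exp(1)-distributed for eta uniform on (0, 1)."""
    if eta is None:
        eta = _u01(rng)
    if not (0.0 < eta < 1.0):
        raise ValueError("eta must lie in the open interval (0, 1)")
    return -math.log(eta)


def distances_to_discrete(T, material_id, density, tables: MaterialTableSet,
                          rng, tecut=None, config: TransportConfig | None = None):
    """Independent exponential distances (mm) for the three discrete
    channels (delta production, elastic, inelastic) at the current
    material and density; +inf for a zero cross-section."""
    cfg = config or TransportConfig()
    sig_ion = density * tables.interp_logT(tables.sig_ion_mass[material_id], T) * 0.1
    out = []
    for sig in (sig_ion,
                macroscopic_nuclear_xs(material_id, density, T, "elastic", tables),
                macroscopic_nuclear_xs(material_id, density, T, "inelastic", tables)):
        if sig <= 0.0:
            out.append(math.inf)
        else:
            out.append(sample_num_mfp(rng) / sig)
    return tuple(out)


def choose_step(d_vox, d_ion, d_el, d_inel, T, material_id, density,
                tables: MaterialTableSet, config: TransportConfig):
    """Step size and event label: minimum of all candidate distances with
    tie-break priority BOUNDARY > RANGE_CAP > discrete channels."""
    from .materials import residual_range
    if tables.material(material_id).is_range_shifter:
        d_max = config.shifter_step_cap
    else:
        d_max = config.range_fraction * residual_range(
            material_id, T, tables, density=density)
    d_max = min(d_max, config.max_step_mm)
    step, event = d_vox, "BOUNDARY"
    for d, name in ((d_max, "RANGE_CAP"), (d_ion, "IONIZATION"),
                    (d_el, "ELASTIC"), (d_inel, "INELASTIC")):
        if d < step:
            step, event = d, name
    return step, event


def continuous_loss(T, material_id, density, dx,
                    tables: MaterialTableSet, rng=None, straggling=True,
                    tecut=None):
    """Energy lost (MeV) over a straight step dx (mm): mean loss from the
    inverted range table, plus a Gaussian draw with Bohr variance when
    straggling is enabled; clamped to [0, T]."""
    from .materials import bohr_variance, energy_after_pathlength
    if dx == 0.0:
        return 0.0
    t_new, exhausted = energy_after_pathlength(material_id, T, dx, tables,
                                               density=density)
    de = T if exhausted else T - t_new
    if straggling:
        var = bohr_variance(material_id, T, dx, tables, tecut=tecut,
                            density=density)
        de += math.sqrt(var) * rng.standard_normal()
    return min(max(de, 0.0), T)


def delta_electron_event(T, rng, tecut=0.1):
    """Delta-electron kinetic energy (MeV), deposited locally by the
    caller; 0.0 when the kinematic maximum is below the threshold."""
    state = np.uint64(K.rng_init(int(rng.integers(0, 2**31)), 0))
    _, td = K.sample_delta_energy(T, tecut, state)
    return td


def max_delta_energy(T):
    """Exact kinematic maximum energy transfer to a free electron (MeV)."""
    return float(K._tmax_delta(T))


def scattering_theta0(T, material_id, density, dx,
                      tables: MaterialTableSet, es_mev=17.5):
    """Rossi-Greisen Gaussian width theta0 (rad) for a step dx (mm)."""
    m = tables.material(material_id)
    x0inv = sum(w / tables._by_sym[s].X0_mass for s, w in m.weights.items())
    e = T + M_P
    pc = math.sqrt(e * e - M_P * M_P)
    pv = pc * pc / e  # pc * beta
    return (es_mev / pv) * math.sqrt(dx * 0.1 * density * x0inv)


def multiple_scattering(direction, T, material_id, density, dx,
                        tables: MaterialTableSet, rng, es_mev=17.5):
    """New unit direction after the condensed multiple-scattering
    deflection of one step."""
    th0 = scattering_theta0(T, material_id, density, dx, tables, es_mev)
    theta = th0 * rng.standard_normal()
    phi = 2.0 * math.pi * _u01(rng)
    d = np.asarray(direction, dtype=float)
    return np.array(K._rotate(d[0], d[1], d[2], math.cos(theta), phi))


def magnetic_deflection(direction, bfield, T, dx):
    """New unit direction after the end-of-step Lorentz kick."""
    d = np.asarray(direction, dtype=float)
    b = bfield.vector if hasattr(bfield, "vector") else np.asarray(bfield, float)
    if not np.any(b):
        return d.copy()
    return np.array(K._magnetic_kick(d[0], d[1], d[2], b[0], b[1], b[2],
                                     T, dx))


def gyroradius_mm(T, b_tesla):
    """Analytic circular-orbit radius pc / (QC * B) in mm."""
    e = T + M_P
    pc = math.sqrt(e * e - M_P * M_P)
    return pc / (QC * b_tesla)


def pp_elastic_cosines(T, T2):
    """Lab-frame cosines (scattered, secondary) for elastic p-p with
    incident kinetic energy T and secondary kinetic energy T2."""
    return K._pp_cos(T - T2, T), K._pp_cos(T2, T)


def elastic_event(T, direction, element_symbol, nucdb: NuclearEventDB, rng):
    """One elastic nuclear event.

    p-p: returns ("pp", scattered ProtonState-like tuple, secondary tuple)
    with exact energy conservation; p-X: returns ("pX", scattered tuple,
    recoil energy deposited locally).
    """
    d = np.asarray(direction, dtype=float)
    if element_symbol == "H":
        T2 = _u01(rng) * T
        T1 = T - T2
        phi = 2.0 * math.pi * _u01(rng)
        c1, c2 = pp_elastic_cosines(T, T2)
        d1 = np.array(K._rotate(d[0], d[1], d[2], c1, phi))
        d2 = np.array(K._rotate(d[0], d[1], d[2], c2, phi + math.pi))
        return "pp", (T1, d1), (T2, d2)
    kept, mu, phi, recoil = nucdb.sample_elastic(element_symbol, T, rng)
    d1 = np.array(K._rotate(d[0], d[1], d[2], mu, phi))
    return "pX", (kept, d1), recoil


def inelastic_event(T, direction, element_symbol, nucdb: NuclearEventDB,
                    rng):
    """One inelastic nuclear event: (secondary protons, local deposit,
    neutral energy); the incident proton is terminated."""
    from .nuclear import (SECONDARY_CHARGED_LOCAL, SECONDARY_NEUTRAL,
                          SECONDARY_PROTON)
    d = np.asarray(direction, dtype=float)
    protons, local, neutral = [], 0.0, 0.0
    for kind, e, mu, phi in nucdb.sample_inelastic(element_symbol, T, rng):
        if kind == SECONDARY_PROTON:
            nd = np.array(K._rotate(d[0], d[1], d[2], mu, phi))
            protons.append((e, nd))
        elif kind == SECONDARY_NEUTRAL:
            neutral += e
        elif kind == SECONDARY_CHARGED_LOCAL:
            local += e
    return protons, local, neutral


# ---------------------------------------------------------------------------
# Full history
# ---------------------------------------------------------------------------

def transport_history(primary: ProtonState, phantom: VoxelPhantom,
                      bfield: MagneticField, kdata: TransportKernelData,
                      deposit: np.ndarray, seed=0, history_index=0,
                      record_trajectory=False, traj_capacity=100000):
    """Transport one primary (and its secondaries) into ``deposit``.

    Returns (EnergyLedger, trajectory array or None). The history's
    random stream is derived from (seed, history_index).
    """
    ledger = np.zeros(4)
    if record_trajectory:
        traj = np.empty((traj_capacity, 3))
    else:
        traj = np.empty((0, 3))
    traj_n = np.zeros(1, dtype=np.int64)
    state = np.uint64(K.rng_init(seed, 2 * history_index + 1))
    args = kdata.kernel_args(phantom, bfield)
    K.transport_history(
        primary.pos[0], primary.pos[1], primary.pos[2],
        primary.dir[0], primary.dir[1], primary.dir[2],
        primary.T, state, *args, deposit, ledger, traj, traj_n)
    led = EnergyLedger(deposited=ledger[0], local_secondary=ledger[1],
                       neutral_discarded=ledger[2], escaped=ledger[3])
    return led, (traj[:traj_n[0]] if record_trajectory else None)
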