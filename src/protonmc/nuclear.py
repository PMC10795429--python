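"""Nuclear secondary-particle event database: schema, persistence,
sampling, and an analytic default generator.

The database stores, per element and per incident-energy bin (10 to
300 MeV in steps of 10 MeV), the secondary-proton multiplicity
distribution, a joint probability table over (secondary energy fraction,
polar-angle cosine), the fraction of the residual event energy carried by
neutral particles, and an elastic proton-nucleus (energy retention,
angle) table.

Secondary energies are stored as fractions of the available energy
(incident kinetic energy minus a fixed reaction offset Q), which makes
energy conservation structural rather than statistical.

The bundled default generator is a physically-motivated analytic stand-in
(forward-peaked quasi-free knockout component plus an isotropic
Maxwellian evaporation component); externally derived tables in the same
schema can replace it without code changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import h5py
import numpy as np

DB_FORMAT_VERSION = 1

E_BIN_MIN = 10.0
E_BIN_MAX = 300.0
E_BIN_STEP = 10.0

#: Fixed reaction Q offset (MeV): energy unavailable to secondaries.
Q_REACTION = 5.0

MAX_MULTIPLICITY = 4

SECONDARY_PROTON = 0
SECONDARY_NEUTRAL = 1
SECONDARY_CHARGED_LOCAL = 2


@dataclass
class GeneratorParams:
    """Tunable shapes of the analytic default tables."""

    kT_evap: float = 4.0          # Maxwellian evaporation temperature, MeV
    qf_center: float = 0.5        # quasi-free fractional-energy peak
    qf_width: float = 0.18
    qf_weight_base: float = 0.2   # quasi-free mixture weight at 0 MeV
    qf_weight_slope: float = 0.5  # ... plus slope * (T/300)
    mult_mean_base: float = 0.8   # mean secondary-proton count at 0 MeV
    mult_mean_slope: float = 0.9
    neutral_fraction: float = 0.45
    forward_k_base: float = 1.5   # exp(k*mu) peaking, k = base + slope*f
    forward_k_slope: float = 4.0
    elastic_tail: float = 0.02    # exp(-(1-f)/tail) retention spectrum
    elastic_k: float = 8.0        # elastic angular forward peaking
    n_efrac: int = 24
    n_mu: int = 18
    n_efrac_el: int = 16


class NuclearEventDB:
    """In-memory probability tables; see the module docstring for schema."""

    def __init__(self, element_symbols, element_A, ebins, efrac_edges,
                 mu_edges, el_frac_edges, pmult, pjoint, neutral_frac,
                 el_joint, q_reaction=Q_REACTION, params_json="{}"):
        self.element_symbols = list(element_symbols)
        self.element_A = np.asarray(element_A, dtype=float)
        self.ebins = np.asarray(ebins, dtype=float)
        self.efrac_edges = np.asarray(efrac_edges, dtype=float)
        self.mu_edges = np.asarray(mu_edges, dtype=float)
        self.el_frac_edges = np.asarray(el_frac_edges, dtype=float)
        self.pmult = np.asarray(pmult, dtype=float)
        self.pjoint = np.asarray(pjoint, dtype=float)
        self.neutral_frac = np.asarray(neutral_frac, dtype=float)
        self.el_joint = np.asarray(el_joint, dtype=float)
        self.q_reaction = float(q_reaction)
        self.params_json = params_json
        self._index = {s: i for i, s in enumerate(self.element_symbols)}
        self.validate()

    # ------------------------------------------------------------------
    def validate(self):
        for edges, nm in [(self.ebins, "ebins"), (self.efrac_edges, "efrac_edges"),
                          (self.mu_edges, "mu_edges"),
                          (self.el_frac_edges, "el_frac_edges")]:
            if np.any(np.diff(edges) <= 0):
                raise ValueError(f"{nm} must be strictly increasing")
        for name, arr in [("pmult", self.pmult), ("pjoint", self.pjoint),
                          ("el_joint", self.el_joint)]:
            if np.any(arr < 0):
                raise ValueError(f"table {name} has negative entries")
            axes = tuple(range(2, arr.ndim))
            sums = arr.sum(axis=axes) if axes else arr
            if name == "pmult":
                sums = arr.sum(axis=2)
            bad = np.abs(sums - 1.0) > 1e-9
            if np.any(bad):
                el, bin_ = np.argwhere(bad)[0][:2]
                raise ValueError(
                    f"table {name} not normalized at element "
                    f"{self.element_symbols[el]}, bin {bin_}")
        if np.any(self.neutral_frac < 0) or np.any(self.neutral_frac > 1):
            raise ValueError("neutral_frac must lie in [0, 1]")
        # expected total secondary-proton energy must not exceed the
        # incident kinetic energy in any bin
        fr = 0.5 * (self.efrac_edges[:-1] + self.efrac_edges[1:])
        mean_f = (self.pjoint.sum(axis=3) * fr).sum(axis=2)
        mean_n = (self.pmult * np.arange(self.pmult.shape[2])).sum(axis=2)
        e_avail = np.maximum(self.ebins - self.q_reaction, 0.0)
        if np.any(mean_n * mean_f * e_avail > self.ebins):
            raise ValueError("expected secondary energy exceeds incident energy")

    def element_bin(self, element, T):
        if element not in self._index:
            raise KeyError(f"element {element!r} not in DB")
        return self._index[element]

    # ------------------------------------------------------------------
    def _pick_bin(self, T, rng):
        """Stochastic linear mixing of the two bracketing incident bins."""
        eb = self.ebins
        if T <= eb[0]:
            return 0
        if T >= eb[-1]:
            return eb.size - 1
        hi = int(np.searchsorted(eb, T))
        lo = hi - 1
        w = (T - eb[lo]) / (eb[hi] - eb[lo])
        return hi if rng.random() < w else lo

    @staticmethod
    def _sample_cell(flat_cum, n_mu, rng):
        c = int(np.searchsorted(flat_cum, rng.random(), side="right"))
        c = min(c, flat_cum.size - 1)
        return c // n_mu, c % n_mu

    def sample_inelastic(self, element, T, rng):
        """Draw one inelastic event: list of (type, energy MeV, mu, phi).

        Types are SECONDARY_PROTON / SECONDARY_NEUTRAL /
        SECONDARY_CHARGED_LOCAL; neutral and charged-local entries carry
        the pooled residual energy with no direction (mu = phi = 0).
        """
        ei = self.element_bin(element, T)
        b = self._pick_bin(T, rng)
        e_avail = max(T - self.q_reaction, 0.0)
        n_mu = self.mu_edges.size - 1

        n_p = int(np.searchsorted(np.cumsum(self.pmult[ei, b]), rng.random(),
                                  side="right"))
        n_p = min(n_p, MAX_MULTIPLICITY)
        flat_cum = np.cumsum(self.pjoint[ei, b].ravel())

        fracs, mus = [], []
        for _ in range(100):
            fracs, mus = [], []
            for _k in range(n_p):
                ie, imu = self._sample_cell(flat_cum, n_mu, rng)
                f = self.efrac_edges[ie] + rng.random() * (
                    self.efrac_edges[ie + 1] - self.efrac_edges[ie])
                mu = self.mu_edges[imu] + rng.random() * (
                    self.mu_edges[imu + 1] - self.mu_edges[imu])
                fracs.append(f)
                mus.append(mu)
            if sum(fracs) <= 1.0:
                break
        else:
            # truncate the last particle so the event conserves energy
            excess = sum(fracs) - 1.0
            fracs[-1] = max(fracs[-1] - excess, 0.0)

        out = []
        for f, mu in zip(fracs, mus):
            out.append((SECONDARY_PROTON, f * e_avail, mu,
                        2.0 * np.pi * rng.random()))
        remainder = T - sum(f * e_avail for f in fracs)
        nf = self.neutral_frac[ei, b]
        out.append((SECONDARY_NEUTRAL, nf * remainder, 0.0, 0.0))
        out.append((SECONDARY_CHARGED_LOCAL, (1.0 - nf) * remainder, 0.0, 0.0))
        return out

    def sample_elastic(self, element, T, rng):
        """Draw one elastic proton-nucleus event.

        Returns (retained proton energy MeV, mu, phi, recoil energy MeV).
        """
        ei = self.element_bin(element, T)
        b = self._pick_bin(T, rng)
        n_mu = self.mu_edges.size - 1
        flat_cum = np.cumsum(self.el_joint[ei, b].ravel())
        ie, imu = self._sample_cell(flat_cum, n_mu, rng)
        f = self.el_frac_edges[ie] + rng.random() * (
            self.el_frac_edges[ie + 1] - self.el_frac_edges[ie])
        mu = self.mu_edges[imu] + rng.random() * (
            self.mu_edges[imu + 1] - self.mu_edges[imu])
        e_kept = f * T
        return e_kept, mu, 2.0 * np.pi * rng.random(), T - e_kept


# ---------------------------------------------------------------------------
# Default generator
# ---------------------------------------------------------------------------

def generate_default_db(elements, params: GeneratorParams | None = None
                        ) -> NuclearEventDB:
    """Build the analytic default database for the given elements.

    Deterministic: identical parameters produce bit-identical tables.
    ``elements`` is a sequence of (symbol, A) pairs or Element objects.
    """
    p = params or GeneratorParams()
    pairs = [(e.symbol, e.A) if hasattr(e, "symbol") else tuple(e)
             for e in elements]
    symbols = [s for s, _ in pairs]
    A = np.array([a for _, a in pairs])

    ebins = np.arange(E_BIN_MIN, E_BIN_MAX + 0.5 * E_BIN_STEP, E_BIN_STEP)
    nb = ebins.size
    nE, nMu, nEel = p.n_efrac, p.n_mu, p.n_efrac_el
    efrac_edges = np.linspace(0.0, 1.0, nE + 1)
    mu_edges = np.linspace(-1.0, 1.0, nMu + 1)
    el_frac_edges = np.linspace(0.70, 1.0, nEel + 1)

    fr = 0.5 * (efrac_edges[:-1] + efrac_edges[1:])
    mu = 0.5 * (mu_edges[:-1] + mu_edges[1:])
    fr_el = 0.5 * (el_frac_edges[:-1] + el_frac_edges[1:])

    ne = len(symbols)
    pmult = np.zeros((ne, nb, MAX_MULTIPLICITY + 1))
    pjoint = np.zeros((ne, nb, nE, nMu))
    el_joint = np.zeros((ne, nb, nEel, nMu))
    neutral_frac = np.full((ne, nb), p.neutral_fraction)

    for b, Tb in enumerate(ebins):
        e_avail = max(Tb - Q_REACTION, 1.0)
        # evaporation spectrum over energy fraction
        e_mev = fr * e_avail
        ev = e_mev * np.exp(-e_mev / p.kT_evap)
        ev /= ev.sum()
        # quasi-free knockout spectrum
        qf = np.exp(-0.5 * ((fr - p.qf_center) / p.qf_width) ** 2)
        qf /= qf.sum()
        w_qf = min(p.qf_weight_base + p.qf_weight_slope * Tb / 300.0, 0.95)
        iso = np.full(nMu, 1.0 / nMu)
        joint = np.zeros((nE, nMu))
        for i, f in enumerate(fr):
            k = p.forward_k_base + p.forward_k_slope * f
            fwd = np.exp(k * mu)
            fwd /= fwd.sum()
            joint[i] = w_qf * qf[i] * fwd + (1.0 - w_qf) * ev[i] * iso
        joint /= joint.sum()
        pjoint[:, b] = joint

        nu = min(p.mult_mean_base + p.mult_mean_slope * Tb / 300.0,
                 MAX_MULTIPLICITY - 0.1)
        q = nu / MAX_MULTIPLICITY  # binomial thinning of MAX trials
        k_arr = np.arange(MAX_MULTIPLICITY + 1)
        from scipy.stats import binom
        pm = binom.pmf(k_arr, MAX_MULTIPLICITY, q)
        pm /= pm.sum()
        pmult[:, b] = pm

        # elastic retention: sharper for heavier nuclei (less energy lost)
        for ei in range(ne):
            fmax = 4.0 * A[ei] / (1.0 + A[ei]) ** 2  # kinematic transfer cap
            tail = p.elastic_tail * max(fmax, 1e-3) / 0.25
            ret = np.exp(-(1.0 - fr_el) / tail)
            fwd = np.exp(p.elastic_k * mu)
            ej = np.outer(ret, fwd)
            ej /= ej.sum()
            el_joint[ei, b] = ej

    meta = json.dumps({k: getattr(p, k) for k in vars(p)})
    return NuclearEventDB(symbols, A, ebins, efrac_edges, mu_edges,
                          el_frac_edges, pmult, pjoint, neutral_frac,
                          el_joint, params_json=meta)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

_ARRAYS = ("ebins", "efrac_edges", "mu_edges", "el_frac_edges", "pmult",
           "pjoint", "neutral_frac", "el_joint", "element_A")


def save_db(db: NuclearEventDB, path):
    with h5py.File(path, "w") as f:
        f.attrs["format_version"] = DB_FORMAT_VERSION
        f.attrs["meta_json"] = json.dumps({
            "format_version": DB_FORMAT_VERSION,
            "elements": db.element_symbols,
            "q_reaction": db.q_reaction,
            "generator_params": db.params_json,
        })
        for name in _ARRAYS:
            f.create_dataset(name, data=getattr(db, name))


def load_db(path) -> NuclearEventDB:
    with h5py.File(path, "r") as f:
        version = int(f.attrs["format_version"])
        if version != DB_FORMAT_VERSION:
            raise ValueError(f"unsupported DB format version {version}")
        meta = json.loads(f.attrs["meta_json"])
        arrays = {name: f[name][()] for name in _ARRAYS}
    return NuclearEventDB(meta["elements"], arrays["element_A"],
                          arrays["ebins"], arrays["efrac_edges"],
                          arrays["mu_edges"], arrays["el_frac_edges"],
                          arrays["pmult"], arrays["pjoint"],
                          arrays["neutral_frac"], arrays["el_joint"],
                          q_reaction=meta["q_reaction"],
                          params_json=meta["generator_params"])
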