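"""Numba-compiled inner loops of the transport engine.

Everything here operates on flat numpy arrays packed by
``transport.TransportKernelData``; no Python objects cross into this
module. All lengths are mm, energies MeV, densities g/cm^3.

The random-number generator is a counter-based splitmix64 stream: one
independent stream per history derived from (seed, history index), so
results do not depend on execution order or batching.
"""

import math

import numpy as np
from numba import njit, uint64

# ---------------------------------------------------------------------------
# RNG: splitmix64, one stream per (seed, history)
# ---------------------------------------------------------------------------

_GOLD = uint64(0x9E3779B97F4A7C15)
_MIX1 = uint64(0xBF58476D1CE4E5B9)
_MIX2 = uint64(0x94D049BB133111EB)
_INV_2_53 = 1.0 / 9007199254740992.0  # 2^-53


@njit(cache=True, inline="always")
def _mix64(z):
    z = (z ^ (z >> uint64(30))) * _MIX1
    z = (z ^ (z >> uint64(27))) * _MIX2
    return z ^ (z >> uint64(31))


@njit(cache=True)
def rng_init(seed, stream):
    """Initial state of the (seed, stream) substream."""
    s = _mix64(uint64(seed) * _GOLD + uint64(0x1))
    return _mix64(s ^ (uint64(stream) * _MIX2 + _GOLD))


@njit(cache=True, inline="always")
def rng_u01(state):
    """Advance the stream; uniform in the open interval (0, 1)."""
    state = state + _GOLD
    z = _mix64(state)
    u = (float(z >> uint64(11)) + 0.5) * _INV_2_53
    return state, u


@njit(cache=True, inline="always")
def rng_normal(state):
    """Standard normal via Box-Muller (uses two uniforms)."""
    state, u1 = rng_u01(state)
    state, u2 = rng_u01(state)
    return state, math.sqrt(-2.0 * math.log(u1)) * math.cos(2.0 * math.pi * u2)


@njit(cache=True)
def fill_u01(seed, stream0, n, k, stride=1):
    """(n, k) uniforms, row i drawn from stream stream0 + stride*i."""
    out = np.empty((n, k))
    for i in range(n):
        st = rng_init(seed, stream0 + stride * i)
        for j in range(k):
            st, u = rng_u01(st)
            out[i, j] = u
    return out


# ---------------------------------------------------------------------------
# Kinematics helpers
# ---------------------------------------------------------------------------

M_P = 938.272
M_E = 0.511
QC = 0.299792
K_BETHE = 0.307075


@njit(cache=True, inline="always")
def _beta2_pc(T):
    e = T + M_P
    pc = math.sqrt(e * e - M_P * M_P)
    beta2 = (pc / e) ** 2
    return beta2, pc


@njit(cache=True, inline="always")
def _tmax_delta(T):
    gamma = 1.0 + T / M_P
    beta2 = 1.0 - 1.0 / (gamma * gamma)
    r = M_E / M_P
    return 2.0 * M_E * beta2 * gamma * gamma / (1.0 + 2.0 * gamma * r + r * r)


# ---------------------------------------------------------------------------
# Table interpolation (uniform energy grid)
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def interp_lin(row, t0, h, T):
    x = (T - t0) / h
    i = int(x)
    if i < 0:
        i = 0
    if i > row.size - 2:
        i = row.size - 2
    w = x - i
    return row[i] + w * (row[i + 1] - row[i])


@njit(cache=True, inline="always")
def interp_logt(row, t0, h, T):
    x = (T - t0) / h
    i = int(x)
    if i < 0:
        i = 0
    if i > row.size - 2:
        i = row.size - 2
    ta = t0 + i * h
    tb = ta + h
    tt = T
    if tt < ta:
        tt = ta
    w = math.log(tt / ta) / math.log(tb / ta)
    return row[i] + w * (row[i + 1] - row[i])


@njit(cache=True)
def invert_range(range_row, t0, h, r):
    """Energy whose cumulative range equals r (g/cm^2); clamps to grid."""
    if r <= range_row[0]:
        return t0
    n = range_row.size
    if r >= range_row[n - 1]:
        return t0 + (n - 1) * h
    i = np.searchsorted(range_row, r) - 1
    w = (r - range_row[i]) / (range_row[i + 1] - range_row[i])
    return t0 + (i + w) * h


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _locate(px, py, pz, ox, oy, oz, sx, sy, sz, nx, ny, nz):
    ix = int(math.floor((px - ox) / sx))
    iy = int(math.floor((py - oy) / sy))
    iz = int(math.floor((pz - oz) / sz))
    if ix < 0 or iy < 0 or iz < 0 or ix >= nx or iy >= ny or iz >= nz:
        return -1, -1, -1
    return ix, iy, iz


@njit(cache=True, inline="always")
def _dist_to_boundary(px, py, pz, dx, dy, dz, ix, iy, iz,
                      ox, oy, oz, sx, sy, sz):
    best = 1.0e300
    if abs(dx) > 1e-12:
        b = ox + (ix + 1) * sx if dx > 0.0 else ox + ix * sx
        t = (b - px) / dx
        if t <= 0.0:
            t += sx / abs(dx)
        if t < best:
            best = t
    if abs(dy) > 1e-12:
        b = oy + (iy + 1) * sy if dy > 0.0 else oy + iy * sy
        t = (b - py) / dy
        if t <= 0.0:
            t += sy / abs(dy)
        if t < best:
            best = t
    if abs(dz) > 1e-12:
        b = oz + (iz + 1) * sz if dz > 0.0 else oz + iz * sz
        t = (b - pz) / dz
        if t <= 0.0:
            t += sz / abs(dz)
        if t < best:
            best = t
    return best


@njit(cache=True)
def _entry_distance(px, py, pz, dx, dy, dz, ox, oy, oz, ex, ey, ez):
    """Slab-method distance to enter the box [o, e); negative if missing."""
    tmin = 0.0
    tmax = 1.0e300
    for axis in range(3):
        if axis == 0:
            p, d, lo, hi = px, dx, ox, ex
        elif axis == 1:
            p, d, lo, hi = py, dy, oy, ey
        else:
            p, d, lo, hi = pz, dz, oz, ez
        if d == 0.0:
            if p < lo or p >= hi:
                return -1.0
        else:
            t1 = (lo - p) / d
            t2 = (hi - p) / d
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
    if tmax <= tmin:
        return -1.0
    return tmin


# ---------------------------------------------------------------------------
# Direction updates
# ---------------------------------------------------------------------------

@njit(cache=True, inline="always")
def _rotate(dx, dy, dz, cth, phi):
    """Rotate unit vector d by polar angle acos(cth) about itself with
    azimuth phi; returns a renormalized unit vector."""
    sth = math.sqrt(max(0.0, 1.0 - cth * cth))
    # orthonormal frame (u, v) perpendicular to d
    if abs(dz) < 0.999999:
        ux, uy, uz = -dy, dx, 0.0
    else:
        ux, uy, uz = 1.0, 0.0, 0.0
    un = math.sqrt(ux * ux + uy * uy + uz * uz)
    ux, uy, uz = ux / un, uy / un, uz / un
    vx = dy * uz - dz * uy
    vy = dz * ux - dx * uz
    vz = dx * uy - dy * ux
    c, s = math.cos(phi), math.sin(phi)
    nx = cth * dx + sth * (c * ux + s * vx)
    ny = cth * dy + sth * (c * uy + s * vy)
    nz = cth * dz + sth * (c * uz + s * vz)
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True, inline="always")
def _magnetic_kick(dx, dy, dz, bx, by, bz, T, step):
    """End-of-step Lorentz deflection: dir <- normalize(dir + dv) with
    dv = (QC * step / pc) (dir x B)."""
    _, pc = _beta2_pc(T)
    f = QC * step / pc
    cx = dy * bz - dz * by
    cy = dz * bx - dx * bz
    cz = dx * by - dy * bx
    nx = dx + f * cx
    ny = dy + f * cy
    nz = dz + f * cz
    norm = math.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


# ---------------------------------------------------------------------------
# Discrete-event sampling pieces
# ---------------------------------------------------------------------------

@njit(cache=True)
def sample_delta_energy(T, tecut, state):
    """Delta-electron kinetic energy via acceptance-rejection on the
    1/T^2 Rutherford spectrum with the (1 - beta^2 T/Tmax) factor."""
    tmax = _tmax_delta(T)
    if tmax <= tecut:
        return state, 0.0
    beta2, _ = _beta2_pc(T)
    for _ in range(10000):
        state, u1 = rng_u01(state)
        state, u2 = rng_u01(state)
        td = tecut * tmax / (tmax - u1 * (tmax - tecut))
        if u2 <= 1.0 - beta2 * td / tmax:
            return state, td
    return state, tecut


@njit(cache=True, inline="always")
def _pp_cos(Ti, T):
    """Lab cosine of an outgoing proton with kinetic energy Ti from
    elastic p-p at incident kinetic energy T (relativistic two-body)."""
    return math.sqrt(Ti * (T + 2.0 * M_P) / (T * (Ti + 2.0 * M_P)))


@njit(cache=True, inline="always")
def _db_bin(T, eb0, ebstep, nbins, state):
    """Stochastic linear mixing between the two bracketing incident bins."""
    x = (T - eb0) / ebstep
    if x <= 0.0:
        return state, 0
    if x >= nbins - 1:
        return state, nbins - 1
    lo = int(x)
    w = x - lo
    state, u = rng_u01(state)
    if u < w:
        return state, lo + 1
    return state, lo


@njit(cache=True, inline="always")
def _sample_flat_cum(flat_cum, nmu, state):
    state, u = rng_u01(state)
    c = np.searchsorted(flat_cum, u)
    if c >= flat_cum.size:
        c = flat_cum.size - 1
    return state, c // nmu, c % nmu


# event codes
EV_BOUNDARY = 0
EV_RANGE_CAP = 1
EV_ION = 2
EV_ELASTIC = 3
EV_INELASTIC = 4

# ledger columns
LG_DEPOSIT = 0
LG_LOCAL = 1
LG_NEUTRAL = 2
LG_ESCAPED = 3

MAX_STACK = 128
MAX_STEPS = 1000000


@njit(cache=True)
def transport_history(
        px, py, pz, ddx, ddy, ddz, T0, state,
        # geometry
        matidx, density, ox, oy, oz, sx, sy, sz,
        # field
        bx, by, bz,
        # tables (uniform grid t0, h)
        t0, h, l_mass, range_mass, sigion_mass, elpart, inelpart,
        x0inv_mass, zoa, is_shifter,
        # nuclear db
        elem_is_h, eb0, ebstep, nbins, pmult_cum, pjoint_cum, el_cum,
        efrac_edges, mu_edges, elfrac_edges, neutral_frac, nmu,
        q_reaction, db_floor,
        # config
        tecut, tmin, range_fraction, shifter_cap, step_cap, eps_mm,
        es_mev, do_straggle, do_ms, do_delta, do_nuclear,
        # output
        deposit, ledger, traj, traj_n):
    """Transport one primary proton and all its secondary protons.

    ``deposit`` is the (nx, ny, nz) energy-deposit grid; ``ledger`` is a
    length-4 accumulator (deposited, local_secondary, neutral, escaped).
    If ``traj`` has nonzero length, primary positions after each step are
    recorded and the count returned through traj_n[0].

    Returns the number of steps taken (negative if the step cap tripped).
    """
    nx, ny, nz = matidx.shape
    exx = ox + nx * sx
    eyy = oy + ny * sy
    ezz = oz + nz * sz
    has_b = bx != 0.0 or by != 0.0 or bz != 0.0
    nelem = elpart.shape[1]

    # secondary stack
    stk = np.empty((MAX_STACK, 7))
    sp = 0
    stk[sp, 0] = px
    stk[sp, 1] = py
    stk[sp, 2] = pz
    stk[sp, 3] = ddx
    stk[sp, 4] = ddy
    stk[sp, 5] = ddz
    stk[sp, 6] = T0
    sp = 1

    nsteps = 0
    record = traj.shape[0] > 0
    first_particle = True

    while sp > 0:
        sp -= 1
        x = stk[sp, 0]
        y = stk[sp, 1]
        z = stk[sp, 2]
        ux = stk[sp, 3]
        uy = stk[sp, 4]
        uz = stk[sp, 5]
        T = stk[sp, 6]
        rec = record and first_particle
        first_particle = False

        # bring entering particles onto the phantom
        ix, iy, iz = _locate(x, y, z, ox, oy, oz, sx, sy, sz, nx, ny, nz)
        if ix < 0:
            tent = _entry_distance(x, y, z, ux, uy, uz, ox, oy, oz,
                                   exx, eyy, ezz)
            if tent < 0.0:
                ledger[LG_ESCAPED] += T
                continue
            x += (tent + eps_mm) * ux
            y += (tent + eps_mm) * uy
            z += (tent + eps_mm) * uz
            ix, iy, iz = _locate(x, y, z, ox, oy, oz, sx, sy, sz, nx, ny, nz)
            if ix < 0:
                ledger[LG_ESCAPED] += T
                continue

        alive = True
        while alive:
            nsteps += 1
            if nsteps > MAX_STEPS:
                deposit[ix, iy, iz] += T
                ledger[LG_DEPOSIT] += T
                return -nsteps

            if T <= tmin:
                deposit[ix, iy, iz] += T
                ledger[LG_DEPOSIT] += T
                break

            mat = matidx[ix, iy, iz]
            rho = density[ix, iy, iz]

            # --- candidate distances ------------------------------------
            d_vox = _dist_to_boundary(x, y, z, ux, uy, uz, ix, iy, iz,
                                      ox, oy, oz, sx, sy, sz)
            if rho > 0.0:
                rmass = interp_lin(range_mass[mat], t0, h, T)
                resid_mm = rmass / rho * 10.0
                # residual range below a micron: the proton is stopped
                if resid_mm < 1e-3:
                    deposit[ix, iy, iz] += T
                    ledger[LG_DEPOSIT] += T
                    break
            else:
                rmass = 0.0
                resid_mm = 1.0e300

            d_max = shifter_cap if is_shifter[mat] else range_fraction * resid_mm
            if d_max > step_cap:
                d_max = step_cap

            d_ion = 1.0e300
            if do_delta and rho > 0.0:
                sig = rho * interp_logt(sigion_mass[mat], t0, h, T) * 0.1
                if sig > 0.0:
                    state, u = rng_u01(state)
                    d_ion = -math.log(u) / sig

            d_el = 1.0e300
            d_inel = 1.0e300
            if do_nuclear and rho > 0.0:
                sel = 0.0
                sinl = 0.0
                for k in range(nelem):
                    sel += interp_logt(elpart[mat, k], t0, h, T)
                    sinl += interp_logt(inelpart[mat, k], t0, h, T)
                sel *= rho
                sinl *= rho
                if sel > 0.0:
                    state, u = rng_u01(state)
                    d_el = -math.log(u) / sel
                if sinl > 0.0:
                    state, u = rng_u01(state)
                    d_inel = -math.log(u) / sinl

            # minimum with tie-break priority boundary > cap > discrete
            step = d_vox
            event = EV_BOUNDARY
            if d_max < step:
                step = d_max
                event = EV_RANGE_CAP
            if d_ion < step:
                step = d_ion
                event = EV_ION
            if d_el < step:
                step = d_el
                event = EV_ELASTIC
            if d_inel < step:
                step = d_inel
                event = EV_INELASTIC

            # --- continuous loss with straggling ------------------------
            if rho > 0.0:
                r_new = rmass - step * 0.1 * rho
                if r_new <= 0.0:
                    de_mean = T
                else:
                    de_mean = T - invert_range(range_mass[mat], t0, h, r_new)
                de = de_mean
                if do_straggle:
                    tmax_e = _tmax_delta(T)
                    tup = tecut if tecut < tmax_e else tmax_e
                    beta2, _ = _beta2_pc(T)
                    var = (0.5 * K_BETHE * zoa[mat] / beta2 * tup
                           * (1.0 - beta2 * tup / (2.0 * tmax_e))
                           * rho * step * 0.1)
                    state, g = rng_normal(state)
                    de += math.sqrt(var) * g
                if de < 0.0:
                    de = 0.0
                if de > T:
                    de = T
                deposit[ix, iy, iz] += de
                ledger[LG_DEPOSIT] += de
                T -= de
                if T <= tmin:
                    deposit[ix, iy, iz] += T
                    ledger[LG_DEPOSIT] += T
                    break

            # --- advance ------------------------------------------------
            adv = step + (eps_mm if event == EV_BOUNDARY else 0.0)
            x += adv * ux
            y += adv * uy
            z += adv * uz

            # --- end-of-step direction changes --------------------------
            if do_ms and rho > 0.0 and step > 0.0:
                beta2, pc = _beta2_pc(T)
                pv = pc * math.sqrt(beta2)
                th0 = (es_mev / pv) * math.sqrt(step * 0.1 * rho
                                                * x0inv_mass[mat])
                state, g = rng_normal(state)
                theta = th0 * g
                state, u = rng_u01(state)
                ux, uy, uz = _rotate(ux, uy, uz, math.cos(theta),
                                     2.0 * math.pi * u)
            if has_b:
                ux, uy, uz = _magnetic_kick(ux, uy, uz, bx, by, bz, T, step)

            if rec:
                n = traj_n[0]
                if n < traj.shape[0]:
                    traj[n, 0] = x
                    traj[n, 1] = y
                    traj[n, 2] = z
                    traj_n[0] = n + 1

            ix, iy, iz = _locate(x, y, z, ox, oy, oz, sx, sy, sz, nx, ny, nz)
            if ix < 0:
                ledger[LG_ESCAPED] += T
                break

            # --- discrete event -----------------------------------------
            if event == EV_ION:
                state, td = sample_delta_energy(T, tecut, state)
                if td > 0.0:
                    deposit[ix, iy, iz] += td
                    ledger[LG_LOCAL] += td
                    T -= td
                    if T <= tmin:
                        deposit[ix, iy, iz] += T
                        ledger[LG_DEPOSIT] += T
                        break

            elif event == EV_ELASTIC:
                # pick target element proportional to its contribution
                tot = 0.0
                for k in range(nelem):
                    tot += interp_logt(elpart[mat, k], t0, h, T)
                state, u = rng_u01(state)
                thresh = u * tot
                acc = 0.0
                kel = nelem - 1
                for k in range(nelem):
                    acc += interp_logt(elpart[mat, k], t0, h, T)
                    if acc >= thresh:
                        kel = k
                        break
                if elem_is_h[kel]:
                    # p-p: secondary energy uniform on (0, T)
                    state, u = rng_u01(state)
                    T2 = u * T
                    T1 = T - T2
                    state, u = rng_u01(state)
                    phi = 2.0 * math.pi * u
                    if T2 > tmin and sp < MAX_STACK:
                        sx2, sy2, sz2 = _rotate(ux, uy, uz, _pp_cos(T2, T),
                                                phi + math.pi)
                        stk[sp, 0] = x
                        stk[sp, 1] = y
                        stk[sp, 2] = z
                        stk[sp, 3] = sx2
                        stk[sp, 4] = sy2
                        stk[sp, 5] = sz2
                        stk[sp, 6] = T2
                        sp += 1
                    else:
                        deposit[ix, iy, iz] += T2
                        ledger[LG_DEPOSIT] += T2
                    ux, uy, uz = _rotate(ux, uy, uz, _pp_cos(T1, T), phi)
                    T = T1
                    if T <= tmin:
                        deposit[ix, iy, iz] += T
                        ledger[LG_DEPOSIT] += T
                        break
                else:
                    # p-X elastic from the DB table; recoil is local
                    state, b = _db_bin(T, eb0, ebstep, nbins, state)
                    state, ie, imu = _sample_flat_cum(el_cum[kel, b], nmu,
                                                      state)
                    state, u = rng_u01(state)
                    f = elfrac_edges[ie] + u * (elfrac_edges[ie + 1]
                                                - elfrac_edges[ie])
                    state, u = rng_u01(state)
                    mu = mu_edges[imu] + u * (mu_edges[imu + 1]
                                              - mu_edges[imu])
                    kept = f * T
                    deposit[ix, iy, iz] += T - kept
                    ledger[LG_LOCAL] += T - kept
                    state, u = rng_u01(state)
                    ux, uy, uz = _rotate(ux, uy, uz, mu, 2.0 * math.pi * u)
                    T = kept
                    if T <= tmin:
                        deposit[ix, iy, iz] += T
                        ledger[LG_DEPOSIT] += T
                        break

            elif event == EV_INELASTIC:
                if T < db_floor:
                    # below the database floor: local deposit
                    deposit[ix, iy, iz] += T
                    ledger[LG_DEPOSIT] += T
                    break
                # pick target element (inelastic contributions)
                tot = 0.0
                for k in range(nelem):
                    tot += interp_logt(inelpart[mat, k], t0, h, T)
                state, u = rng_u01(state)
                thresh = u * tot
                acc = 0.0
                kel = nelem - 1
                for k in range(nelem):
                    acc += interp_logt(inelpart[mat, k], t0, h, T)
                    if acc >= thresh:
                        kel = k
                        break
                state, b = _db_bin(T, eb0, ebstep, nbins, state)
                # multiplicity
                state, u = rng_u01(state)
                npro = np.searchsorted(pmult_cum[kel, b], u)
                if npro > pmult_cum.shape[2] - 1:
                    npro = pmult_cum.shape[2] - 1
                e_avail = T - q_reaction
                if e_avail < 0.0:
                    e_avail = 0.0
                fr = np.empty(8)
                mus = np.empty(8)
                ok = False
                for _try in range(100):
                    tot_f = 0.0
                    for kk in range(npro):
                        state, ie, imu = _sample_flat_cum(
                            pjoint_cum[kel, b], nmu, state)
                        state, u = rng_u01(state)
                        fr[kk] = efrac_edges[ie] + u * (efrac_edges[ie + 1]
                                                        - efrac_edges[ie])
                        state, u = rng_u01(state)
                        mus[kk] = mu_edges[imu] + u * (mu_edges[imu + 1]
                                                       - mu_edges[imu])
                        tot_f += fr[kk]
                    if tot_f <= 1.0:
                        ok = True
                        break
                if not ok and npro > 0:
                    excess = tot_f - 1.0
                    fr[npro - 1] = max(fr[npro - 1] - excess, 0.0)
                spent = 0.0
                for kk in range(npro):
                    ek = fr[kk] * e_avail
                    spent += ek
                    if ek > tmin and sp < MAX_STACK:
                        state, u = rng_u01(state)
                        sdx, sdy, sdz = _rotate(ux, uy, uz, mus[kk],
                                                2.0 * math.pi * u)
                        stk[sp, 0] = x
                        stk[sp, 1] = y
                        stk[sp, 2] = z
                        stk[sp, 3] = sdx
                        stk[sp, 4] = sdy
                        stk[sp, 5] = sdz
                        stk[sp, 6] = ek
                        sp += 1
                    else:
                        deposit[ix, iy, iz] += ek
                        ledger[LG_DEPOSIT] += ek
                remainder = T - spent
                nf = neutral_frac[kel, b]
                ledger[LG_NEUTRAL] += nf * remainder
                deposit[ix, iy, iz] += (1.0 - nf) * remainder
                ledger[LG_LOCAL] += (1.0 - nf) * remainder
                break  # incident proton terminated

        # end particle loop
    return nsteps


@njit(cache=True)
def run_batch(
        primaries, seed, hist0,
        matidx, density, ox, oy, oz, sx, sy, sz,
        bx, by, bz,
        t0, h, l_mass, range_mass, sigion_mass, elpart, inelpart,
        x0inv_mass, zoa, is_shifter,
        elem_is_h, eb0, ebstep, nbins, pmult_cum, pjoint_cum, el_cum,
        efrac_edges, mu_edges, elfrac_edges, neutral_frac, nmu,
        q_reaction, db_floor,
        tecut, tmin, range_fraction, shifter_cap, step_cap, eps_mm,
        es_mev, do_straggle, do_ms, do_delta, do_nuclear,
        deposit, ledgers):
    """Transport ``primaries`` (rows: x,y,z,ux,uy,uz,T), history i using
    the substream 2*(hist0+i)+1 of ``seed``. Per-history ledgers are
    written to ``ledgers`` (nh, 4). Returns the number of aborted
    histories (step-cap trips)."""
    nh = primaries.shape[0]
    traj = np.empty((0, 3))
    traj_n = np.zeros(1, dtype=np.int64)
    aborted = 0
    for i in range(nh):
        state = rng_init(seed, 2 * (hist0 + i) + 1)
        r = transport_history(
            primaries[i, 0], primaries[i, 1], primaries[i, 2],
            primaries[i, 3], primaries[i, 4], primaries[i, 5],
            primaries[i, 6], state,
            matidx, density, ox, oy, oz, sx, sy, sz,
            bx, by, bz,
            t0, h, l_mass, range_mass, sigion_mass, elpart, inelpart,
            x0inv_mass, zoa, is_shifter,
            elem_is_h, eb0, ebstep, nbins, pmult_cum, pjoint_cum, el_cum,
            efrac_edges, mu_edges, elfrac_edges, neutral_frac, nmu,
            q_reaction, db_floor,
            tecut, tmin, range_fraction, shifter_cap, step_cap, eps_mm,
            es_mev, do_straggle, do_ms, do_delta, do_nuclear,
            deposit, ledgers[i], traj, traj_n)
        if r < 0:
            aborted += 1
    return aborted
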