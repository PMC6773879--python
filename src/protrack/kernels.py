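"""Numba inner loops for the Monte Carlo transport.

Tables are passed as a flat "medium pack" of arrays (see
`transport.pack_tables`): per species (H+, H0) and process (ionization,
excitation, capture-or-loss, elastic) log-TCS on a log energy grid, plus
the sampling marginals.  All kernels draw randomness from a splitmix64
counter RNG seeded per history, so histories are independent streams and
runs are bit-reproducible for a given seed regardless of batching.

Energy-loss bookkeeping per event (projectile energy E in eV):

* ionization: dE = <binding> + E_k, the ejected electron carries E_k;
* excitation: dE = W of the sampled state, deposited locally;
* capture (H+ -> H0): dE = <binding> + (m_e/m_p) E - 13.6 eV, clamped
  at 0, deposited locally;
* loss (H0 -> H+): electron launched forward with E_e = (m_e/m_p) E,
  dE = 13.6 eV + E_e;
* elastic: direction change only; the nuclear recoil T = T_max
  sin^2(theta/2) is deposited locally in dose mode and excluded from the
  electronic stopping-power tallies.

Secondary electrons use analytic water cross sections (binary-encounter
ionization per molecular orbital, velocity-scaled excitation, screened-
Rutherford elastic) scaled by the medium's electron count, and deposit
their remaining energy locally below the 7.4 eV cutoff.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

ME_MP = 1.0 / 1836.15267343
H_BIND = 13.605693122994
E_CUTOFF_EV = 7.4
P_CUTOFF_EV = 10.0e3

# water molecular-orbital data for the secondary-electron model
_E_B = np.array([12.6, 14.7, 18.4, 32.2, 539.7])
_E_N = np.array([2.0, 2.0, 2.0, 2.0, 2.0])
RYD = 13.605693122994
A0SQ = 2.800285e-17

# ----------------------------------------------------------------------
# counter RNG: splitmix64
# ----------------------------------------------------------------------


@njit(cache=True, inline="always")
def _sm64(state):
    state = (state + np.uint64(0x9E3779B97F4A7C15)) & np.uint64(-1)
    z = state
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) \
        & np.uint64(-1)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) \
        & np.uint64(-1)
    z = z ^ (z >> np.uint64(31))
    return state, z


@njit(cache=True, inline="always")
def _mix64(x):
    z = x
    z = ((z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) \
        & np.uint64(-1)
    z = ((z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) \
        & np.uint64(-1)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _rng_init(seed, history):
    """Per-history substream: the history index is hashed through the
    avalanche finalizer so streams carry no arithmetic relation to the
    generator's own increment."""
    a = _mix64((np.uint64(history) + np.uint64(0x6A09E667F3BCC909))
               & np.uint64(-1))
    s = _mix64((a + np.uint64(seed) * np.uint64(0xD1342543DE82EF95))
               & np.uint64(-1))
    return s


@njit(cache=True, inline="always")
def _uniform(state):
    state, z = _sm64(state)
    return state, (np.float64(z >> np.uint64(11))
                   * (1.0 / 9007199254740992.0))


# ----------------------------------------------------------------------
# table lookups
# ----------------------------------------------------------------------


@njit(cache=True, inline="always")
def _grid_pos(log_e_grid, log_e):
    n = log_e_grid.shape[0]
    if log_e <= log_e_grid[0]:
        return 0, 0.0
    if log_e >= log_e_grid[n - 1]:
        return n - 2, 1.0
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if log_e_grid[mid] <= log_e:
            lo = mid
        else:
            hi = mid
    t = (log_e - log_e_grid[lo]) / (log_e_grid[lo + 1] - log_e_grid[lo])
    return lo, t


@njit(cache=True, inline="always")
def _tcs_at(log_tcs, m, sp, pr, ie, t):
    a = log_tcs[m, sp, pr, ie]
    b = log_tcs[m, sp, pr, ie + 1]
    v = (1.0 - t) * a + t * b
    if v < -500.0:
        return 0.0
    return math.exp(v)


@njit(cache=True, inline="always")
def _invert_cdf_log(grid_row, cdf_row, u):
    """CDF inversion with geometric interpolation between grid points
    (appropriate for log-spaced grids carrying ~1/E-type densities)."""
    n = grid_row.shape[0]
    if u <= cdf_row[0]:
        return grid_row[0]
    for i in range(1, n):
        if cdf_row[i] >= u:
            c0 = cdf_row[i - 1]
            c1 = cdf_row[i]
            if c1 <= c0 or grid_row[i - 1] <= 0.0:
                return grid_row[i]
            w = (u - c0) / (c1 - c0)
            return grid_row[i - 1] * (grid_row[i] / grid_row[i - 1]) ** w
    return grid_row[n - 1]


@njit(cache=True, inline="always")
def _invert_cdf(grid_row, cdf_row, u):
    n = grid_row.shape[0]
    if u <= cdf_row[0]:
        return grid_row[0]
    for i in range(1, n):
        if cdf_row[i] >= u:
            c0 = cdf_row[i - 1]
            c1 = cdf_row[i]
            if c1 <= c0:
                return grid_row[i]
            w = (u - c0) / (c1 - c0)
            return grid_row[i - 1] + w * (grid_row[i] - grid_row[i - 1])
    return grid_row[n - 1]


# ----------------------------------------------------------------------
# secondary-electron analytic model (water, electron-count scaled)
# ----------------------------------------------------------------------


@njit(cache=True)
def _e_sigma_ion(t_ev):
    """Binary-encounter(BEB-style) ionization TCS per water molecule."""
    tot = 0.0
    for i in range(5):
        b = _E_B[i]
        t = t_ev / b
        if t <= 1.0:
            continue
        u = 0.5  # reduced orbital kinetic term, folded constant
        s = 4.0 * math.pi * A0SQ * _E_N[i] * (RYD / b) ** 2
        lnt = math.log(t)
        tot += s / (t + u + 1.0) * (0.5 * lnt * (1.0 - 1.0 / (t * t))
                                    + 1.0 - 1.0 / t
                                    - lnt / (t + 1.0))
    return tot


@njit(cache=True)
def _e_sigma_exc(t_ev):
    """Excitation: velocity scaling of the proton Miller-Green fit
    (a proton of the same speed has E = (m_p/m_e) T)."""
    e_kev = t_ev / ME_MP * 1e-3
    tot = 0.0
    ws = (8.17, 10.13, 11.31, 12.91, 14.50)
    aa = (876.0, 2084.0, 1373.0, 1692.0, 900.0)
    jj = (19820.0, 23490.0, 27770.0, 30830.0, 33080.0)
    om = (0.85, 0.88, 0.88, 0.78, 0.78)
    for i in range(5):
        if t_ev <= ws[i]:
            continue
        e_ev = e_kev * 1e3
        num = (10.0 * aa[i]) ** om[i] * (e_ev - ws[i])
        den = jj[i] ** (om[i] + 1.0) + e_ev ** (om[i] + 1.0)
        tot += 1e-16 * num / den
    return tot


@njit(cache=True)
def _e_sigma_el(t_ev):
    """Screened-Rutherford elastic TCS per water molecule (Z = 10)."""
    z = 10.0
    tau = t_ev / 511.0e3
    eta = 1.7e-5 * z ** (2.0 / 3.0) / max(tau * (tau + 2.0), 1e-12)
    t_ryd = t_ev / RYD
    sig = math.pi * z * (z + 1.0) * A0SQ * 4.0 / (
        t_ryd * t_ryd * eta * (1.0 + eta)) * 1e-2
    return sig


@njit(cache=True)
def _transport_electron(e0_ev, x0, y0, z0, ux0, uy0, uz0, rng, geom,
                        region_nd, e_scale, tally):
    """Event-by-event electron transport; deposits into tally[:, 2].

    geom: (r_nucleus, r_cyto, r_cell) in cm (geom[2] <= 0 -> infinite
    single-region medium).  region_nd: per-region molecular number
    density; e_scale: per-region electron-count scale relative to water.
    Secondaries are handled with an explicit stack; the sum of deposits
    plus the returned escaped energy equals e0_ev exactly.
    """
    stk_e = np.empty(64)
    stk_x = np.empty(64)
    stk_y = np.empty(64)
    stk_z = np.empty(64)
    stk_u = np.empty((64, 3))
    top = 0
    stk_e[0] = e0_ev
    stk_x[0] = x0
    stk_y[0] = y0
    stk_z[0] = z0
    stk_u[0, 0] = ux0
    stk_u[0, 1] = uy0
    stk_u[0, 2] = uz0
    escaped = 0.0
    while top >= 0:
        e_ev = stk_e[top]
        x = stk_x[top]
        y = stk_y[top]
        z = stk_z[top]
        ux = stk_u[top, 0]
        uy = stk_u[top, 1]
        uz = stk_u[top, 2]
        top -= 1
        while e_ev > E_CUTOFF_EV:
            reg = _region_of(x, y, z, geom)
            if reg == 3:
                escaped += e_ev
                e_ev = 0.0
                break
            nd_eff = region_nd[reg] * e_scale[reg]
            s_ion = _e_sigma_ion(e_ev)
            s_exc = _e_sigma_exc(e_ev)
            s_el = _e_sigma_el(e_ev)
            s_tot = s_ion + s_exc + s_el
            if s_ion + s_exc <= 0.0 or nd_eff <= 0.0:
                # sub-excitation electron: only elastic channels remain,
                # deposit on the spot
                break
            lam = 1.0 / (nd_eff * s_tot)
            rng, u = _uniform(rng)
            step = -lam * math.log(max(u, 1e-300))
            db = _dist_to_boundary(x, y, z, ux, uy, uz, geom)
            if db < step:
                adv = db + 1e-6 * lam
                x += ux * adv
                y += uy * adv
                z += uz * adv
                continue
            x += ux * step
            y += uy * step
            z += uz * step
            reg = _region_of(x, y, z, geom)
            if reg == 3:
                escaped += e_ev
                e_ev = 0.0
                break
            rng, u = _uniform(rng)
            pick = u * s_tot
            if pick < s_ion:
                # orbital with binding below E, weighted by occupation
                nopen = 0
                for i in range(5):
                    if _E_B[i] < e_ev:
                        nopen += 1
                rng, u2 = _uniform(rng)
                idx = min(int(u2 * nopen), nopen - 1)
                b = _E_B[idx]
                wmax = 0.5 * (e_ev - b)
                if wmax <= 0.0:
                    break
                # f(w) ~ 1/(w + b)^2 on [0, wmax]
                rng, u3 = _uniform(rng)
                w = b * u3 * wmax / (b + wmax - u3 * wmax)
                tally[reg, 2] += b
                e_ev = e_ev - b - w
                if w <= E_CUTOFF_EV:
                    tally[reg, 2] += w
                elif top < 62:
                    rng, a1 = _uniform(rng)
                    rng, a2 = _uniform(rng)
                    ct = 2.0 * a1 - 1.0
                    st = math.sqrt(max(0.0, 1.0 - ct * ct))
                    ph = 2.0 * math.pi * a2
                    top += 1
                    stk_e[top] = w
                    stk_x[top] = x
                    stk_y[top] = y
                    stk_z[top] = z
                    stk_u[top, 0] = st * math.cos(ph)
                    stk_u[top, 1] = st * math.sin(ph)
                    stk_u[top, 2] = ct
                else:
                    tally[reg, 2] += w
            elif pick < s_ion + s_exc:
                rng, u2 = _uniform(rng)
                w_ev = 8.17 + u2 * (14.50 - 8.17)
                w_ev = min(w_ev, e_ev)
                tally[reg, 2] += w_ev
                e_ev -= w_ev
            else:
                tau = e_ev / 511.0e3
                eta = 1.7e-5 * 10.0 ** (2.0 / 3.0) / max(
                    tau * (tau + 2.0), 1e-12)
                rng, u2 = _uniform(rng)
                ct = 1.0 - 2.0 * eta * u2 / (1.0 + eta - u2)
                ct = min(1.0, max(-1.0, ct))
                rng, u3 = _uniform(rng)
                ux, uy, uz = _rotate(ux, uy, uz, ct, 2.0 * math.pi * u3)
        if e_ev > 0.0:
            reg = _region_of(x, y, z, geom)
            if reg == 3:
                escaped += e_ev
            else:
                tally[reg, 2] += e_ev
    return rng, escaped


@njit(cache=True, inline="always")
def _region_of(x, y, z, geom):
    """0 nucleus, 1 cytoplasm, 2 membrane, 3 outside.  geom radii in cm;
    geom[2] <= 0 means an infinite single-region medium."""
    if geom[2] <= 0.0:
        return 0
    r2 = x * x + y * y + z * z
    if r2 <= geom[0] * geom[0]:
        return 0
    if r2 <= geom[1] * geom[1]:
        return 1
    if r2 <= geom[2] * geom[2]:
        return 2
    return 3


@njit(cache=True, inline="always")
def _dist_to_boundary(x, y, z, ux, uy, uz, geom):
    """Distance along (ux,uy,uz) to the nearest region boundary sphere."""
    if geom[2] <= 0.0:
        return 1e30
    best = 1e30
    b = x * ux + y * uy + z * uz
    c0 = x * x + y * y + z * z
    for i in range(3):
        r = geom[i]
        c = c0 - r * r
        disc = b * b - c
        if disc <= 0.0:
            continue
        sq = math.sqrt(disc)
        t1 = -b - sq
        t2 = -b + sq
        if t1 > 1e-12 and t1 < best:
            best = t1
        if t2 > 1e-12 and t2 < best:
            best = t2
    return best


@njit(cache=True, inline="always")
def _rotate(ux, uy, uz, ct, phi):
    """Rotate unit vector by polar angle acos(ct), azimuth phi."""
    st = math.sqrt(max(0.0, 1.0 - ct * ct))
    cp = math.cos(phi)
    sp = math.sin(phi)
    if abs(uz) > 0.99999999:
        sign = 1.0 if uz > 0.0 else -1.0
        return st * cp, sign * st * sp, sign * ct
    s = math.sqrt(1.0 - uz * uz)
    vx = st * (cp * uz * ux - sp * uy) / s + ct * ux
    vy = st * (cp * uz * uy + sp * ux) / s + ct * uy
    vz = -st * cp * s + ct * uz
    norm = math.sqrt(vx * vx + vy * vy + vz * vz)
    return vx / norm, vy / norm, vz / norm


# ----------------------------------------------------------------------
# projectile kernels
# ----------------------------------------------------------------------


@njit(cache=True)
def _inelastic_tcs(log_tcs, m, sp, ie, t):
    s = _tcs_at(log_tcs, m, sp, 0, ie, t)
    s += _tcs_at(log_tcs, m, sp, 1, ie, t)
    s += _tcs_at(log_tcs, m, sp, 2, ie, t)
    return s


@njit(cache=True)
def _sample_loss(rng, m, sp, e_ev, log_e_grid, log_tcs, ek_grid, ek_cdf,
                 binding, exc_cdf, exc_w):
    """Pick an inelastic process and return
    (rng, process, dE_projectile, E_secondary)."""
    log_e = math.log(e_ev * 1e-3)
    ie, t = _grid_pos(log_e_grid, log_e)
    s0 = _tcs_at(log_tcs, m, sp, 0, ie, t)
    s1 = _tcs_at(log_tcs, m, sp, 1, ie, t)
    s2 = _tcs_at(log_tcs, m, sp, 2, ie, t)
    tot = s0 + s1 + s2
    rng, u = _uniform(rng)
    pick = u * tot
    # stochastic interpolation between energy nodes for the marginals
    rng, un = _uniform(rng)
    node = ie + 1 if un < t else ie
    if pick < s0:                       # ionization
        rng, u2 = _uniform(rng)
        ek = _invert_cdf_log(ek_grid[m, node], ek_cdf[m, node], u2)
        de = binding[m, node] + ek
        if de > e_ev:
            de = e_ev
            ek = max(0.0, e_ev - binding[m, node])
        return rng, 0, de, ek
    if pick < s0 + s1:                  # excitation
        rng, u2 = _uniform(rng)
        iw = 0
        for j in range(5):
            if exc_cdf[m, node, j] >= u2:
                iw = j
                break
        w = exc_w[iw]
        return rng, 1, min(w, e_ev), 0.0
    if sp == 0:                          # capture
        de = binding[m, node] + ME_MP * e_ev - H_BIND
        if de < 0.0:
            de = 0.0
        return rng, 2, min(de, e_ev), 0.0
    # loss
    e_e = ME_MP * e_ev
    return rng, 3, min(H_BIND + e_e, e_ev), e_e


@njit(cache=True)
def stationary_sp(e_kev, n_proj, seed, m, log_e_grid, log_tcs, ek_grid,
                  ek_cdf, binding, exc_cdf, exc_w, nd):
    """Stationary-mode stopping power per species.

    Each projectile is followed to its first inelastic interaction; the
    estimator is SP_sp = sum dE / sum path.  Returns
    (sp_Hplus, sp_H0, err_Hplus, err_H0) in eV/cm.
    """
    e_ev = e_kev * 1e3
    log_e = math.log(e_kev)
    ie, t = _grid_pos(log_e_grid, log_e)
    out = np.zeros(4)
    for sp in range(2):
        sig = _inelastic_tcs(log_tcs, m, sp, ie, t)
        if sig <= 0.0:
            continue
        lam = 1.0 / (nd * sig)
        s_de = 0.0
        s_de2 = 0.0
        s_path = 0.0
        for h in range(n_proj):
            rng = _rng_init(seed + 1000003 * sp, h)
            rng, u = _uniform(rng)
            path = -lam * math.log(max(u, 1e-300))
            rng, proc, de, esec = _sample_loss(
                rng, m, sp, e_ev, log_e_grid, log_tcs, ek_grid, ek_cdf,
                binding, exc_cdf, exc_w)
            s_de += de
            s_de2 += de * de
            s_path += path
        sp_val = s_de / s_path
        mean_de = s_de / n_proj
        var_de = s_de2 / n_proj - mean_de * mean_de
        # relative errors of numerator and denominator in quadrature
        rel2 = (var_de / (mean_de * mean_de) + 1.0) / n_proj
        out[sp] = sp_val
        out[2 + sp] = sp_val * math.sqrt(max(rel2, 0.0))
    return out


@njit(cache=True)
def slowing_down_path(e0_kev, n_hist, seed, m, log_e_grid, log_tcs,
                      ek_grid, ek_cdf, binding, exc_cdf, exc_w, nd,
                      start_h0_fraction):
    """Slowing-down total path length (cm) to the 10 keV cutoff.

    Charge-changing cycles included; elastic deflection ignored (it does
    not change the path length).  Returns (mean, std_of_mean).
    """
    tot = 0.0
    tot2 = 0.0
    for h in range(n_hist):
        rng = _rng_init(seed, h)
        e_ev = e0_kev * 1e3
        rng, u0 = _uniform(rng)
        sp = 1 if u0 < start_h0_fraction else 0
        path = 0.0
        while e_ev > P_CUTOFF_EV:
            log_e = math.log(e_ev * 1e-3)
            ie, t = _grid_pos(log_e_grid, log_e)
            sig = _inelastic_tcs(log_tcs, m, sp, ie, t)
            lam = 1.0 / (nd * sig)
            rng, u = _uniform(rng)
            path += -lam * math.log(max(u, 1e-300))
            rng, proc, de, esec = _sample_loss(
                rng, m, sp, e_ev, log_e_grid, log_tcs, ek_grid, ek_cdf,
                binding, exc_cdf, exc_w)
            e_ev -= de
            if proc == 2:
                sp = 1
            elif proc == 3:
                sp = 0
        tot += path
        tot2 += path * path
    mean = tot / n_hist
    var = tot2 / n_hist - mean * mean
    return mean, math.sqrt(max(var, 0.0) / n_hist)


@njit(cache=True)
def cell_irradiation(e0_kev, h_start, h_end, seed, geom, region_medium,
                     log_e_grid, log_tcs, ek_grid, ek_cdf, binding,
                     exc_cdf, exc_w, cos_nodes, theta_cdf, el_x, el_theta,
                     nd, e_scale, elastic_mass, transport_electrons,
                     tally, cosine_source):
    """Slowing-down transport of protons through the spherical cell.

    geom = (r_nucleus, r_cyto_outer, r_cell) cm; region_medium maps
    region -> medium index in the packed tables; tally (3 regions x 3
    species) accumulates deposits in eV.  Returns total escaped energy.
    """
    escaped = 0.0
    r_cell = geom[2]
    for h in range(h_start, h_end):
        rng = _rng_init(seed, h)
        # start point uniform on the outer sphere; inward direction
        rng, a1 = _uniform(rng)
        rng, a2 = _uniform(rng)
        ctp = 2.0 * a1 - 1.0
        stp = math.sqrt(max(0.0, 1.0 - ctp * ctp))
        php = 2.0 * math.pi * a2
        x = r_cell * stp * math.cos(php) * 0.9999999
        y = r_cell * stp * math.sin(php) * 0.9999999
        z = r_cell * ctp * 0.9999999
        # inward direction about the inward normal
        nxi = -x / r_cell
        nyi = -y / r_cell
        nzi = -z / r_cell
        rng, b1 = _uniform(rng)
        rng, b2 = _uniform(rng)
        if cosine_source:
            ct = math.sqrt(b1)
        else:
            ct = b1
        ph = 2.0 * math.pi * b2
        ux, uy, uz = _rotate(nxi, nyi, nzi, ct, ph)

        e_ev = e0_kev * 1e3
        sp = 0
        while True:
            reg = _region_of(x, y, z, geom)
            if reg == 3:
                escaped += e_ev
                break
            if e_ev <= P_CUTOFF_EV:
                tally[reg, sp] += e_ev
                break
            m = region_medium[reg]
            log_e = math.log(e_ev * 1e-3)
            ie, t = _grid_pos(log_e_grid, log_e)
            sig_in = _inelastic_tcs(log_tcs, m, sp, ie, t)
            sig_el = _tcs_at(log_tcs, m, sp, 3, ie, t)
            sig = sig_in + sig_el
            lam = 1.0 / (nd[m] * sig)
            rng, u = _uniform(rng)
            step = -lam * math.log(max(u, 1e-300))
            db = _dist_to_boundary(x, y, z, ux, uy, uz, geom)
            if db < step:
                adv = db + 1e-4 * lam
                x += ux * adv
                y += uy * adv
                z += uz * adv
                continue
            x += ux * step
            y += uy * step
            z += uz * step
            reg = _region_of(x, y, z, geom)
            if reg == 3:
                escaped += e_ev
                break
            rng, u2 = _uniform(rng)
            if u2 * sig < sig_el:
                # elastic: P(theta > theta(sqrt(u) rho_c)) = u
                rng, u3 = _uniform(rng)
                rng, un = _uniform(rng)
                node = ie + 1 if un < t else ie
                th = _interp1(el_x, el_theta[m, node], u3)
                # recoil energy (deposited locally, nuclear)
                mt = elastic_mass[m] / 1.00727646688
                tmax = 4.0 * mt / (1.0 + mt) ** 2 * e_ev
                trec = tmax * math.sin(0.5 * th) ** 2
                if trec > 0.0:
                    trec = min(trec, e_ev)
                    tally[reg, sp] += trec
                    e_ev -= trec
                rng, u4 = _uniform(rng)
                ux, uy, uz = _rotate(ux, uy, uz, math.cos(th),
                                     2.0 * math.pi * u4)
                continue
            rng, proc, de, esec = _sample_loss(
                rng, m, sp, e_ev, log_e_grid, log_tcs, ek_grid, ek_cdf,
                binding, exc_cdf, exc_w)
            e_ev -= de
            local = de - esec
            tally[reg, sp] += local
            if esec > 0.0:
                if transport_electrons:
                    if proc == 0:
                        # ejection angle from the tabulated marginal
                        rng, un = _uniform(rng)
                        node = ie + 1 if un < t else ie
                        iek = _nearest_ek(ek_grid[m, node], esec)
                        rng, u5 = _uniform(rng)
                        ctd = _invert_cdf(cos_nodes,
                                          theta_cdf[m, node, iek], u5)
                        rng, u6 = _uniform(rng)
                        ex, ey, ez = _rotate(ux, uy, uz, ctd,
                                             2.0 * math.pi * u6)
                    else:
                        ex, ey, ez = ux, uy, uz
                    rng, esc_e = _transport_electron(
                        esec, x, y, z, ex, ey, ez, rng, geom, nd,
                        e_scale, tally)
                    escaped += esc_e
                else:
                    tally[reg, 2] += esec
            if proc == 2:
                sp = 1
            elif proc == 3:
                sp = 0
    return escaped


@njit(cache=True, inline="always")
def _interp1(xs, ys, x):
    n = xs.shape[0]
    if x <= xs[0]:
        return ys[0]
    if x >= xs[n - 1]:
        return ys[n - 1]
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if xs[mid] <= x:
            lo = mid
        else:
            hi = mid
    w = (x - xs[lo]) / (xs[lo + 1] - xs[lo])
    return ys[lo] + w * (ys[lo + 1] - ys[lo])


@njit(cache=True, inline="always")
def _nearest_ek(ek_row, e):
    n = ek_row.shape[0]
    best = 0
    bd = 1e300
    for i in range(n):
        d = abs(ek_row[i] - e)
        if d < bd:
            bd = d
            best = i
    return best
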