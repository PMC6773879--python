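"""Closed-form Coulomb integrals for the distorted-wave amplitudes.

Two families are provided, both in hartree atomic units:

* the Nordsieck integral

      J0(alpha, Q; k, lam) = int d3x e^{iQ.x} e^{-alpha x} / x
                               1F1(i lam; 1; i(k x + k.x))
                           = 4 pi A^{i lam - 1} B^{-i lam},
      A = Q.Q + alpha^2,  B = A + 2 Q.k - 2 i alpha k,

  together with its alpha-derivative and Q-gradient (all elementary), for
  the target-side bound-continuum matrix elements; and

* the eikonal-power family

      K(beta, Q; p, zeta; nu) = int d3s e^{iQ.s} e^{-beta s} / s
                                  (v s + v.s)^{-i nu - 1}
                                  1F1(i zeta; 1; i(p s + p.s)),

  with its beta-derivative and Q-gradient, for the projectile-side factors
  of the eikonal-initial-state perturbation.  K is evaluated through the
  representation (u = v s + v.s)

      u^{-i nu - 1} = 1/Gamma(1 + i nu) int_0^inf tau^{i nu} e^{-tau u} dtau,

  under which the s-integral becomes J0 with alpha -> beta + tau v and
  Q -> Q + i tau v zhat, whose A and B coefficients are LINEAR in tau.  The
  remaining 1-D tau-integral is done with an analytic small-tau head, a
  Gauss-Legendre middle section in log(tau), and an Abel-regularized
  power-law tail (the tau-integral converges only in the Abel sense, which
  is the limit of the absolutely convergent regularized s-integral).

  Branch note: along the tau path Re A > 0 always, and Im B decreases
  monotonically from a start on or below the real axis (q_z > 0 for both
  ionization and capture kinematics), so B never crosses the negative real
  axis and the principal powers are the correct analytic continuation.

The velocity v is taken along +z throughout.
"""

from __future__ import annotations

import numpy as np
from scipy.special import gamma as cgamma

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:      # pragma: no cover - numba is a hard dependency
    _HAVE_NUMBA = False

FOUR_PI = 4.0 * np.pi

__all__ = ["j0_closed", "j0_dalpha", "j0_gradq", "k_family",
           "coulomb_norm"]


def coulomb_norm(a):
    """N(a) = Gamma(1 - i a) exp(pi a / 2)."""
    return cgamma(1.0 - 1j * np.asarray(a)) * np.exp(np.pi * np.asarray(a) / 2.0)


def _ab(alpha, qx, qy, qz, kx, ky, kz, kmag):
    a = qx * qx + qy * qy + qz * qz + alpha * alpha
    b = a + 2.0 * (qx * kx + qy * ky + qz * kz) - 2j * alpha * kmag
    return a, b


def j0_closed(alpha, qx, qy, qz, kx, ky, kz, kmag, lam):
    a, b = _ab(alpha, qx, qy, qz, kx, ky, kz, kmag)
    il = 1j * lam
    return FOUR_PI * a ** (il - 1.0) * b ** (-il)


def j0_dalpha(alpha, qx, qy, qz, kx, ky, kz, kmag, lam):
    """d J0 / d alpha."""
    a, b = _ab(alpha, qx, qy, qz, kx, ky, kz, kmag)
    il = 1j * lam
    da = 2.0 * alpha
    db = 2.0 * alpha - 2j * kmag
    core = a ** (il - 1.0) * b ** (-il)
    return FOUR_PI * core * ((il - 1.0) * da / a - il * db / b)


def j0_gradq(alpha, qx, qy, qz, kx, ky, kz, kmag, lam):
    """(d/dQx, d/dQy, d/dQz) of J0."""
    a, b = _ab(alpha, qx, qy, qz, kx, ky, kz, kmag)
    il = 1j * lam
    core = FOUR_PI * a ** (il - 1.0) * b ** (-il)
    fa = (il - 1.0) / a
    fb = -il / b
    gx = core * (fa * 2.0 * qx + fb * (2.0 * qx + 2.0 * kx))
    gy = core * (fa * 2.0 * qy + fb * (2.0 * qy + 2.0 * ky))
    gz = core * (fa * 2.0 * qz + fb * (2.0 * qz + 2.0 * kz))
    return gx, gy, gz


# ----------------------------------------------------------------------
# eikonal-power family
# ----------------------------------------------------------------------

if _HAVE_NUMBA:

    @njit(cache=True, fastmath=False)
    def _k_middle_numba(a0, a1, b0, b1, beta, qx, qy, qz, px, py, pz,
                        pmag, zeta, ulo, uhi, xg, wg, inu, v,
                        out):      # pragma: no cover - exercised via wrapper
        n = a0.shape[0]
        ng = xg.shape[0]
        for i in range(n):
            iz = 1j * zeta[i]
            acc_k = 0.0 + 0.0j
            acc_db = 0.0 + 0.0j
            acc_gx = 0.0 + 0.0j
            acc_gy = 0.0 + 0.0j
            acc_gz = 0.0 + 0.0j
            half = 0.5 * (uhi[i] - ulo[i])
            for j in range(ng):
                u = half * (xg[j] + 1.0) + ulo[i]
                du = half * wg[j]
                tau = np.exp(u)
                a = a0[i] + a1[i] * tau
                b = b0[i] + b1[i] * tau
                core = np.exp((iz - 1.0) * np.log(a) - iz * np.log(b))
                w = np.exp((1.0 + inu) * u) * du
                cw = core * w
                acc_k += cw
                da = 2.0 * beta[i] + 2.0 * tau * v
                db = da - 2j * pmag[i]
                fa = (iz - 1.0) / a
                fb = -iz / b
                acc_db += cw * (fa * da + fb * db)
                dax = 2.0 * qx[i]
                acc_gx += cw * (fa * dax + fb * (dax + 2.0 * px[i]))
                day = 2.0 * qy[i]
                acc_gy += cw * (fa * day + fb * (day + 2.0 * py[i]))
                daz = 2.0 * qz[i] + 2j * tau * v
                acc_gz += cw * (fa * daz + fb * (daz + 2.0 * pz[i]))
            out[0, i] = acc_k
            out[1, i] = acc_db
            out[2, i] = acc_gx
            out[3, i] = acc_gy
            out[4, i] = acc_gz

def _k_integrands(tau, a0, a1, b0, b1, beta, v, qj, pj, pmag, zeta, which):
    """tau-integrand values (without the tau^{i nu} factor).

    A = a0 + a1 tau and B = b0 + b1 tau are linear in tau; derivative
    integrands follow by differentiating the A, B arguments w.r.t. beta or
    a Q component.
    """
    a = a0 + a1 * tau
    b = b0 + b1 * tau
    iz = 1j * zeta
    core = a ** (iz - 1.0) * b ** (-iz)
    out = []
    for w in which:
        if w == "k":
            out.append(core)
        elif w == "dbeta":
            da = 2.0 * beta + 2.0 * tau * v
            db = da - 2j * pmag
            out.append(core * ((iz - 1.0) * da / a - iz * db / b))
        elif w in ("gx", "gy", "gz"):
            j = {"gx": 0, "gy": 1, "gz": 2}[w]
            da = 2.0 * qj[j] + (2j * tau * v if j == 2 else 0.0)
            db = da + 2.0 * pj[j]
            out.append(core * ((iz - 1.0) * da / a - iz * db / b))
        else:
            raise ValueError(w)
    return out


def k_family(beta, qx, qy, qz, px, py, pz, pmag, zeta, nu, v,
             n_mid=96, outputs=("k", "dbeta", "gx", "gy", "gz")):
    """Evaluate K and its derivatives on broadcast node arrays.

    Node arguments broadcast to a common shape; ``nu`` and ``v`` are
    scalars.  Returns {output name: complex array}.  Relative accuracy is
    set by the middle-section Gauss order ``n_mid`` (~1e-6 at default).
    """
    arrs = [np.asarray(w, dtype=float)
            for w in (beta, qx, qy, qz, px, py, pz, pmag, zeta)]
    shape = np.broadcast_shapes(*(a.shape for a in arrs))
    n_nodes = int(np.prod(shape)) if shape else 1
    # bound memory: the middle section builds (nodes, n_mid) complex
    # temporaries, so process large node sets in chunks
    max_chunk = 16384
    if n_nodes > max_chunk:
        flat = [np.broadcast_to(a, shape).reshape(-1) for a in arrs]
        res = {w: np.empty(n_nodes, dtype=complex) for w in outputs}
        for lo in range(0, n_nodes, max_chunk):
            hi = min(lo + max_chunk, n_nodes)
            sub = k_family(*(f[lo:hi] for f in flat), nu, v,
                           n_mid=n_mid, outputs=outputs)
            for w in outputs:
                res[w][lo:hi] = sub[w]
        return {w: res[w].reshape(shape) for w in outputs}
    beta, qx, qy, qz, px, py, pz, pmag, zeta = (
        np.ascontiguousarray(np.broadcast_to(a, shape).reshape(-1, 1))
        for a in arrs)
    qj = (qx, qy, qz)
    pj = (px, py, pz)

    a0 = qx * qx + qy * qy + qz * qz + beta * beta
    a1 = 2.0 * v * (beta + 1j * qz)
    b0 = a0 + 2.0 * (qx * px + qy * py + qz * pz) - 2j * beta * pmag
    b1 = a1 + 2j * v * (pz - pmag)

    absb1 = np.abs(b1)
    absb1 = np.where(absb1 == 0.0, 1.0, absb1)
    s_a = np.abs(a0) / np.abs(a1)
    s_b = np.abs(b0) / absb1
    s_lo = np.clip(np.minimum(s_a, s_b), 1e-12, None)
    s_hi = np.maximum(s_a, s_b)
    eps = 1e-5 * s_lo
    big = 400.0 * np.clip(s_hi, s_lo, None) + 400.0 / v

    inu = 1j * nu
    res = {w: np.zeros((shape and int(np.prod(shape))) or 1, dtype=complex)
           for w in outputs}

    # analytic head: int_0^eps tau^{i nu} (g0 + g0' tau) dtau
    g0s = _k_integrands(0.0, a0, a1, b0, b1, beta, v, qj, pj, pmag, zeta,
                        outputs)
    ges = _k_integrands(eps, a0, a1, b0, b1, beta, v, qj, pj, pmag, zeta,
                        outputs)
    for w, g0, ge in zip(outputs, g0s, ges):
        slope = (ge - g0) / eps
        head = (g0 * eps ** (1.0 + inu) / (1.0 + inu)
                + slope * eps ** (2.0 + inu) / (2.0 + inu))
        res[w] += head[:, 0]

    # middle: Gauss-Legendre in log(tau) on [eps, big]
    xg, wg = np.polynomial.legendre.leggauss(n_mid)
    ulo = np.log(eps)
    uhi = np.log(big)
    if _HAVE_NUMBA and tuple(outputs) == ("k", "dbeta", "gx", "gy", "gz"):
        out = np.empty((5, a0.shape[0]), dtype=complex)
        _k_middle_numba(a0[:, 0], a1[:, 0], b0[:, 0], b1[:, 0],
                        beta[:, 0], qx[:, 0], qy[:, 0], qz[:, 0],
                        px[:, 0], py[:, 0], pz[:, 0], pmag[:, 0],
                        zeta[:, 0], ulo[:, 0], uhi[:, 0], xg, wg,
                        complex(inu), float(v), out)
        for idx, w in enumerate(outputs):
            res[w] += out[idx]
    else:
        u = 0.5 * (uhi - ulo) * (xg[None, :] + 1.0) + ulo
        du = 0.5 * (uhi - ulo) * wg[None, :]
        tau = np.exp(u)
        gs = _k_integrands(tau, a0, a1, b0, b1, beta, v, qj, pj, pmag,
                           zeta, outputs)
        phase = np.exp((1.0 + inu) * u) * du
        for w, g in zip(outputs, gs):
            res[w] += np.sum(g * phase, axis=1)

    # Abel-regularized tail: fit g ~ sum_m c_m (tau/big)^{-m}, m = 1..4
    tpow = np.array([1.0, 2.0, 4.0, 8.0])
    tg = _k_integrands(big * tpow[None, :], a0, a1, b0, b1, beta, v, qj, pj,
                       pmag, zeta, outputs)
    m = np.arange(1, 5, dtype=float)
    vinv = np.linalg.inv(tpow[:, None] ** (-m[None, :]))
    tail_int = big ** (1.0 + inu) / (m[None, :] - 1.0 - inu)
    for w, g in zip(outputs, tg):
        cm = g @ vinv.T
        res[w] += np.sum(cm * tail_int, axis=1)

    gam = cgamma(1.0 + 1j * nu)
    return {w: (FOUR_PI / gam) * res[w].reshape(shape) for w in outputs}
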