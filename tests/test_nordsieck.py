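"""Closed-form Coulomb integrals: independent quadrature oracles and
derivative consistency."""

import numpy as np
import pytest
from scipy.special import j0 as besj0

from protrack.nordsieck import coulomb_norm, j0_closed, j0_dalpha, k_family


def _j0_numeric(alpha, Q, k, lam, nr=260, nt=90):
    """Direct 2-D quadrature of the Nordsieck integral (k along z,
    azimuthal Bessel reduction), using the oracle-grade 1F1."""
    from protrack.cdweis import _hyp1f1_imag
    rmax = 40.0 / alpha
    xr, wr = np.polynomial.legendre.leggauss(nr)
    r = 0.5 * rmax * (xr + 1.0)
    wr = 0.5 * rmax * wr
    ct, wt = np.polynomial.legendre.leggauss(nt)
    total = 0j
    for ri, wi in zip(r, wr):
        f = _hyp1f1_imag(lam, k[2] * ri * (1.0 + ct))
        st = np.sqrt(1.0 - ct ** 2)
        ang = (besj0(Q[0] * ri * st) * np.exp(1j * Q[2] * ri * ct) * f)
        total += wi * ri * np.exp(-alpha * ri) * 2 * np.pi * (wt @ ang)
    return total


@pytest.mark.parametrize("alpha,Q,kz,lam", [
    (1.0, (0.5, 0.0, 0.8), 1.3, 0.6),
    (0.7, (1.5, 0.0, -0.4), 0.9, -0.8),
    (2.0, (0.2, 0.0, 2.5), 2.0, 0.3),
])
def test_nordsieck_closed_form_vs_quadrature(alpha, Q, kz, lam):
    k = np.array([0.0, 0.0, kz])
    num = _j0_numeric(alpha, np.array(Q), k, lam)
    cl = complex(j0_closed(alpha, Q[0], Q[1], Q[2], 0.0, 0.0, kz,
                           abs(kz), lam))
    assert abs(num - cl) / abs(num) < 1e-6


def test_j0_alpha_derivative_consistency():
    args = (0.9, 0.4, 0.2, 0.7, 0.1, 0.0, 1.1)
    kmag = np.hypot(args[4], args[6])
    h = 1e-6
    fd = (complex(j0_closed(args[0] + h, *args[1:], kmag, 0.5))
          - complex(j0_closed(args[0] - h, *args[1:], kmag, 0.5))) / (2 * h)
    an = complex(j0_dalpha(*args, kmag, 0.5))
    assert abs(an - fd) / abs(fd) < 1e-7


def test_k_family_derivatives_match_finite_differences():
    base = dict(beta=0.6, qx=0.5, qy=0.3, qz=0.8, px=0.2, py=0.0, pz=1.0,
                zeta=0.6, nu=0.7)
    v = 2.0
    pm = float(np.hypot(base["px"], base["pz"]))

    def K(**kw):
        a = {**base, **kw}
        return complex(k_family(a["beta"], a["qx"], a["qy"], a["qz"],
                                a["px"], a["py"], a["pz"], pm, a["zeta"],
                                a["nu"], v, outputs=("k",))["k"])

    res = k_family(base["beta"], base["qx"], base["qy"], base["qz"],
                   base["px"], base["py"], base["pz"], pm, base["zeta"],
                   base["nu"], v)
    h = 1e-5
    for name, var in [("dbeta", "beta"), ("gx", "qx"), ("gz", "qz")]:
        fd = (K(**{var: base[var] + h}) - K(**{var: base[var] - h})) \
            / (2 * h)
        assert abs(complex(res[name]) - fd) / abs(fd) < 1e-6


def test_k_family_numba_matches_numpy_path():
    import protrack.nordsieck as nd
    rng = np.random.default_rng(0)
    n = 64
    qx, qy = rng.uniform(-2, 2, n), rng.uniform(-2, 2, n)
    qz = rng.uniform(0.1, 2, n)
    px, py = rng.uniform(-1, 1, n), rng.uniform(-1, 1, n)
    pz = rng.uniform(-3, -0.5, n)
    pm = np.sqrt(px ** 2 + py ** 2 + pz ** 2)
    r1 = nd.k_family(0.0, -qx, -qy, -qz, px, py, pz, pm, 1.0 / pm,
                     0.5, 2.0)
    have = nd._HAVE_NUMBA
    nd._HAVE_NUMBA = False
    try:
        r2 = nd.k_family(0.0, -qx, -qy, -qz, px, py, pz, pm, 1.0 / pm,
                         0.5, 2.0)
    finally:
        nd._HAVE_NUMBA = have
    for w in r1:
        err = np.max(np.abs(r1[w] - r2[w])
                     / np.maximum(np.abs(r2[w]), 1e-300))
        assert err < 1e-12


def test_coulomb_norm_modulus():
    """|N(a)|^2 = 2 pi a / (1 - e^{-2 pi a})."""
    for a in (0.3, 1.2, -0.7):
        n2 = abs(complex(coulomb_norm(a))) ** 2
        ref = 2 * np.pi * a / (1.0 - np.exp(-2 * np.pi * a))
        assert n2 == pytest.approx(ref, rel=1e-12)
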