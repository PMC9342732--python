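"""Independent brute-force oracles used to validate the fast engines.

These deliberately avoid the implementation's numerical choices: adaptive
scipy quadrature (or dense uniform Simpson sums) instead of fixed
Gauss–Legendre panels, no series splitting, no caching, no interpolation.
They are slow and only ever run on small grids.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad, simpson
from scipy.special import j0


def oracle_finite_size(s: float, L: float, sigma: float) -> float:
    """Truncated-Gaussian-averaged triangular overlap, by adaptive quadrature."""
    if sigma == 0:
        return max(0.0, 1.0 - s / L)
    lo, hi = max(L - 12.0 * sigma, 1e-12), L + 12.0 * sigma
    pdf = lambda x: math.exp(-0.5 * ((x - L) / sigma) ** 2)
    Z, _ = quad(pdf, lo, hi)
    pts = [s] if lo < s < hi else None
    num, _ = quad(lambda x: max(0.0, 1.0 - s / x) * pdf(x), lo, hi,
                  limit=400, points=pts)
    return num / Z


def oracle_delta_u(r: float, n: int, eta_c: float, xi: float, q1: float) -> float:
    """δu_n(r) by adaptive quadrature directly in the x variable."""
    a = r / xi
    n = abs(int(n))

    def f(x):
        g = 1.0 / (math.sqrt(1.0 + x * x) + x)
        return (1.0 - j0(a * math.sqrt(2.0 * x)) * g ** (2 * n)) / (
            x * math.sqrt(1.0 + x * x)
        )

    v1, _ = quad(f, 0.0, 10.0, limit=2000)
    v2, _ = quad(f, 10.0, 2.0e4, limit=5000)
    # beyond x = 2e4 the Bessel/g^{2n} factor is negligible and the
    # remaining ∫ dx/(x√(1+x²)) has the closed form asinh(1/x)
    v3 = math.asinh(1.0 / 2.0e4)
    return 2.0 * eta_c / q1**2 * (v1 + v2 + v3)


def oracle_delta_u_table(r_vals, n_vals, eta_c, xi, q1, u_max=120.0, n_u=40001):
    """Dense uniform-Simpson evaluation of δu_n for a whole (n, r) table."""
    u = np.linspace(0.0, u_max, n_u)
    x = 0.5 * u * u
    g = 1.0 / (np.sqrt(1.0 + x * x) + x)
    with np.errstate(divide="ignore", invalid="ignore"):
        Ku = u / (x * np.sqrt(1.0 + x * x))
    Ku[0] = 0.0
    prefac = 2.0 * eta_c / q1**2
    tail = math.asinh(2.0 / u_max**2)
    out = np.zeros((len(n_vals), len(r_vals)))
    a = np.asarray(r_vals, dtype=float) / xi
    g2n = {n: g ** (2 * n) for n in n_vals}
    chunk = 100
    for lo in range(0, len(r_vals), chunk):
        J = j0(np.outer(a[lo : lo + chunk], u))
        for i, n in enumerate(n_vals):
            integ = (1.0 - J * g2n[n][None, :]) * Ku[None, :]
            out[i, lo : lo + chunk] = simpson(integ, x=u, axis=1) + tail
    return prefac * out


def oracle_structure_factor_grid(
    qz_list, qpar_list, stack, domains, hz_cut=1e-6, hr_cut=1e-6, n_r=2001
):
    """S(q_z, q_∥) on a grid, everything by brute force."""
    r_max = domains.Lr + 10.0 * domains.sigma_r
    while oracle_finite_size(r_max, domains.Lr, domains.sigma_r) < hr_cut:
        r_max *= 0.98
    r = np.linspace(0.0, r_max, n_r)
    Hr = np.array([oracle_finite_size(ri, domains.Lr, domains.sigma_r) for ri in r])
    n = 0
    while oracle_finite_size((n + 1) * stack.d, domains.Lz, domains.sigma_z) >= hz_cut:
        n += 1
    n_vals = list(range(n + 1))
    Hz = np.array(
        [oracle_finite_size(k * stack.d, domains.Lz, domains.sigma_z) for k in n_vals]
    )
    du = oracle_delta_u_table(r, n_vals, stack.eta_c, stack.xi, stack.q1)
    S = np.zeros((len(qz_list), len(qpar_list)))
    n_arr = np.asarray(n_vals)
    for iz, qz in enumerate(qz_list):
        W = np.exp(-0.5 * qz * qz * du)
        fac = np.where(n_arr == 0, 1.0, 2.0) * Hz * np.cos(qz * n_arr * stack.d)
        for ip, qp in enumerate(qpar_list):
            integ = r * Hr * j0(qp * r) * W
            S[iz, ip] = fac @ simpson(integ, x=r, axis=1)
    return S


def oracle_tilt_roughness(r: float, Kt_int: float, Qmin: float, Qmax: float) -> float:
    """Same-membrane tilt roughness by adaptive quadrature; Kt in kBT/Å²."""
    val, _ = quad(lambda Q: (1.0 - j0(Q * r)) / Q, Qmin, Qmax, limit=2000)
    return val / (math.pi * Kt_int)
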