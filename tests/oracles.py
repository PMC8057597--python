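"""Independent reference computations used by the tests.

Everything here is deliberately naive (nested loops, dense matrices,
generic optimisers, grid search) and shares no code path with the package
implementation it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def brute_periodic_convolve(weights: np.ndarray, anchor: tuple[int, int],
                            f: np.ndarray) -> np.ndarray:
    """Direct nested-loop periodic convolution of ``f`` with a stencil."""
    n = f.shape[0]
    k1, k2 = weights.shape
    out = np.zeros_like(f, dtype=float)
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for a in range(k1):
                for b in range(k2):
                    ii = (i - (a - anchor[0])) % n
                    jj = (j - (b - anchor[1])) % n
                    acc += weights[a, b] * f[ii, jj]
            out[i, j] = acc
    return out


def brute_ogs_value(v: np.ndarray, K: int) -> float:
    """Direct group enumeration of the overlapping-group-sparsity value."""
    m1, m2 = (K - 1) // 2, K // 2
    n0, n1 = v.shape
    total = 0.0
    for i in range(n0):
        for j in range(n1):
            s = 0.0
            for a in range(-m1, m2 + 1):
                for b in range(-m1, m2 + 1):
                    if 0 <= i + a < n0 and 0 <= j + b < n1:
                        s += v[i + a, j + b] ** 2
            total += np.sqrt(s)
    return total


def ogs_objective(v: np.ndarray, v0: np.ndarray, lam: float, K: int) -> float:
    return 0.5 * ((v - v0) ** 2).sum() + lam * brute_ogs_value(v, K)


def _ogs_obj_grad(x: np.ndarray, v0: np.ndarray, lam: float, K: int,
                  eps: float = 1e-12):
    """Objective and gradient of the (eps-smoothed) OGS prox problem."""
    v = x.reshape(v0.shape)
    m1, m2 = (K - 1) // 2, K // 2
    n0, n1 = v.shape
    # group norms via explicit shifts (zero extension)
    energy = np.zeros_like(v)
    for a in range(-m1, m2 + 1):
        for b in range(-m1, m2 + 1):
            src_i = slice(max(a, 0), min(n0 + a, n0))
            dst_i = slice(max(-a, 0), min(n0 - a, n0))
            src_j = slice(max(b, 0), min(n1 + b, n1))
            dst_j = slice(max(-b, 0), min(n1 - b, n1))
            energy[dst_i, dst_j] += v[src_i, src_j] ** 2
    norms = np.sqrt(energy + eps)
    val = 0.5 * ((v - v0) ** 2).sum() + lam * norms.sum()
    inv = 1.0 / norms
    weight = np.zeros_like(v)
    for a in range(-m2, m1 + 1):
        src_i = slice(max(a, 0), min(n0 + a, n0))
        dst_i = slice(max(-a, 0), min(n0 - a, n0))
        for b in range(-m2, m1 + 1):
            src_j = slice(max(b, 0), min(n1 + b, n1))
            dst_j = slice(max(-b, 0), min(n1 - b, n1))
            weight[dst_i, dst_j] += inv[src_i, src_j]
    grad = (v - v0) + lam * v * weight
    return val, grad.ravel()


def ogs_prox_lbfgs(v0: np.ndarray, lam: float, K: int) -> np.ndarray:
    """High-accuracy generic convex solve of the OGS prox problem."""
    res = optimize.minimize(
        _ogs_obj_grad, v0.ravel(), args=(v0, lam, K), jac=True,
        method="L-BFGS-B",
        options=dict(maxiter=20000, maxfun=100000, ftol=1e-18, gtol=1e-13))
    return res.x.reshape(v0.shape)


def lp_grid_minima(z0: float, lam: float, p: float,
                   lo: float = -3.0, hi: float = 3.0,
                   m: int = 10 ** 6):
    """Grid search of the scalar l_p prox objective.

    Returns (global minimum value, array of local-minimiser locations).
    """
    grid = np.linspace(lo, hi, m)
    obj = 0.5 * (grid - z0) ** 2 + lam * np.abs(grid) ** p
    interior = (obj[1:-1] <= obj[:-2]) & (obj[1:-1] <= obj[2:])
    return float(obj.min()), grid[1:-1][interior]


def poisson_pixel_minimize(g: float, c: float, lam: float, d1: float) -> float:
    """Numeric 1-D minimisation of the per-pixel Poisson splitting objective

        lam*(x - g*ln x) + (d1/2)*(x - c)^2   on x > 0  (x >= 0 for g = 0),

    refined by bisection on the derivative to ~1e-12.
    """
    hi = max(10.0 * (abs(c) + g + lam / d1), 10.0)

    def obj(x):
        fid = lam * (x - g * np.log(x)) if g > 0 else lam * x
        return fid + 0.5 * d1 * (x - c) ** 2

    res = optimize.minimize_scalar(obj, bounds=(1e-300, hi), method="bounded",
                                   options=dict(xatol=1e-14))
    x = res.x

    def deriv(x):
        fid = lam * (1.0 - g / x) if g > 0 else lam
        return fid + d1 * (x - c)

    a, b = x * 0.5, x * 2.0 + 1e-12
    if deriv(a) < 0 < deriv(b):
        for _ in range(200):
            mid = 0.5 * (a + b)
            if deriv(mid) < 0:
                a = mid
            else:
                b = mid
        x = 0.5 * (a + b)
    return float(x)


def dense_operator_matrices(n: int, blur_apply):
    """Explicit matrices of the blur, gradient and second-difference
    operators on an n x n grid, built column-by-column from the package's
    own stencil applications (``blur_apply`` maps image -> image)."""
    from poissontv.operators import forward_diff, second_order_diff

    H = np.zeros((n * n, n * n))
    G = np.zeros((2 * n * n, n * n))
    S = np.zeros((4 * n * n, n * n))
    for i in range(n * n):
        e = np.zeros(n * n)
        e[i] = 1.0
        img = e.reshape(n, n)
        H[:, i] = blur_apply(img).ravel()
        G[:, i] = forward_diff(img).ravel()
        S[:, i] = second_order_diff(img).ravel()
    return H, G, S
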