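"""Per-iteration subproblem solvers for the splitting algorithm.

Three proximal-type problems recur in the outer loop:

* the Poisson data update -- a separable problem whose per-pixel optimality
  condition is a quadratic with a unique nonnegative root;
* the overlapping-group-sparsity (OGS) prox -- solved by
  majorization-minimization with a quadratic majorizer of the group norm;
* the nonconvex ``l_p`` (0 < p < 1) prox -- solved by iteratively
  reweighted least squares (IRLS) on an epsilon-smoothed objective.

Also provided: the generalized Kullback-Leibler data fidelity and the full
objective of the hybrid model.
"""

from __future__ import annotations

import warnings

import numpy as np

from .operators import forward_diff, second_order_diff

DEFAULT_SAFEGUARD = 1e-12


# ---------------------------------------------------------------------------
# Poisson data update
# ---------------------------------------------------------------------------

def poisson_data_update(blur_est: np.ndarray, mult: np.ndarray, g: np.ndarray,
                        lam: float, delta1: float) -> np.ndarray:
    """Exact minimiser of the Poisson-fidelity splitting subproblem.

    Minimises ``lam*D_KL(x||g) + (delta1/2)*||x - Hf + w1/delta1||^2``
    pixel by pixel.  Setting ``t = Hf - (w1 + lam)/delta1``, the stationary
    condition is ``x^2 - t*x - lam*g/delta1 = 0`` and the unique
    nonnegative root is returned:

        x = (t + sqrt(t^2 + 4*lam*g/delta1)) / 2

    For ``g = 0`` this collapses to ``max(t, 0)``.
    """
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("observed counts g must be nonnegative")
    if lam <= 0 or delta1 <= 0:
        raise ValueError("lam and delta1 must be strictly positive")
    t = np.asarray(blur_est, dtype=float) - (np.asarray(mult, dtype=float) + lam) / delta1
    return 0.5 * (t + np.sqrt(t * t + 4.0 * lam * g / delta1))


# ---------------------------------------------------------------------------
# overlapping group sparsity
# ---------------------------------------------------------------------------

def _window_sum(a: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Sum of ``a`` over offsets ``lo..hi`` (inclusive) along both axes,
    with zero extension outside the grid."""
    out = np.zeros_like(a)
    n0, n1 = a.shape
    for di in range(lo, hi + 1):
        for dj in range(lo, hi + 1):
            src_i = slice(max(di, 0), min(n0 + di, n0))
            dst_i = slice(max(-di, 0), min(n0 - di, n0))
            src_j = slice(max(dj, 0), min(n1 + dj, n1))
            dst_j = slice(max(-dj, 0), min(n1 - dj, n1))
            out[dst_i, dst_j] += a[src_i, src_j]
    return out


def group_energy(u: np.ndarray, K: int) -> np.ndarray:
    """Squared Euclidean norm of the K x K group centred at each pixel.

    The group at (i, j) spans offsets ``-m1..m2`` with
    ``m1 = floor((K-1)/2)``, ``m2 = floor(K/2)``; entries outside the grid
    count as zero.
    """
    u = np.asarray(u, dtype=float)
    if K < 1:
        raise ValueError("group size K must be >= 1")
    if K > min(u.shape):
        raise ValueError(f"group size {K} exceeds grid side {min(u.shape)}")
    m1, m2 = (K - 1) // 2, K // 2
    return _window_sum(u * u, -m1, m2)


def group_weights(u: np.ndarray, K: int,
                  safeguard: float = DEFAULT_SAFEGUARD) -> np.ndarray:
    """Diagonal MM weights: sum over the K x K groups containing each pixel
    of the inverse (safeguarded) group norm.

        d[r,t] = sum_{i,j=-m1..m2} (safeguard + E[r-i, t-j])^(-1/2)

    where ``E`` is :func:`group_energy`.  The safeguard keeps the weight
    finite when a whole group vanishes, preserving the fixed point at 0.
    """
    if safeguard <= 0:
        raise ValueError("safeguard must be strictly positive")
    m1, m2 = (K - 1) // 2, K // 2
    inv_norm = 1.0 / np.sqrt(safeguard + group_energy(u, K))
    # offsets r-i for i in -m1..m2 form the reflected window -m2..m1
    return _window_sum(inv_norm, -m2, m1)


def ogs_prox(v0: np.ndarray, lam_mm: float, K: int, n_inner: int,
             safeguard: float = DEFAULT_SAFEGUARD) -> np.ndarray:
    """MM solver for ``min_v (1/2)||v - v0||^2 + lam_mm * phi_O(v)``.

    Each sweep replaces the group norms by their quadratic majorizer at the
    current iterate, giving the diagonal closed-form update

        v <- v0 / (1 + lam_mm * d(v))

    with ``d`` the :func:`group_weights` diagonal.  The update divides by a
    factor >= 1, so iterates shrink towards zero componentwise and the
    surrogate objective never increases.
    """
    if lam_mm <= 0:
        raise ValueError("lam_mm must be strictly positive")
    if n_inner < 1:
        raise ValueError("need at least one inner iteration")
    v0 = np.asarray(v0, dtype=float)
    v = v0.copy()
    for _ in range(n_inner):
        v = v0 / (1.0 + lam_mm * group_weights(v, K, safeguard))
    return v


def ogs_value(v: np.ndarray, K: int) -> float:
    """OGS functional: sum over all pixels of the Euclidean norm of the
    K x K group centred there (zero extension at borders).  For K=1 this is
    the plain l1 norm."""
    return float(np.sqrt(group_energy(v, K)).sum())


def ogs_majorizer(v: np.ndarray, u: np.ndarray, K: int,
                  safeguard: float = DEFAULT_SAFEGUARD) -> float:
    """Quadratic majorizer of :func:`ogs_value` tangent at ``u``:

        psi(v|u) = (1/2) * sum_g [ ||v_g||^2 / ||u_g|| + ||u_g|| ]  >=  phi_O(v)

    with equality at ``v = u`` (group norms safeguarded as in the MM step).
    """
    ev = group_energy(v, K)
    nu = np.sqrt(safeguard + group_energy(u, K))
    return float(0.5 * (ev / nu + nu).sum())


# ---------------------------------------------------------------------------
# nonconvex l_p prox (IRLS)
# ---------------------------------------------------------------------------

def lp_prox_irls(z0: np.ndarray, lam_irls: float, p: float,
                 epsilon: float = 1e-6, n_irls: int = 5) -> np.ndarray:
    """IRLS for ``min_z (1/2)||z - z0||^2 + lam_irls * sum_i |z_i|^p``.

    The nonconvex penalty is smoothed to ``(z^2 + epsilon)^(p/2)``; each
    sweep linearises it in ``z^2`` (a concave function of ``z^2``), giving
    the diagonal update

        omega = lam_irls * p * (z^2 + epsilon)^(p/2 - 1)
        z <- z0 / (1 + omega)

    starting from ``z = z0``.  This is a majorize-minimise scheme on the
    smoothed objective, so that objective is non-increasing; the limit is a
    stationary point (local minimiser in the basin of ``z0``).
    """
    if not (0.0 < p < 1.0):
        raise ValueError("p must lie strictly in (0, 1)")
    if lam_irls < 0:
        raise ValueError("lam_irls must be nonnegative")
    if epsilon <= 0:
        raise ValueError("epsilon must be strictly positive")
    z0 = np.asarray(z0, dtype=float)
    if lam_irls == 0:
        return z0.copy()
    z = z0.copy()
    for _ in range(n_irls):
        omega = lam_irls * p * (z * z + epsilon) ** (p / 2.0 - 1.0)
        z = z0 / (1.0 + omega)
    return z


def lp_smoothed_objective(z: np.ndarray, z0: np.ndarray, lam_irls: float,
                          p: float, epsilon: float = 1e-6) -> float:
    """The epsilon-smoothed IRLS objective (used for descent checks)."""
    z = np.asarray(z, dtype=float)
    z0 = np.asarray(z0, dtype=float)
    return float(0.5 * ((z - z0) ** 2).sum()
                 + lam_irls * ((z * z + epsilon) ** (p / 2.0)).sum())


# ---------------------------------------------------------------------------
# fidelity and full objective
# ---------------------------------------------------------------------------

def kl_divergence(blur_est: np.ndarray, g: np.ndarray) -> float:
    """Generalized Kullback-Leibler divergence of ``Hf`` from ``g`` (zero
    background):

        sum_ij [ (Hf) - g + g * ln(g / Hf) ]

    with the convention ``0*ln 0 = 0``.  Where ``g > 0`` but ``Hf = 0`` the
    divergence is infinite; +inf is returned with a warning.
    """
    hf = np.asarray(blur_est, dtype=float)
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ValueError("observed counts g must be nonnegative")
    pos = g > 0
    if np.any(hf[pos] <= 0):
        warnings.warn("Hf vanishes where g > 0: KL divergence is infinite",
                      RuntimeWarning, stacklevel=2)
        return float("inf")
    total = float(hf.sum() - g.sum())
    total += float((g[pos] * np.log(g[pos] / hf[pos])).sum())
    return total


def objective_value(f: np.ndarray, g: np.ndarray, blur_est: np.ndarray,
                    lam: float, eta: float, p: float, K: int) -> float:
    """Value of the hybrid model

        lam * D_KL(Hf || g) + phi_O(grad_h f) + phi_O(grad_v f)
            + eta * sum |grad2 f|^p

    where the l_p term runs over all 4 n^2 second-difference entries
    (the p-th power of the l_p quasi-norm is entrywise separable).
    ``blur_est`` is ``Hf`` precomputed by the caller.
    """
    gh, gv = forward_diff(f)
    lp_term = float((np.abs(second_order_diff(f)) ** p).sum())
    return (lam * kl_divergence(blur_est, g)
            + ogs_value(gh, K) + ogs_value(gv, K)
            + eta * lp_term)
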