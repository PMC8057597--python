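"""Periodic finite-difference operators, their adjoints, and transfer spectra.

All linear operators in the restoration model -- the blur ``H``, the
first-order gradient ``grad`` and the four second-order differences
``grad2`` -- are periodic convolutions on an ``n x n`` grid.  They are
therefore diagonalised by the 2-D DFT, which is what makes the inner
least-squares image update solvable in closed form.  This module provides
both the direct stencil application of each operator (used by the ADMM
residuals and the tests) and the precomputed frequency-domain spectra
(used by the FFT image update).

Index convention: arrays are ``(row, column)``; the horizontal difference
acts along columns, the vertical one along rows.  Boundary handling is
periodic everywhere; no other mode is offered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.fft import fft2


def _check_image(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.ndim != 2 or f.shape[0] != f.shape[1]:
        raise ValueError(f"expected a square 2-D image, got shape {f.shape}")
    if f.shape[0] < 2:
        raise ValueError("image side must be at least 2")
    return f


# ---------------------------------------------------------------------------
# first- and second-order differences (periodic)
# ---------------------------------------------------------------------------

def forward_diff(f: np.ndarray) -> np.ndarray:
    """Forward differences with wraparound.

    Returns an ``(2, n, n)`` array: channel 0 is the horizontal difference
    ``f[i, j+1] - f[i, j]`` (column ``n`` wrapping to column 1), channel 1
    the vertical difference on rows.
    """
    f = _check_image(f)
    h = np.roll(f, -1, axis=1) - f
    v = np.roll(f, -1, axis=0) - f
    return np.stack([h, v])


def backward_diff(f: np.ndarray) -> np.ndarray:
    """Backward differences with wraparound; channels as in :func:`forward_diff`."""
    f = _check_image(f)
    h = f - np.roll(f, 1, axis=1)
    v = f - np.roll(f, 1, axis=0)
    return np.stack([h, v])


def second_order_diff(f: np.ndarray) -> np.ndarray:
    """All four second-order periodic differences of ``f``.

    Returns a ``(4, n, n)`` array with channels
    ``(D1- D1+ f, D1+ D2+ f, D2+ D1+ f, D2- D2+ f)``: the two pure second
    differences flanked by the two (identical) mixed ones.  Both mixed
    channels are kept so the splitting variable for the second-order prior
    has the full 4n^2 entries.
    """
    f = _check_image(f)
    h = np.roll(f, -1, axis=1) - f          # D1+ f
    v = np.roll(f, -1, axis=0) - f          # D2+ f
    c11 = h - np.roll(h, 1, axis=1)         # D1- (D1+ f)
    c12 = np.roll(v, -1, axis=1) - v        # D1+ (D2+ f)
    c21 = np.roll(h, -1, axis=0) - h        # D2+ (D1+ f)
    c22 = v - np.roll(v, 1, axis=0)         # D2- (D2+ f)
    return np.stack([c11, c12, c21, c22])


def adjoint_grad(v: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`forward_diff` under the standard inner product.

    ``D1+^T u = roll(u, +1, cols) - u`` (the negated backward difference),
    and analogously for the vertical channel.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 3 or v.shape[0] != 2:
        raise ValueError(f"expected a (2, n, n) gradient field, got {v.shape}")
    h, vv = v[0], v[1]
    return (np.roll(h, 1, axis=1) - h) + (np.roll(vv, 1, axis=0) - vv)


def adjoint_second(v: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`second_order_diff` for a ``(4, n, n)`` field."""
    v = np.asarray(v, dtype=float)
    if v.ndim != 3 or v.shape[0] != 4:
        raise ValueError(f"expected a (4, n, n) curvature field, got {v.shape}")
    c11, c12, c21, c22 = v

    def t1p(u):  # (D1+)^T
        return np.roll(u, 1, axis=1) - u

    def t1m(u):  # (D1-)^T
        return u - np.roll(u, -1, axis=1)

    def t2p(u):  # (D2+)^T
        return np.roll(u, 1, axis=0) - u

    def t2m(u):  # (D2-)^T
        return u - np.roll(u, -1, axis=0)

    # adjoint of a composition reverses the factors
    return t1p(t1m(c11)) + t2p(t1p(c12)) + t1p(t2p(c21)) + t2p(t2m(c22))


# ---------------------------------------------------------------------------
# TV functionals
# ---------------------------------------------------------------------------

def tv_value(f: np.ndarray) -> float:
    """Isotropic total variation: sum of pixelwise Euclidean gradient norms."""
    g = forward_diff(f)
    return float(np.sqrt((g ** 2).sum(axis=0)).sum())


def htv_value(f: np.ndarray) -> float:
    """Second-order total variation: pixelwise Euclidean norms of all four
    second differences, summed over the grid."""
    c = second_order_diff(f)
    return float(np.sqrt((c ** 2).sum(axis=0)).sum())


# ---------------------------------------------------------------------------
# blur kernels and transfer spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlurKernel:
    """A small nonnegative PSF stencil normalised to unit sum.

    The full circulant blur matrix is never materialised; the kernel acts
    through periodic convolution with ``anchor`` marking the stencil entry
    that sits on the output pixel.
    """

    weights: np.ndarray
    anchor: tuple[int, int] | None = None

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2:
            raise ValueError("kernel weights must be a 2-D matrix")
        if np.any(w < 0):
            raise ValueError("kernel weights must be nonnegative")
        s = w.sum()
        if abs(s - 1.0) > 1e-12:
            raise ValueError(f"kernel must sum to 1 (got {s!r}); normalise on load")
        object.__setattr__(self, "weights", w)
        if self.anchor is None:
            object.__setattr__(
                self, "anchor", ((w.shape[0] - 1) // 2, (w.shape[1] - 1) // 2)
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape


def identity_kernel() -> BlurKernel:
    return BlurKernel(np.array([[1.0]]))


def kernel_to_transfer(kernel: BlurKernel, n: int) -> np.ndarray:
    """DFT spectrum of the periodic convolution operator of ``kernel``.

    The kernel is embedded in an ``n x n`` zero field with its anchor
    circularly shifted to the grid origin (the psf-to-otf convention), so
    that multiplying an image spectrum by the result and inverting
    reproduces unshifted periodic convolution.
    """
    k1, k2 = kernel.shape
    if k1 > n or k2 > n:
        raise ValueError(f"kernel {kernel.shape} larger than image side {n}")
    pad = np.zeros((n, n))
    pad[:k1, :k2] = kernel.weights
    pad = np.roll(pad, (-kernel.anchor[0], -kernel.anchor[1]), axis=(0, 1))
    return fft2(pad)


def apply_spectrum(spec: np.ndarray, f: np.ndarray) -> np.ndarray:
    """Apply a periodic convolution operator through its spectrum."""
    return np.real(np.fft.ifft2(spec * fft2(f)))


def apply_blur(kernel: BlurKernel, f: np.ndarray) -> np.ndarray:
    """Periodic blur of ``f`` by ``kernel`` (via FFT)."""
    f = _check_image(f)
    return apply_spectrum(kernel_to_transfer(kernel, f.shape[0]), f)


def _impulse_spectrum(op, n: int) -> np.ndarray:
    """Spectrum of a periodic-convolution operator from its impulse response."""
    delta = np.zeros((n, n))
    delta[0, 0] = 1.0
    return fft2(op(delta))


@dataclass
class TransferSet:
    """Precomputed spectra of all linear operators for one (kernel, n, delta).

    ``denom`` is the real symbol of the normal-equation operator
    ``d1 H^T H + d2 grad^T grad + d3 grad2^T grad2``; it is strictly
    positive everywhere when ``d1 > 0`` and the kernel sums to one, since
    the blur symbol equals 1 at the zero frequency where the difference
    symbols vanish.
    """

    h_spec: np.ndarray
    d_specs: np.ndarray        # (2, n, n) first-order spectra
    s_specs: np.ndarray        # (4, n, n) second-order spectra
    denom: np.ndarray
    delta: tuple[float, float, float]
    n: int = field(init=False)

    def __post_init__(self):
        self.n = self.h_spec.shape[0]

    @classmethod
    def build(cls, kernel: BlurKernel, n: int,
              delta: tuple[float, float, float]) -> "TransferSet":
        d1, d2, d3 = (float(d) for d in delta)
        if d1 <= 0:
            raise ValueError("delta1 must be strictly positive")
        h_spec = kernel_to_transfer(kernel, n)
        delta_img = np.zeros((n, n))
        delta_img[0, 0] = 1.0
        d_specs = np.stack([fft2(c) for c in forward_diff(delta_img)])
        s_specs = np.stack([fft2(c) for c in second_order_diff(delta_img)])
        denom = (
            d1 * np.abs(h_spec) ** 2
            + d2 * (np.abs(d_specs) ** 2).sum(axis=0)
            + d3 * (np.abs(s_specs) ** 2).sum(axis=0)
        )
        if np.any(denom <= 0):
            raise FloatingPointError(
                "normal-equation symbol has a nonpositive entry; "
                "is the kernel normalised and delta1 > 0?"
            )
        return cls(h_spec=h_spec, d_specs=d_specs, s_specs=s_specs,
                   denom=denom, delta=(d1, d2, d3))

    def blur(self, f: np.ndarray) -> np.ndarray:
        return apply_spectrum(self.h_spec, f)
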