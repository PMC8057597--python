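"""Forward degradation model and synthetic test images.

The observation model is photon-limited imaging: a clean image is scaled
so its peak equals a preset photon count ``max_f`` (lower peaks mean
relatively stronger noise), blurred by a point-spread function under
periodic boundaries, and each pixel of the blurred mean is replaced by a
Poisson draw.  The background level is zero throughout.

Named kernels cover the two standard artificial blurs (isotropic Gaussian
and linear motion); phantoms provide piecewise-constant and ramp-plus-
block scenes so that both staircase-artifact and over-smoothing behaviour
can be exercised without any external photographs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .operators import BlurKernel, apply_blur


@dataclass(frozen=True)
class DegradationSpec:
    """Degradation protocol: peak photon count, blur kernel, RNG seed."""

    max_f: float
    kernel: BlurKernel
    seed: int

    def __post_init__(self):
        if self.max_f <= 0:
            raise ValueError("max_f must be > 0")

    def describe(self) -> dict:
        return {
            "max_f": float(self.max_f),
            "kernel_shape": list(self.kernel.shape),
            "seed": int(self.seed),
            "rng": "numpy.random.Generator(PCG64)",
        }


def scale_to_peak(f: np.ndarray, max_f: float) -> np.ndarray:
    """Rescale ``f`` linearly so its maximum equals ``max_f`` exactly."""
    f = np.asarray(f, dtype=float)
    peak = f.max(initial=-np.inf)
    if not peak > 0:
        raise ValueError("image must have a positive entry to scale")
    if max_f <= 0:
        raise ValueError("max_f must be > 0")
    return f * (max_f / peak)


def degrade(f: np.ndarray, spec: DegradationSpec) -> np.ndarray:
    """Blur ``f`` periodically and draw per-pixel Poisson counts.

    ``f`` is used as-is (scale it first with :func:`scale_to_peak`); the
    blurred means stay real-valued, only the observation is integral.
    Reproducible for a fixed seed via ``numpy.random.default_rng``.
    """
    f = np.asarray(f, dtype=float)
    if np.any(f < 0):
        raise ValueError("clean image must be nonnegative")
    mean = apply_blur(spec.kernel, f)
    # tiny negative round-off from the FFT blur is clipped, true negatives abort
    if np.any(mean < -1e-9 * max(f.max(initial=0.0), 1.0)):
        raise FloatingPointError("blurred mean has a negative entry")
    mean = np.clip(mean, 0.0, None)
    rng = np.random.default_rng(spec.seed)
    return rng.poisson(mean).astype(float)


# ---------------------------------------------------------------------------
# named kernels
# ---------------------------------------------------------------------------

def make_gaussian_kernel(size: int = 9, sigma: float = 1.0) -> BlurKernel:
    """Isotropic Gaussian PSF sampled at integer offsets, unit-normalised.

    ``size`` must be odd so the centre is unambiguous; the default 9x9
    with sigma 1 is the standard out-of-focus surrogate.
    """
    if size < 1 or size % 2 == 0:
        raise ValueError("kernel size must be a positive odd integer")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    r = np.arange(size) - (size - 1) / 2.0
    gx = np.exp(-r ** 2 / (2.0 * sigma ** 2))
    k = np.outer(gx, gx)
    return BlurKernel(k / k.sum())


def make_motion_kernel(length: float = 5.0, angle_deg: float = 45.0,
                       samples_per_unit: int = 4096) -> BlurKernel:
    """Linear motion PSF: uniform density along a centred segment.

    The segment has the given length, oriented counterclockwise from the
    horizontal axis (y pointing up, i.e. decreasing row index).  Arc
    length is accumulated into the nearest pixel, so an axis-aligned
    length-5 blur gives five equal weights of 1/5 and a 45-degree blur is
    supported exactly on the main anti-diagonal.
    """
    if length < 1:
        raise ValueError("motion length must be >= 1")
    half = int(np.ceil((length - 1) / 2.0))
    size = 2 * half + 1
    if size == 1:
        return BlurKernel(np.array([[1.0]]))
    theta = np.deg2rad(angle_deg)
    m = max(int(round(samples_per_unit * length)), 1)
    t = (np.arange(m) + 0.5) / m * length - length / 2.0
    x = t * np.cos(theta)
    y = t * np.sin(theta)
    col = np.rint(x).astype(int) + half
    row = half - np.rint(y).astype(int)          # y up = row index down
    keep = (row >= 0) & (row < size) & (col >= 0) & (col < size)
    k = np.zeros((size, size))
    np.add.at(k, (row[keep], col[keep]), 1.0)
    return BlurKernel(k / k.sum())


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

def make_phantom(n: int, kind: str = "disks", seed: int = 0) -> np.ndarray:
    """Synthetic clean scene with values in [0, 1], deterministic per seed.

    ``disks``       -- piecewise-constant disks on a flat background; at
                       most five distinct intensity levels, stressing
                       staircase behaviour and edge preservation.
    ``ramp_blocks`` -- smooth linear ramps abutting flat blocks, stressing
                       over-smoothing of gradual transitions.
    """
    if n < 16:
        raise ValueError("phantom side must be at least 16")
    rng = np.random.default_rng(seed)
    ii, jj = np.mgrid[0:n, 0:n].astype(float)

    if kind == "disks":
        img = np.full((n, n), 0.2)
        levels = (0.5, 0.8, 1.0, 0.35)
        for lv in levels:
            cx = rng.uniform(0.15 * n, 0.85 * n)
            cy = rng.uniform(0.15 * n, 0.85 * n)
            r = rng.uniform(0.08 * n, 0.2 * n)
            img[(ii - cy) ** 2 + (jj - cx) ** 2 <= r ** 2] = lv
        return img

    if kind == "ramp_blocks":
        img = np.empty((n, n))
        half = n // 2
        # left half: horizontal ramp between seeded endpoints
        lo = rng.uniform(0.0, 0.2)
        hi = rng.uniform(0.8, 1.0)
        ramp = lo + (hi - lo) * jj[:, :half] / max(half - 1, 1)
        img[:, :half] = ramp
        # right half: vertical ramp on top, flat blocks below
        vramp = lo + (hi - lo) * ii[:half, half:] / max(half - 1, 1)
        img[:half, half:] = vramp
        img[half:, half:] = rng.uniform(0.3, 0.7)
        q = half + (n - half) // 2
        img[half:, q:] = rng.uniform(0.75, 1.0)
        return img

    raise ValueError(f"unknown phantom kind {kind!r}")
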