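"""File interfaces: grayscale image read/write and plain-text kernel files.

Images are held as float arrays internally; files are 8- or 16-bit
grayscale PNG/TIFF, or whitespace-separated text matrices.  Writing
rescales to the chosen bit depth and logs the scaling so the mapping back
to photon counts is recoverable.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np

from .operators import BlurKernel

log = logging.getLogger("poissontv")

_TEXT_SUFFIXES = {".txt", ".dat", ".csv", ".tsv"}


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image (PNG/TIFF via imageio, or a text matrix)."""
    path = Path(path)
    if path.suffix.lower() in _TEXT_SUFFIXES:
        return np.atleast_2d(np.loadtxt(path, dtype=float))
    import imageio.v3 as iio

    arr = np.asarray(iio.imread(path)).astype(float)
    if arr.ndim == 3:                      # collapse any color/alpha planes
        arr = arr[..., :3].mean(axis=-1)
    return arr


def write_image(path: str | Path, img: np.ndarray, bit_depth: int = 16) -> None:
    """Write ``img`` as grayscale PNG/TIFF (rescaled) or as a text matrix."""
    path = Path(path)
    img = np.asarray(img, dtype=float)
    if path.suffix.lower() in _TEXT_SUFFIXES:
        np.savetxt(path, img)
        return
    import imageio.v3 as iio

    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    lo, hi = float(img.min()), float(img.max())
    span = hi - lo if hi > lo else 1.0
    top = (1 << bit_depth) - 1
    scaled = np.round((img - lo) / span * top)
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    log.info("writing %s: [%g, %g] -> [0, %d]", path, lo, hi, top)
    iio.imwrite(path, scaled.astype(dtype))


def load_kernel(path: str | Path) -> BlurKernel:
    """Load a PSF from a whitespace-separated text matrix.

    The kernel is normalised to unit sum on load; a warning is emitted if
    the raw sum deviates from 1 by more than 1e-6.
    """
    w = np.atleast_2d(np.loadtxt(Path(path), dtype=float))
    if np.any(w < 0):
        raise ValueError(f"kernel file {path} has negative weights")
    s = w.sum()
    if s <= 0:
        raise ValueError(f"kernel file {path} sums to {s}; cannot normalise")
    if abs(s - 1.0) > 1e-6:
        warnings.warn(f"kernel file {path} sums to {s:g}; renormalising to 1",
                      UserWarning, stacklevel=2)
    return BlurKernel(w / s)
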