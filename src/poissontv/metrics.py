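"""Image-quality metrics on the photon-count scale.

Both metrics are parameterised by the peak intensity ``max_f`` of the
clean image rather than a fixed 255 dynamic range, because test images are
scaled to a preset photon peak before degradation.

The SSIM here is the *global* single-statistics form: one mean, variance
and covariance over the whole image, stabilised by C1 = max_f^2 / 1e4 and
C2 = 9 * max_f^2 / 1e4.  This is deliberately not the sliding-window SSIM
of Wang et al. as implemented in scikit-image; the windowed variant is
available behind ``windowed=True`` for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


@dataclass(frozen=True)
class QualityReport:
    psnr: float
    ssim: float
    max_f: float

    def to_dict(self) -> dict:
        return asdict(self)


def _pair(f, fhat):
    f = np.asarray(f, dtype=float)
    fhat = np.asarray(fhat, dtype=float)
    if f.shape != fhat.shape:
        raise ValueError(f"shape mismatch: {f.shape} vs {fhat.shape}")
    return f, fhat


def psnr(f: np.ndarray, fhat: np.ndarray, max_f: float) -> float:
    """Peak signal-to-noise ratio, 20*log10(n*max_f / ||f - fhat||_2).

    Because the Frobenius norm runs over n^2 pixels this equals
    20*log10(max_f / RMSE).  Identical images give +inf.
    """
    f, fhat = _pair(f, fhat)
    if max_f <= 0:
        raise ValueError("max_f must be > 0")
    err = np.linalg.norm(f - fhat)
    if err == 0:
        return float("inf")
    return float(20.0 * np.log10(f.shape[0] * max_f / err))


def ssim(f: np.ndarray, fhat: np.ndarray, max_f: float,
         windowed: bool = False) -> float:
    """Structural similarity with whole-image statistics.

        (2 mu_f mu_g + C1)(2 cov + C2)
        ------------------------------ ,  C1 = max_f^2/1e4, C2 = 9 max_f^2/1e4
        (mu_f^2 + mu_g^2 + C1)(var_f + var_g + C2)

    Moments use the population (1/n^2) convention.  The value is symmetric
    in its arguments, equals 1 iff the images coincide, and may be negative
    for anti-correlated inputs (not clamped).  ``windowed=True`` instead
    defers to scikit-image's sliding-window SSIM (requires scikit-image).
    """
    f, fhat = _pair(f, fhat)
    if windowed:
        from skimage.metrics import structural_similarity
        return float(structural_similarity(f, fhat, data_range=max_f))
    c1 = max_f ** 2 / 1e4
    c2 = 9.0 * max_f ** 2 / 1e4
    mu_f, mu_g = f.mean(), fhat.mean()
    var_f, var_g = f.var(), fhat.var()
    cov = ((f - mu_f) * (fhat - mu_g)).mean()
    return float((2 * mu_f * mu_g + c1) * (2 * cov + c2)
                 / ((mu_f ** 2 + mu_g ** 2 + c1) * (var_f + var_g + c2)))


def quality_report(f: np.ndarray, fhat: np.ndarray, max_f: float) -> QualityReport:
    return QualityReport(psnr=psnr(f, fhat, max_f),
                         ssim=ssim(f, fhat, max_f),
                         max_f=float(max_f))
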