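# poissontv

Restoration of single-channel images corrupted by blur and Poisson noise —
the regime of photon-counting detectors (fluorescence microscopy,
low-dose radiography, astronomy), where noise is signal-dependent and a
least-squares data term is the wrong likelihood.

## Model

Given counts `g ~ Poisson(Hf)` with `H` a known point-spread function
acting by periodic convolution, the estimate minimises

    λ·D_KL(Hf ‖ g) + φ_O(∇₁f) + φ_O(∇₂f) + η·‖∇²f‖ₚᵖ ,   0 < p < 1

where `D_KL` is the generalized Kullback–Leibler divergence (the Poisson
negative log-likelihood up to constants), `φ_O` sums the Euclidean norms
of all overlapping K×K windows of each first-difference field (group
sparsity: gradients cluster at true edges, so isolated noise gradients
are suppressed without the staircase artifacts of plain TV), and the
nonconvex entrywise `ℓ_p` quasi-norm of the four second-difference fields
flattens spurious curvature while sparing genuine edges.

The objective is minimised by a multi-block ADMM: a closed-form per-pixel
Poisson data update, a majorization–minimization solver for the
overlapping-group-sparse prox, an IRLS solver for the `ℓ_p` prox, an
FFT-diagonalised exact solve of the image normal equation, and dual
ascent. See `docs/methods.md` for the full derivation-level description,
parameter table and numerical choices.

## Worked example

```python
import numpy as np
from poissontv import (
    DegradationSpec, default_params, degrade, identity_kernel,
    make_phantom, psnr, restore, scale_to_peak, ssim,
)

# a piecewise-constant phantom scaled to a peak of 100 photons,
# observed through Poisson noise (no blur)
clean = scale_to_peak(make_phantom(64, "disks", seed=0), 100.0)
noisy = degrade(clean, DegradationSpec(max_f=100.0,
                                       kernel=identity_kernel(), seed=0))

params = default_params("denoise", max_f=100.0)
result = restore(noisy, identity_kernel(), params)

print(f"iterations : {result.iterations} (converged={result.converged})")
print(f"PSNR  noisy -> restored : {psnr(clean, noisy, 100.0):.2f} dB -> "
      f"{psnr(clean, result.image, 100.0):.2f} dB")
print(f"SSIM  noisy -> restored : {ssim(clean, noisy, 100.0):.4f} -> "
      f"{ssim(clean, result.image, 100.0):.4f}")
```

prints

```
iterations : 50 (converged=False)
PSNR  noisy -> restored : 24.63 dB -> 29.43 dB
SSIM  noisy -> restored : 0.9754 -> 0.9915
```

A gain of ~4.8 dB PSNR means the squared error dropped to about a third;
SSIM moving toward 1 means the restored structure (means, contrasts,
correlation with the truth) is nearly that of the clean scene.
`converged=False` here simply records that the denoising run used its
full 50-sweep budget rather than settling below the relative-change
tolerance early — the deblurring presets typically converge around sweep
35–41.

The same pipeline is available from the shell:

```
poissontv phantom --n 64 --seed 0 --output-dir run
poissontv degrade --input run/phantom_disks.txt --kernel gaussian \
    --max-f 100 --seed 0 --output-dir run
poissontv restore --input run/degraded.txt --kernel gaussian \
    --max-f 100 --truth run/phantom_disks.txt --output-dir run
poissontv evaluate --truth run/phantom_disks.txt \
    --estimate run/restored.txt --max-f 100
```

Each command writes a resolved-config JSON snapshot next to its outputs,
so any artifact can be regenerated exactly.

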