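# waveshrink

Wavelet-domain shrinkage de-noising for 2-D grayscale images — in
particular MRI brain slices corrupted by additive white Gaussian noise —
with the full family of adaptive and generalized-Gaussian (AGGD) threshold
functions, MAD noise estimation, automatic threshold selection, and
PSNR/MSE evaluation.

## The problem and the method

An observed image `f = u + n` carries i.i.d. zero-mean Gaussian noise `n`
on top of the true image `u`. In an orthogonal wavelet basis the noise
spreads evenly over all coefficients while the image concentrates in a few
large ones, so de-noising reduces to: decompose (2-D DWT, default Db4 at
one level), apply an elementwise *shrinkage function* η to the detail
coefficients, and reconstruct.

The package implements eight shrinkage families:

| family | rule | threshold t |
|---|---|---|
| `hard` | keep x if \|x\| > t, else 0 | σ̂·√(2 ln n) (universal) |
| `soft` | sign(x)·max(\|x\|−t, 0) | universal |
| `zhang_soft` | smooth soft surrogate, x + (√((x−t)²+λ) − √((x+t)²+λ))/2 | universal |
| `zhang_hard` | sigmoid-gate surrogate of hard, shape μ | universal |
| `adaptive_hard` | keep \|x\| > σₙ; *tune* the rest via the AGGD core | t = σₙ |
| `adaptive_soft` | shrink \|x\| > σₙ by t − (s(t)−s(0)); tune the rest | t = σₙ |
| `aggd` | keep \|x\| > t; tune inside | t = t\* |
| `improved_aggd` | sigmoid-gated tails (1/(1+e^(−x+t)))·x + t/2; tune inside | t = t\* |

The AGGD core is `s(x) = σₙ·(exp(x²/2σₙ²) − ½)`; tuning maps x in [−t, t]
to `sign(x)·(s(|x|) − s(0))`, attenuating noise-dominated coefficients
without zeroing them. The intersection threshold t\* is the unique positive
solution of `s(t) − s(0) = t` (t\* = 1.285889·σₙ), the value at which the
AGGD rules are continuous. The noise level is estimated from the finest
diagonal subband as `σ̂ = median(|HH1|)/0.6745`. Quality is reported as
`MSE = mean((d − d̂)²)` and `PSNR = 10·log10(255²/MSE)` dB on the [0, 255]
intensity scale.

Because no learning or metaheuristic search is involved, every threshold is
available in closed form (or from a one-dimensional root), which is the
point of the adaptive/AGGD family: de-noising at a fixed, tiny cost.

## Worked example

```python
import numpy as np
from waveshrink import (PhantomSpec, NoiseModel, make_phantom, add_awgn,
                        WaveletDenoiser, psnr)

clean = make_phantom(PhantomSpec())                      # 256x256 brain-like phantom
noisy = add_awgn(clean, NoiseModel(variance=0.01, seed=42))
print(f"noisy PSNR: {psnr(clean, noisy):.2f} dB")

res = WaveletDenoiser(noisy, family="adaptive_soft").fit(reference=clean)
print(res.summary())
```

prints

```
noisy PSNR: 19.98 dB
Wavelet shrinkage de-noising
==================================
family                adaptive_soft
wavelet               db4
levels                1
sigma_hat             25.1763
threshold             25.1763
MSE vs reference      377.32
PSNR vs reference     22.36 dB
```

Unit-scale noise variance 0.01 means noise sd 25.5 on [0, 255], an analytic
noisy baseline of 10·log10(1/0.01) = 20 dB; the MAD estimate σ̂ = 25.18
recovers that level from the noisy image alone, the adaptive rule sets
t = σ̂, and de-noising gains ≈ 2.4 dB. `res.image` holds the de-noised
pixels, `res.plot(noisy=noisy, reference=clean)` shows the three panels,
and `run_benchmark(clean, variances, families, seeds)` produces the
PSNR/MSE comparison table across noise levels.

## Command line

```sh
waveshrink simulate  --out sim/ --n-phantoms 2 --variances 0.01,0.03,0.05 --seeds 3
waveshrink denoise   --in noisy.png --out clean.png --method improved-aggd \
                     --ref truth.png --report report.json
waveshrink evaluate  --ref truth.png --test clean.png --out metrics.json
waveshrink benchmark --variances 0.01,0.03,0.05 --methods soft,adaptive-soft \
                     --seeds 20 --out bench.csv
```

PNG, TIFF and single-slice NIfTI (`--slice N`) inputs are supported;
per-stage σ̂/threshold lines go to stderr (`--quiet` suppresses).

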