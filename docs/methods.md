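# Methods

## Signal model and pipeline

The observed image is `f(i,j) = u(i,j) + n(i,j)` with `n` i.i.d. zero-mean
Gaussian, independent of `u`, on the [0, 255] intensity scale. All
processing happens in an orthogonal 2-D discrete wavelet basis
(PyWavelets `wavedec2`/`waverec2`), Daubechies-4 with one decomposition
level by default, symmetric (half-sample) boundary extension. The pipeline
is strictly: decompose → estimate σ̂ from HH1 → select the threshold for
the requested family → shrink every detail subband (LH, HL, HH at every
level) with the same spec → reconstruct → clip to [0, 255]. The
approximation (LL) band is never touched: at one decomposition level it
retains a quarter of the noise energy, which bounds the achievable gain of
any shrinkage rule. Metrics are computed on the clipped output — the
storable image — while the pipeline itself always sees the unclipped noisy
input.

## Shrinkage families

The middle ("tune") branch of the adaptive/AGGD rules is implemented as
`sign(x)·(s(|x|) − s(0))` with `s(x) = σₙ(e^{x²/2σₙ²} − ½)`. The even form
`s(x) − s(0)` would map negative coefficients to positive values and
cannot be continuous with the identity-like outer branches at both ±t; the
odd-symmetric form is the unique continuous completion and is what the
published curves of these functions show. The adaptive-soft outer branch
is read as `x − (t − (s(t) − s(0)))`, again the unique parenthesisation
continuous at |x| = t.

The improved-AGGD outer branch is implemented exactly as published:
`(1/(1+e^{−x+t}))·x + t/2` for x > t (mirrored for x < −t). Note its
asymptote is `x + t/2`, not the identity: every large coefficient is
inflated by t\*/2 ≈ 0.643·σₙ. On the [0, 255] coefficient scale the
dimensionless sigmoid saturates within a few intensity units, so the
offset applies almost everywhere outside the band. This is a property of
the published formula, deliberately preserved; see *Limitations*.

All sigmoids are evaluated through `scipy.special.expit` (log-sum-exp
safe); no positive argument is ever exponentiated directly, so
`zhang_hard` and `improved_aggd` are exact for arbitrarily large
coefficients. The middle branch is evaluated on coefficients clipped to
[−t, t] before `expm1`, so the dead branch of the vectorised `where`
cannot overflow.

## Thresholds

* hard/soft/zhang: VisuShrink universal threshold `t = σ̂·√(2 ln n)` with
  `n` the total pixel count of the input image (the alternative — per
  subband — is smaller and less smoothing; image scope is the conventional
  VisuShrink reading).
* adaptive rules: `t = σₙ` by definition.
* AGGD rules: the intersection `s(t) − s(0) = t`. The equation is
  scale-equivariant, so it is solved once in dimensionless form
  (`e^{u²/2} − 1 = u`, bisection on [1, 3] to 1e−13; the positive root is
  u\* = 1.285889…) and rescaled by σₙ. This keeps the defining residual
  below 1e−9·σₙ across at least five orders of magnitude of σₙ, which a
  fixed absolute tolerance in t-units would not.
* σ̂ is estimated once from the finest HH band and reused for all detail
  subbands; no per-level re-estimation. A zero σ̂ (noise-free input)
  degenerates every family to the identity — allowed, not an error.

Default shape parameters for the Zhang surrogates are λ = 0.1 and
μ = 0.05 (both CLI-exposed): small enough to stay visually close to the
soft/hard rules they smooth, large enough to keep their gradients bounded.

## Synthetic phantoms and noise

`make_phantom` draws a deterministic, seed-reproducible stand-in for an
axial MRI slice: nested ellipses (outermost bright, skull-like; interior
tissue plateaus; darker inner structures) over a dark background, plus an
optional low-frequency cosine texture confined to the head region.
Defaults: 256×256, 4 ellipses, texture amplitude 6 intensity units. The
generator algorithm (ellipse geometry, intensity cycle, draw order) is
fixed and documented in the module docstring.

Noise variance is specified on the unit intensity scale: variance v adds
Gaussian noise of sd 255·√v on [0, 255], so v = 0.01/0.03/0.05 give
analytic noisy baselines of exactly 10·log10(1/v) = 20.00/15.23/13.01 dB —
a closed-form consistency check tying the noise generator to the metrics.
Noisy images are intentionally not clipped.

What the phantom does *not* emulate: Rician/scanner noise statistics,
partial-volume effects, bias fields, and — importantly — the dense
high-frequency anatomical texture of real MRI. Its detail subbands are
nearly signal-free, which favours aggressive (universal-threshold)
smoothing; conclusions about the *ranking* of shrinkage families on real
MRI data should not be drawn from phantom benchmarks alone.

## Problem sizes

Benchmarks and the reproduction script use the default 256×256 phantom
with 20 noise seeds per variance at v ∈ {0.01, 0.03, 0.05}; noise-recovery
checks use 50 replicates of 128×128 pure-noise images at unit-scale sd
∈ {0.05, 0.1, 0.2}. These sizes give sub-0.1 dB Monte-Carlo error on mean
PSNR while keeping a full run in seconds.

## Numerical choices and degenerate inputs

* Median of an even-length array is the mean of the two central order
  statistics (numpy convention).
* Reconstruction output is cropped to the original shape (odd dimensions
  overshoot by one under the decimated transform).
* Colour inputs collapse to Rec. 709 luminance; 16-bit integers rescale by
  255/65535; NIfTI slices are min-max rescaled to [0, 255].
* 16-bit fixture PNGs store an affine (offset, scale) in the manifest so
  negative/overflow noise excursions survive the round trip to within half
  a quantisation step.

## Known limitations

* **MAD bias under symmetric padding.** With half-sample symmetric
  extension the HH1 band is redundant (67×67 from a 128×128 image) and its
  boundary coefficients are low-variance, biasing the MAD estimate by
  ≈ −6.5% at that size. This is within the ±10% recovery band the tests
  enforce, and symmetric padding is kept for its better edge behaviour; a
  periodized transform would remove the bias at the cost of wrap-around
  artefacts.
* **Improved-AGGD tail offset.** Because the published outer branch tends
  to x + t/2, the improved-AGGD rule incurs an unavoidable squared bias of
  (t\*/2)² ≈ (0.643·σₙ)² on every kept coefficient, so in mean-squared
  error it is dominated by the adaptive-hard rule on *any* input on this
  intensity scale. On the synthetic phantoms the measured mean-PSNR
  ranking at all three noise levels is
  hard ≈ soft > adaptive_soft > aggd ≈ adaptive_hard > improved_aggd —
  every family still improves on the unclipped noisy baseline, but the
  adaptive/AGGD families do not out-rank universal-threshold smoothing on
  smooth phantoms, and improved-AGGD cannot out-rank adaptive-soft
  anywhere. The corresponding acceptance test states the originally
  claimed ranking and is expected to fail; it is kept as an honest record
  rather than weakened.
* One-level decimated transform only as the default protocol; no cycle
  spinning or undecimated variants, no SURE/Bayes threshold selection,
  no per-subband adaptive parameters.
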