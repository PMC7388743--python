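"""Synthetic brain-like phantoms and AWGN corruption.

The phantom stands in for a T1-like axial MRI slice: a bright skull-like
outer ellipse, nested interior tissue ellipses with distinct mean
intensities (grey/white-matter-like plateaus and a dark ventricle-like
core), and an optional smooth low-frequency cosine texture.  It deliberately
contains both large smooth regions and sharp edges, the two regimes that
stress a shrinkage rule in opposite directions.

Noise is additive white Gaussian with zero mean on the *unit* intensity
scale: variance v corresponds to standard deviation 255 * sqrt(v) on the
[0, 255] working scale (v = 0.01 -> sd 25.5).  Noisy images are NOT clipped:
the pipeline must see the raw noisy signal; clipping is an output-stage
concern.

Generator algorithm (fixed, for cross-platform reproducibility): ellipse
k = 0..n-1 has semi-axes (0.92, 0.78) * 0.82**k, centre jittered for k >= 2
by uniform draws in [-0.08, 0.08], and intensity cycling through
(230, 120, 60, 170, 95, 205); the texture is a sum of three cosine plane
waves with integer frequencies drawn from {1, 2, 3} and uniform phases,
scaled to peak amplitude ``texture_amp`` and applied inside the outermost
ellipse only.  All randomness comes from ``numpy.random.default_rng(seed)``
with draws in a fixed order.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["PhantomSpec", "NoiseModel", "make_phantom", "add_awgn",
           "make_test_suite"]

_INTENSITIES = (230.0, 120.0, 60.0, 170.0, 95.0, 205.0)
_BACKGROUND = 20.0


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic brain-like phantom."""

    size: Tuple[int, int] = (256, 256)
    n_ellipses: int = 4
    texture_amp: float = 6.0
    seed: int = 0

    def __post_init__(self):
        if min(self.size) < 32:
            raise ValueError(f"phantom size must be >= 32x32, got {self.size}")
        if self.n_ellipses < 1:
            raise ValueError("n_ellipses must be >= 1")
        if self.texture_amp < 0:
            raise ValueError("texture_amp must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Zero-mean AWGN with unit-scale variance v (sd = 255 * sqrt(v))."""

    variance: float
    seed: int = 0
    mean: float = 0.0

    def __post_init__(self):
        if not (0.0 < self.variance < 1.0):
            raise ValueError(
                f"variance must lie in (0, 1) on the unit scale, "
                f"got {self.variance!r}"
            )
        if self.mean != 0.0:
            raise ValueError("the noise model is zero-mean by definition")

    @property
    def sigma255(self) -> float:
        """Noise standard deviation on the [0, 255] working scale."""
        return 255.0 * float(np.sqrt(self.variance))


def make_phantom(spec: PhantomSpec = PhantomSpec()) -> np.ndarray:
    """Deterministic brain-like phantom on [0, 255] (float64)."""
    rows, cols = spec.size
    rng = np.random.default_rng(spec.seed)
    yy = np.linspace(-1.0, 1.0, rows)[:, None]
    xx = np.linspace(-1.0, 1.0, cols)[None, :]

    img = np.full((rows, cols), _BACKGROUND)
    outer_mask = None
    for k in range(spec.n_ellipses):
        a = 0.92 * 0.82**k
        b = 0.78 * 0.82**k
        if k >= 2:
            cy, cx = rng.uniform(-0.08, 0.08, size=2)
        else:
            cy = cx = 0.0
        mask = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
        img[mask] = _INTENSITIES[k % len(_INTENSITIES)]
        if k == 0:
            outer_mask = mask

    if spec.texture_amp > 0:
        tex = np.zeros((rows, cols))
        for _ in range(3):
            fy, fx = rng.integers(1, 4, size=2)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            tex += np.cos(np.pi * (fy * yy + fx * xx) + phase)
        tex *= spec.texture_amp / 3.0
        img = np.where(outer_mask, img + tex, img)

    return np.clip(img, 0.0, 255.0)


def add_awgn(img, noise: NoiseModel) -> np.ndarray:
    """Add i.i.d. zero-mean Gaussian noise (sd = 255 * sqrt(v)); unclipped."""
    arr = np.asarray(img, dtype=float)
    rng = np.random.default_rng(noise.seed)
    return arr + rng.normal(0.0, noise.sigma255, size=arr.shape)


def _write_png16(path: str, img: np.ndarray) -> Tuple[float, float]:
    """Store a float image as 16-bit PNG with a recorded affine (offset, scale).

    value_uint16 = round((img - offset) / scale); noisy images can excurse
    outside [0, 255], so the affine keeps those excursions through the
    round trip (error <= scale / 2 < 4e-3 intensity units).
    """
    import imageio.v3 as iio

    lo = float(img.min())
    hi = float(img.max())
    scale = (hi - lo) / 65535.0 if hi > lo else 1.0
    quant = np.round((img - lo) / scale).astype(np.uint16)
    iio.imwrite(path, quant)
    return lo, scale


def read_png16(path: str, offset: float, scale: float) -> np.ndarray:
    """Invert :func:`_write_png16` using the manifest's affine."""
    import imageio.v3 as iio

    return iio.imread(path).astype(float) * scale + offset


def make_test_suite(out_dir: str,
                    variances: Sequence[float],
                    seeds: Sequence[int],
                    n_phantoms: int = 1,
                    size: Tuple[int, int] = (256, 256)) -> pd.DataFrame:
    """Write clean phantoms and AWGN-corrupted variants plus a CSV manifest.

    One phantom per index 0..n_phantoms-1 (phantom seed = index), each
    corrupted at every (variance, seed) pair.  Returns the manifest, which
    is also written to ``out_dir/manifest.csv`` with columns
    (file, role, phantom, variance, seed, offset, scale).
    """
    os.makedirs(out_dir, exist_ok=True)
    records: List[dict] = []
    for p in range(n_phantoms):
        clean = make_phantom(PhantomSpec(size=size, seed=p))
        fname = f"phantom{p:02d}_clean.png"
        off, sc = _write_png16(os.path.join(out_dir, fname), clean)
        records.append(dict(file=fname, role="clean", phantom=p,
                            variance=0.0, seed=-1, offset=off, scale=sc))
        for v in variances:
            for s in seeds:
                noisy = add_awgn(clean, NoiseModel(variance=v, seed=s))
                fname = f"phantom{p:02d}_v{v:g}_s{s}.png"
                off, sc = _write_png16(os.path.join(out_dir, fname), noisy)
                records.append(dict(file=fname, role="noisy", phantom=p,
                                    variance=v, seed=s, offset=off, scale=sc))
    manifest = pd.DataFrame.from_records(records)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
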