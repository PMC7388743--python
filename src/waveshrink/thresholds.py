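"""Noise-level estimation and threshold selection.

The noise standard deviation is estimated once, from the finest diagonal
(HH1) detail subband, with the robust median (MAD) estimator

    sigma_hat = Median(|G(i, j)|) / 0.6745,

where 0.6745 is the upper quartile of the standard normal.  Threshold
selection then depends on the shrinkage family:

* hard / soft / zhang_* use the VisuShrink universal threshold
  t = sigma * sqrt(2 ln n) with n the total pixel count of the image;
* the adaptive families use t = sigma_hat directly;
* the AGGD families use the intersection threshold t* — the unique positive
  solution of s(t) - s(0) = t, i.e. sigma_n * (exp(t^2 / (2 sigma_n^2)) - 1) = t,
  which is where the shifted generalized-Gaussian core meets the identity
  line and hence the unique t making the AGGD rules continuous.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
from scipy.optimize import bisect

from .shrinkage import FAMILIES, ShrinkageSpec

__all__ = [
    "NoiseEstimate",
    "estimate_sigma",
    "universal_threshold",
    "solve_aggd_threshold",
    "select_threshold",
    "DEFAULT_LAM",
    "DEFAULT_MU",
]

#: Normal upper-quartile constant of the MAD-to-sigma conversion.
MAD_SCALE = 0.6745

#: Default shape parameters for the Zhang smooth threshold functions.
DEFAULT_LAM = 0.1
DEFAULT_MU = 0.05


@dataclass(frozen=True)
class NoiseEstimate:
    """MAD-based noise-level estimate from a detail subband."""

    sigma_hat: float
    source_subband: str
    n_coeffs: int

    def __post_init__(self):
        if self.sigma_hat < 0:
            raise ValueError("sigma_hat must be >= 0")
        if self.n_coeffs < 1:
            raise ValueError("n_coeffs must be >= 1")


def estimate_sigma(hh_subband, source_subband: str = "HH1") -> NoiseEstimate:
    """Robust median estimator sigma_hat = median(|coeffs|) / 0.6745.

    Invariant to sign flips and permutations of the subband.  The median of
    an even-length array is the mean of the two central order statistics
    (numpy's convention).
    """
    arr = np.asarray(hh_subband, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot estimate noise from an empty subband")
    if not np.all(np.isfinite(arr)):
        raise ValueError("subband coefficients must be finite")
    sigma = float(np.median(np.abs(arr))) / MAD_SCALE
    return NoiseEstimate(sigma_hat=sigma, source_subband=source_subband,
                         n_coeffs=int(arr.size))


def universal_threshold(sigma: float, n: int) -> float:
    """VisuShrink universal threshold t = sigma * sqrt(2 ln n)."""
    if sigma < 0 or not math.isfinite(sigma):
        raise ValueError("sigma must be finite and >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(sigma) * math.sqrt(2.0 * math.log(n))


@lru_cache(maxsize=1)
def _aggd_unit_ratio() -> float:
    # Dimensionless intersection equation: exp(u^2/2) - 1 = u, u = t/sigma_n.
    # u = 0 is the trivial root; the positive root lies in (1, 3) since
    # exp(1/2) - 2 < 0 < exp(9/2) - 4.
    f = lambda u: math.expm1(u * u / 2.0) - u
    return float(bisect(f, 1.0, 3.0, xtol=1e-13))


def solve_aggd_threshold(sigma_n: float) -> float:
    """Intersection threshold t* solving s(t) - s(0) = t for the AGGD rules.

    The defining equation is scale-equivariant, t*(sigma_n) = sigma_n * t*(1),
    so it is solved once in dimensionless form (bisection on [1, 3] to 1e-13)
    and rescaled; t*(1) = 1.285889...  Always t* > sigma_n, matching the
    t > sigma_n regime of the AGGD families.
    """
    if not math.isfinite(sigma_n) or sigma_n <= 0:
        raise ValueError("sigma_n must be finite and > 0")
    return sigma_n * _aggd_unit_ratio()


def select_threshold(family: str, sigma_hat: float, n: int,
                     lam: Optional[float] = None,
                     mu: Optional[float] = None) -> ShrinkageSpec:
    """Build the ShrinkageSpec for a family from the estimated noise level.

    ``lam`` / ``mu`` default to :data:`DEFAULT_LAM` / :data:`DEFAULT_MU` for
    the Zhang families and must be omitted otherwise.  A zero ``sigma_hat``
    (noise-free input) yields a degenerate spec with t = 0 under which every
    family acts as the identity.
    """
    if family not in FAMILIES:
        raise ValueError(
            f"unknown shrinkage family {family!r}; expected one of {FAMILIES}"
        )
    if sigma_hat < 0 or not math.isfinite(sigma_hat):
        raise ValueError("sigma_hat must be finite and >= 0")
    if n < 1:
        raise ValueError("n must be >= 1")

    if family in ("hard", "soft", "zhang_soft", "zhang_hard"):
        t = universal_threshold(sigma_hat, n)
        if family == "zhang_soft":
            return ShrinkageSpec(family, t, lam=DEFAULT_LAM if lam is None else lam)
        if family == "zhang_hard":
            return ShrinkageSpec(family, t, mu=DEFAULT_MU if mu is None else mu)
        return ShrinkageSpec(family, t)
    if lam is not None or mu is not None:
        raise ValueError("lam/mu only apply to the zhang_* families")
    if family in ("adaptive_hard", "adaptive_soft"):
        return ShrinkageSpec(family, t=sigma_hat, sigma_n=sigma_hat)
    # aggd / improved_aggd
    t = solve_aggd_threshold(sigma_hat) if sigma_hat > 0 else 0.0
    return ShrinkageSpec(family, t=t, sigma_n=sigma_hat)
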