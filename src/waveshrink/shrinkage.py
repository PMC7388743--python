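"""Elementwise shrinkage (threshold) functions for wavelet detail coefficients.

Eight families are provided.  The classical *hard* and *soft* rules kill every
coefficient inside the threshold band; Zhang's smooth variants replace the
kink/jump with differentiable surrogates controlled by shape parameters
``lam`` (soft) and ``mu`` (hard).  The adaptive and AGGD families instead
*tune* sub-threshold coefficients through the generalized-Gaussian core

    s(x) = sigma_n * (exp(x**2 / (2 sigma_n**2)) - 1/2),

mapping x in [-t, t] to sign(x) * (s(|x|) - s(0)) so that small, noise-dominated
coefficients are attenuated but never zeroed, while large coefficients are
kept (adaptive hard, AGGD), uniformly shrunk (adaptive soft) or passed through
a sigmoid gate (improved AGGD).

All functions accept scalars or ndarrays and are odd in ``x``.  The middle
branch is written in the odd-symmetric form: the even form would map negative
coefficients to positive values and break continuity at the band edges.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import expit

__all__ = [
    "FAMILIES",
    "ShrinkageSpec",
    "s_core",
    "shrink_hard",
    "shrink_soft",
    "shrink_zhang_soft",
    "shrink_zhang_hard",
    "shrink_adaptive_hard",
    "shrink_adaptive_soft",
    "shrink_aggd",
    "shrink_improved_aggd",
    "apply_shrinkage",
]

#: Recognised shrinkage families, in increasing order of sophistication.
FAMILIES = (
    "hard",
    "soft",
    "zhang_soft",
    "zhang_hard",
    "adaptive_hard",
    "adaptive_soft",
    "aggd",
    "improved_aggd",
)

_SIGMA_FAMILIES = frozenset(
    {"adaptive_hard", "adaptive_soft", "aggd", "improved_aggd"}
)


def _as_array(x):
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("coefficients must be finite")
    return arr, np.isscalar(x) or np.ndim(x) == 0


def _ret(res, scalar):
    return float(res) if scalar else res


def _check_positive(name, value):
    if not np.isfinite(value) or value <= 0:
        raise ValueError(f"{name} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class ShrinkageSpec:
    """Which threshold family to apply, plus its parameters.

    Parameters
    ----------
    family : str
        One of :data:`FAMILIES`.
    t : float
        Threshold value in coefficient units.  Normally strictly positive;
        ``t == 0`` is the degenerate noise-free case in which every family
        acts as the identity.
    sigma_n : float, optional
        Noise standard deviation in coefficient units.  Required for the
        families built on the generalized-Gaussian core.  The adaptive
        families use ``t == sigma_n``; the AGGD families require
        ``t >= sigma_n``.
    lam : float, optional
        Zhang soft shape parameter (lambda >= 0); required iff
        ``family == "zhang_soft"``.
    mu : float, optional
        Zhang hard shape parameter (mu > 0); required iff
        ``family == "zhang_hard"``.
    """

    family: str
    t: float
    sigma_n: Optional[float] = None
    lam: Optional[float] = None
    mu: Optional[float] = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown shrinkage family {self.family!r}; "
                f"expected one of {FAMILIES}"
            )
        if not np.isfinite(self.t) or self.t < 0:
            raise ValueError(f"threshold t must be finite and >= 0, got {self.t!r}")
        if self.family in _SIGMA_FAMILIES:
            if self.sigma_n is None:
                raise ValueError(f"family {self.family!r} requires sigma_n")
            if not np.isfinite(self.sigma_n) or self.sigma_n < 0:
                raise ValueError("sigma_n must be finite and >= 0")
            if self.family in ("adaptive_hard", "adaptive_soft"):
                if not np.isclose(self.t, self.sigma_n, rtol=1e-9, atol=0.0):
                    raise ValueError(
                        "adaptive families use t == sigma_n "
                        f"(got t={self.t}, sigma_n={self.sigma_n})"
                    )
            elif self.t < self.sigma_n:
                raise ValueError(
                    "AGGD families require t >= sigma_n "
                    f"(got t={self.t}, sigma_n={self.sigma_n})"
                )
        if self.family == "zhang_soft":
            if self.lam is None or self.lam < 0:
                raise ValueError("zhang_soft requires lam >= 0")
        elif self.lam is not None:
            raise ValueError("lam is only meaningful for zhang_soft")
        if self.family == "zhang_hard":
            if self.mu is None or self.mu <= 0:
                raise ValueError("zhang_hard requires mu > 0")
        elif self.mu is not None:
            raise ValueError("mu is only meaningful for zhang_hard")

    @property
    def is_degenerate(self) -> bool:
        """True when t == 0 (noise-free input): shrinkage is the identity."""
        return self.t == 0


def s_core(x, sigma_n):
    """Generalized-Gaussian core s(x) = sigma_n * (exp(x^2/(2 sigma_n^2)) - 1/2).

    Even in ``x``, with ``s(0) = sigma_n / 2``.
    """
    _check_positive("sigma_n", sigma_n)
    arr, scalar = _as_array(x)
    res = sigma_n * (np.exp(arr * arr / (2.0 * sigma_n**2)) - 0.5)
    return _ret(res, scalar)


def _aggd_mid(x, sigma_n, half_width):
    # sign(x) * (s(|x|) - s(0)) evaluated only inside the band; clipping keeps
    # the dead branch of np.where from overflowing the exponential.
    xc = np.clip(x, -half_width, half_width)
    return np.sign(xc) * sigma_n * np.expm1(xc * xc / (2.0 * sigma_n**2))


def shrink_hard(x, t):
    """Standard keep-or-kill rule: x if |x| > t, else 0."""
    _check_positive("t", t)
    arr, scalar = _as_array(x)
    return _ret(np.where(np.abs(arr) > t, arr, 0.0), scalar)


def shrink_soft(x, t):
    """Standard soft rule: sign(x) * max(|x| - t, 0)."""
    _check_positive("t", t)
    arr, scalar = _as_array(x)
    return _ret(np.sign(arr) * np.maximum(np.abs(arr) - t, 0.0), scalar)


def shrink_zhang_soft(x, t, lam):
    """Zhang's smooth soft rule x + (sqrt((x-t)^2+lam) - sqrt((x+t)^2+lam))/2.

    Converges to :func:`shrink_soft` as ``lam -> 0``.
    """
    _check_positive("t", t)
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam!r}")
    arr, scalar = _as_array(x)
    res = arr + 0.5 * (
        np.sqrt((arr - t) ** 2 + lam) - np.sqrt((arr + t) ** 2 + lam)
    )
    return _ret(res, scalar)


def shrink_zhang_hard(x, t, mu):
    """Zhang's smooth hard rule: a sigmoid gate multiplying x.

    The multiplier is sigmoid((x-t)/mu) - sigmoid((x+t)/mu) + 1, evaluated
    through :func:`scipy.special.expit` so large |x +- t| / mu never
    overflows.  Converges pointwise to :func:`shrink_hard` as ``mu -> 0``
    (except exactly at |x| = t).
    """
    _check_positive("t", t)
    _check_positive("mu", mu)
    arr, scalar = _as_array(x)
    gate = expit((arr - t) / mu) - expit((arr + t) / mu) + 1.0
    return _ret(gate * arr, scalar)


def shrink_adaptive_hard(x, sigma_n):
    """'Tune and keep': identity for |x| > sigma_n, AGGD core inside.

    Discontinuous at |x| = sigma_n, like the standard hard rule, but
    sub-threshold coefficients are attenuated rather than zeroed.
    """
    _check_positive("sigma_n", sigma_n)
    arr, scalar = _as_array(x)
    mid = _aggd_mid(arr, sigma_n, sigma_n)
    return _ret(np.where(np.abs(arr) > sigma_n, arr, mid), scalar)


def shrink_adaptive_soft(x, sigma_n):
    """'Tune and shrink': AGGD core inside, shifted identity outside.

    With t = sigma_n the outer branch is sign(x) * (|x| - (t - (s(t)-s(0)))),
    which meets the core at |x| = sigma_n, so the function is continuous
    everywhere.
    """
    _check_positive("sigma_n", sigma_n)
    arr, scalar = _as_array(x)
    # t = sigma_n; s(t) - s(0) = sigma_n * (e^{1/2} - 1)
    shift = sigma_n * (2.0 - np.exp(0.5))
    mid = _aggd_mid(arr, sigma_n, sigma_n)
    outer = np.sign(arr) * (np.abs(arr) - shift)
    return _ret(np.where(np.abs(arr) > sigma_n, outer, mid), scalar)


def shrink_aggd(x, sigma_n, t):
    """AGGD rule: identity for |x| > t, AGGD core inside [-t, t].

    Continuous at |x| = t exactly when t solves s(t) - s(0) = t, the
    intersection threshold returned by
    :func:`waveshrink.thresholds.solve_aggd_threshold`.
    """
    _check_positive("sigma_n", sigma_n)
    _check_positive("t", t)
    if t < sigma_n:
        raise ValueError("AGGD requires t >= sigma_n")
    arr, scalar = _as_array(x)
    mid = _aggd_mid(arr, sigma_n, t)
    return _ret(np.where(np.abs(arr) > t, arr, mid), scalar)


def shrink_improved_aggd(x, sigma_n, t):
    """Improved AGGD rule: sigmoid-gated outer branches, AGGD core inside.

    For x > t the branch is sigmoid(x - t) * x + t/2 (mirrored for x < -t),
    which equals t at the band edge, so the whole function is continuous at
    +-t exactly when t is the intersection threshold t*.  Fully non-linear
    and differentiable away from the band edges.
    """
    _check_positive("sigma_n", sigma_n)
    _check_positive("t", t)
    if t < sigma_n:
        raise ValueError("improved AGGD requires t >= sigma_n")
    arr, scalar = _as_array(x)
    mid = _aggd_mid(arr, sigma_n, t)
    right = expit(arr - t) * arr + t / 2.0
    left = expit(-(arr + t)) * arr - t / 2.0
    res = np.where(arr > t, right, np.where(arr < -t, left, mid))
    return _ret(res, scalar)


def apply_shrinkage(coeffs, spec: ShrinkageSpec):
    """Apply the family selected by ``spec`` elementwise to ``coeffs``.

    Shape-preserving; the input array is never mutated.  A degenerate spec
    (t == 0, noise-free input) returns an unmodified copy.
    """
    if not isinstance(spec, ShrinkageSpec):
        raise TypeError("spec must be a ShrinkageSpec")
    arr = np.array(coeffs, dtype=float, copy=True)
    if arr.size == 0:
        return arr
    if not np.all(np.isfinite(arr)):
        raise ValueError("coefficients must be finite")
    if spec.is_degenerate:
        return arr
    if spec.family == "hard":
        return shrink_hard(arr, spec.t)
    if spec.family == "soft":
        return shrink_soft(arr, spec.t)
    if spec.family == "zhang_soft":
        return shrink_zhang_soft(arr, spec.t, spec.lam)
    if spec.family == "zhang_hard":
        return shrink_zhang_hard(arr, spec.t, spec.mu)
    if spec.family == "adaptive_hard":
        return shrink_adaptive_hard(arr, spec.sigma_n)
    if spec.family == "adaptive_soft":
        return shrink_adaptive_soft(arr, spec.sigma_n)
    if spec.family == "aggd":
        return shrink_aggd(arr, spec.sigma_n, spec.t)
    if spec.family == "improved_aggd":
        return shrink_improved_aggd(arr, spec.sigma_n, spec.t)
    raise ValueError(f"unknown shrinkage family {spec.family!r}")  # unreachable
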