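"""Image-quality metrics on the [0, 255] intensity scale.

MSE is the plain 1/(MN) sum of squared pixel differences; PSNR is
10 * log10(255^2 / MSE) in dB, with the peak fixed at 255 regardless of the
actual image maximum (inputs on other scales must be rescaled first).
Identical images have MSE 0 and an infinite-PSNR sentinel (math.inf).
"""

from __future__ import annotations

import math
from typing import NamedTuple

import numpy as np

__all__ = ["MetricPair", "mse", "psnr", "evaluate_pair", "PEAK"]

PEAK = 255.0


class MetricPair(NamedTuple):
    mse: float
    psnr_db: float  # math.inf when mse == 0


def _check_pair(ref, test):
    r = np.asarray(ref, dtype=float)
    t = np.asarray(test, dtype=float)
    if r.shape != t.shape:
        raise ValueError(f"shape mismatch: ref {r.shape} vs test {t.shape}")
    if not (np.all(np.isfinite(r)) and np.all(np.isfinite(t))):
        raise ValueError("images must be finite")
    return r, t


def mse(ref, test) -> float:
    """Mean squared error; symmetric in its arguments."""
    r, t = _check_pair(ref, test)
    return float(np.mean((r - t) ** 2))


def psnr(ref, test) -> float:
    """Peak signal-to-noise ratio, 10 * log10(255^2 / MSE), in dB."""
    err = mse(ref, test)
    if err == 0.0:
        return math.inf
    return 10.0 * math.log10(PEAK * PEAK / err)


def evaluate_pair(ref, test) -> MetricPair:
    """Both metrics at once, as produced by the ``evaluate`` CLI subcommand."""
    err = mse(ref, test)
    return MetricPair(mse=err,
                      psnr_db=math.inf if err == 0.0
                      else 10.0 * math.log10(PEAK * PEAK / err))
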