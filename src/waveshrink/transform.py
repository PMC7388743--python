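"""2-D discrete wavelet decomposition and reconstruction (PyWavelets backed).

The decomposition container keeps the approximation (LL) band and, per level
from coarsest to finest, the (LH, HL, HH) detail triplets, along with enough
metadata to invert exactly: wavelet name, depth and the original image shape
(waverec2 can overshoot odd shapes by one row/column, so reconstruction crops).
Symmetric (half-sample) boundary extension is used throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np
import pywt

__all__ = ["WaveletDecomposition", "decompose", "reconstruct", "BOUNDARY_MODE"]

BOUNDARY_MODE = "symmetric"


@dataclass
class WaveletDecomposition:
    """Multilevel 2-D DWT of an image.

    ``details[k]`` is the (LH, HL, HH) triplet of level ``levels - k``, i.e.
    coarsest first and finest last, matching PyWavelets' wavedec2 layout.
    """

    approx: np.ndarray
    details: List[Tuple[np.ndarray, np.ndarray, np.ndarray]]
    wavelet: str
    levels: int
    original_shape: Tuple[int, int]

    def __post_init__(self):
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if len(self.details) != self.levels:
            raise ValueError("details must hold one (LH, HL, HH) triplet per level")

    @property
    def hh_finest(self) -> np.ndarray:
        """Finest-level diagonal subband (HH1), used for noise estimation."""
        return self.details[-1][2]

    def map_details(self, func) -> "WaveletDecomposition":
        """Return a new decomposition with ``func`` applied to every detail band."""
        new_details = [tuple(func(band) for band in triplet)
                       for triplet in self.details]
        return WaveletDecomposition(self.approx.copy(), new_details,
                                    self.wavelet, self.levels,
                                    self.original_shape)


def decompose(img, wavelet: str = "db4", levels: int = 1) -> WaveletDecomposition:
    """Multilevel 2-D DWT; defaults follow the Db4 / one-level protocol."""
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image must be finite")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    wav = pywt.Wavelet(wavelet)
    max_lev = pywt.dwt_max_level(min(arr.shape), wav.dec_len)
    if levels > max_lev:
        raise ValueError(
            f"image of shape {arr.shape} supports at most {max_lev} "
            f"decomposition level(s) with {wavelet}, requested {levels}"
        )
    coeffs = pywt.wavedec2(arr, wav, mode=BOUNDARY_MODE, level=levels)
    approx = coeffs[0]
    details = [tuple(np.asarray(b) for b in triplet) for triplet in coeffs[1:]]
    return WaveletDecomposition(approx=approx, details=details, wavelet=wavelet,
                                levels=levels, original_shape=arr.shape)


def reconstruct(dec: WaveletDecomposition) -> np.ndarray:
    """Inverse 2-D DWT cropped to the original image shape."""
    coeffs = [dec.approx] + [tuple(triplet) for triplet in dec.details]
    try:
        out = pywt.waverec2(coeffs, pywt.Wavelet(dec.wavelet), mode=BOUNDARY_MODE)
    except ValueError as exc:
        raise ValueError(f"inconsistent subband shapes: {exc}") from exc
    r, c = dec.original_shape
    if out.shape[0] < r or out.shape[1] < c:
        raise ValueError(
            f"reconstruction of shape {out.shape} cannot cover "
            f"original shape {dec.original_shape}"
        )
    return out[:r, :c]
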