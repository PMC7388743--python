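"""The denoising model and its results object.

`WaveletDenoiser` is constructed from a noisy image plus the method
configuration (shrinkage family, wavelet, depth, shape parameters); `fit()`
runs decompose -> estimate sigma -> select threshold -> shrink all detail
subbands -> reconstruct -> clip, and returns a `DenoiseResult` carrying the
denoised image, the estimated noise level and threshold, optional
MSE/PSNR against a clean reference, and a `summary()` table.

`run_benchmark` sweeps noise variances, seeds and families over a clean
image, reproducing the familiar PSNR/MSE comparison-table structure.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import imgio
from .metrics import evaluate_pair
from .phantom import NoiseModel, add_awgn
from .shrinkage import FAMILIES, apply_shrinkage
from .thresholds import (DEFAULT_LAM, DEFAULT_MU, estimate_sigma,
                         select_threshold)
from .transform import decompose, reconstruct

__all__ = ["WaveletDenoiser", "DenoiseResult", "denoise", "run_benchmark"]


@dataclass
class DenoiseResult:
    """Outcome of one denoising fit.

    ``mse`` / ``psnr_db`` are present iff a clean reference was supplied to
    :meth:`WaveletDenoiser.fit`.
    """

    image: np.ndarray
    sigma_hat: float
    threshold: float
    family: str
    wavelet: str
    levels: int
    mse: Optional[float] = None
    psnr_db: Optional[float] = None

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            "Wavelet shrinkage de-noising",
            "=" * 34,
            f"{'family':<22}{self.family}",
            f"{'wavelet':<22}{self.wavelet}",
            f"{'levels':<22}{self.levels}",
            f"{'sigma_hat':<22}{self.sigma_hat:.4f}",
            f"{'threshold':<22}{self.threshold:.4f}",
        ]
        if self.psnr_db is not None:
            lines.append(f"{'MSE vs reference':<22}{self.mse:.2f}")
            lines.append(f"{'PSNR vs reference':<22}{self.psnr_db:.2f} dB")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serialisable report (without the pixel data)."""
        d = {
            "family": self.family,
            "wavelet": self.wavelet,
            "levels": self.levels,
            "sigma_hat": self.sigma_hat,
            "threshold": self.threshold,
        }
        if self.psnr_db is not None:
            d["mse"] = self.mse
            d["psnr_db"] = None if math.isinf(self.psnr_db) else self.psnr_db
        return d

    def save_report(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    def plot(self, noisy=None, reference=None, ax=None):
        """Show the denoised image (and optionally noisy/reference panels)."""
        import matplotlib.pyplot as plt

        panels = [("de-noised", self.image)]
        if noisy is not None:
            panels.insert(0, ("noisy", np.asarray(noisy)))
        if reference is not None:
            panels.insert(0, ("reference", np.asarray(reference)))
        if ax is None:
            _, axes = plt.subplots(1, len(panels), squeeze=False)
            axes = axes[0]
        else:
            axes = [ax]
        for a, (title, img) in zip(axes, panels):
            a.imshow(np.clip(img, 0, 255), cmap="gray", vmin=0, vmax=255)
            a.set_title(title)
            a.set_axis_off()
        return axes


class WaveletDenoiser:
    """Wavelet-shrinkage denoiser for a 2-D grayscale image.

    Parameters
    ----------
    image : array-like
        Noisy grayscale image on the [0, 255] scale (colour arrays are
        collapsed to luminance).
    family : str
        Shrinkage family, one of :data:`waveshrink.shrinkage.FAMILIES`.
    wavelet : str
        PyWavelets wavelet name; default ``"db4"``.
    levels : int
        Decomposition depth; default 1.
    lam, mu : float
        Shape parameters for the ``zhang_soft`` / ``zhang_hard`` families
        (ignored by the others).
    """

    def __init__(self, image, family: str = "improved_aggd",
                 wavelet: str = "db4", levels: int = 1,
                 lam: float = DEFAULT_LAM, mu: float = DEFAULT_MU):
        if family not in FAMILIES:
            raise ValueError(
                f"unknown shrinkage family {family!r}; expected one of {FAMILIES}"
            )
        arr = np.asarray(image, dtype=float)
        if arr.ndim == 3:
            arr = imgio.to_luminance(arr)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2-D image, got ndim={arr.ndim}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image must be finite")
        self.image = arr
        self.family = family
        self.wavelet = wavelet
        self.levels = levels
        self.lam = lam
        self.mu = mu

    @classmethod
    def from_file(cls, path: str, slice_index: Optional[int] = None, **kwargs
                  ) -> "WaveletDenoiser":
        """Build the model from a PNG/TIFF/NIfTI file."""
        return cls(imgio.read_image(path, slice_index=slice_index), **kwargs)

    def fit(self, reference=None) -> DenoiseResult:
        """Run the full pipeline and return a :class:`DenoiseResult`.

        Deterministic given the input image.  The approximation (LL)
        subband is never thresholded; all detail subbands at all levels are
        shrunk with the same spec.  The output is clipped to [0, 255]
        *before* any metric is computed, so reported PSNR corresponds to
        the storable image.
        """
        dec = decompose(self.image, self.wavelet, self.levels)
        est = estimate_sigma(dec.hh_finest)
        kwargs = {}
        if self.family == "zhang_soft":
            kwargs["lam"] = self.lam
        elif self.family == "zhang_hard":
            kwargs["mu"] = self.mu
        spec = select_threshold(self.family, est.sigma_hat,
                                n=self.image.size, **kwargs)
        shrunk = dec.map_details(lambda band: apply_shrinkage(band, spec))
        out = np.clip(reconstruct(shrunk), 0.0, 255.0)

        res_mse = res_psnr = None
        if reference is not None:
            pair = evaluate_pair(reference, out)
            res_mse, res_psnr = pair.mse, pair.psnr_db
        return DenoiseResult(image=out, sigma_hat=est.sigma_hat,
                             threshold=spec.t, family=self.family,
                             wavelet=self.wavelet, levels=self.levels,
                             mse=res_mse, psnr_db=res_psnr)


def denoise(image, family: str, wavelet: str = "db4", levels: int = 1,
            lam: float = DEFAULT_LAM, mu: float = DEFAULT_MU,
            reference=None) -> DenoiseResult:
    """Functional one-shot wrapper around :class:`WaveletDenoiser`."""
    return WaveletDenoiser(image, family=family, wavelet=wavelet,
                           levels=levels, lam=lam, mu=mu).fit(reference)


def run_benchmark(clean, variances: Sequence[float], families: Sequence[str],
                  seeds: Sequence[int], wavelet: str = "db4", levels: int = 1,
                  lam: float = DEFAULT_LAM, mu: float = DEFAULT_MU,
                  include_noisy: bool = False) -> pd.DataFrame:
    """PSNR/MSE sweep over noise variances, seeds and shrinkage families.

    For each (variance, seed) an AWGN-corrupted copy of ``clean`` is
    denoised with every family; PSNR and MSE against ``clean`` are averaged
    over seeds.  With ``include_noisy`` a baseline row per variance reports
    the metrics of the clipped noisy input itself.  Returns a DataFrame
    with columns (family, variance, psnr_db, mse); fully deterministic
    given the seed list.
    """
    clean = np.asarray(clean, dtype=float)
    if not variances or not list(families) or not list(seeds):
        raise ValueError("variances, families and seeds must be non-empty")
    unknown = set(families) - set(FAMILIES)
    if unknown:
        raise ValueError(f"unknown families: {sorted(unknown)}")

    rows = []
    for v in variances:
        scores = {fam: [] for fam in families}
        noisy_scores = []
        for s in seeds:
            noisy = add_awgn(clean, NoiseModel(variance=v, seed=s))
            if include_noisy:
                noisy_scores.append(
                    evaluate_pair(clean, np.clip(noisy, 0.0, 255.0)))
            for fam in families:
                res = denoise(noisy, fam, wavelet=wavelet, levels=levels,
                              lam=lam, mu=mu, reference=clean)
                scores[fam].append((res.psnr_db, res.mse))
        if include_noisy:
            rows.append(dict(
                family="noisy", variance=v,
                psnr_db=float(np.mean([p.psnr_db for p in noisy_scores])),
                mse=float(np.mean([p.mse for p in noisy_scores]))))
        for fam in families:
            psnrs, mses = zip(*scores[fam])
            rows.append(dict(family=fam, variance=v,
                             psnr_db=float(np.mean(psnrs)),
                             mse=float(np.mean(mses))))
    return pd.DataFrame(rows, columns=["family", "variance", "psnr_db", "mse"])
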