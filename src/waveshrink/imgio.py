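"""Reading and writing 2-D grayscale images on the [0, 255] float scale.

PNG/TIFF go through imageio; NIfTI volumes go through nibabel with a slice
index (middle axial slice by default).  Integer inputs are rescaled from
their dtype range to [0, 255]; float inputs on [0, 1] are scaled by 255,
other float inputs are min-max rescaled; colour inputs are collapsed to
Rec. 709 luminance.
"""

from __future__ import annotations

import numpy as np

__all__ = ["read_image", "write_image", "to_luminance"]

_LUMA = np.array([0.2126, 0.7152, 0.0722])


def to_luminance(arr: np.ndarray) -> np.ndarray:
    """Collapse an (r, c, 3|4) colour array to single-channel luminance."""
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return arr[..., :3] @ _LUMA
    if arr.ndim == 2:
        return arr
    raise ValueError(f"cannot interpret array of shape {arr.shape} as an image")


def _rescale(arr: np.ndarray) -> np.ndarray:
    if np.issubdtype(arr.dtype, np.uint8):
        return arr.astype(float)
    if np.issubdtype(arr.dtype, np.uint16):
        return arr.astype(float) * (255.0 / 65535.0)
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float)
    arr = np.asarray(arr, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    if lo >= 0.0 and hi <= 1.0:
        return arr * 255.0
    if lo >= 0.0 and hi <= 255.0:
        return arr
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) * (255.0 / (hi - lo))


def read_image(path: str, slice_index: int | None = None) -> np.ndarray:
    """Read a grayscale image (PNG/TIFF/NIfTI) as float64 on [0, 255].

    ``slice_index`` selects the axial slice of a NIfTI volume (middle slice
    when omitted); it is ignored for 2-D raster formats.
    """
    p = str(path)
    if p.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        vol = np.asanyarray(nib.load(p).dataobj)
        if vol.ndim == 2:
            sl = vol
        elif vol.ndim >= 3:
            vol = vol.reshape(vol.shape[:3])
            idx = vol.shape[2] // 2 if slice_index is None else slice_index
            if not (0 <= idx < vol.shape[2]):
                raise ValueError(
                    f"slice index {idx} out of range for volume with "
                    f"{vol.shape[2]} slices"
                )
            sl = vol[:, :, idx]
        else:
            raise ValueError(f"unsupported NIfTI dimensionality {vol.ndim}")
        return _rescale(np.asarray(sl))

    import imageio.v3 as iio

    arr = iio.imread(p)
    lum = to_luminance(arr) if arr.ndim == 3 else arr
    return _rescale(np.asarray(lum))


def write_image(path: str, img: np.ndarray, bitdepth: int = 8) -> None:
    """Write a [0, 255] float image as 8- or 16-bit PNG/TIFF."""
    import imageio.v3 as iio

    arr = np.clip(np.asarray(img, dtype=float), 0.0, 255.0)
    if bitdepth == 8:
        iio.imwrite(str(path), np.round(arr).astype(np.uint8))
    elif bitdepth == 16:
        iio.imwrite(str(path), np.round(arr * (65535.0 / 255.0)).astype(np.uint16))
    else:
        raise ValueError("bitdepth must be 8 or 16")
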