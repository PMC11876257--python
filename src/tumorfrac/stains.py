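"""Two-stain Beer-Lambert optical-density model for H&E.

A pixel's transmitted intensity is ``I = I0 * exp(-OD)`` per channel, with
``OD = c_h * H + c_e * E`` for fixed unit stain vectors ``H`` (hematoxylin)
and ``E`` (eosin) taken from the standard Ruifrok-Johnston H&E pair.
Rendering (:func:`od_to_rgb`) and color deconvolution (:func:`deconvolve`)
share the same vectors, so the transform is exactly invertible up to 8-bit
quantization.
"""

from __future__ import annotations

import numpy as np

__all__ = ["STAIN_H", "STAIN_E", "od_to_rgb", "rgb_to_od", "deconvolve"]


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


#: Hematoxylin absorption direction (RGB optical-density space).
STAIN_H = _unit(np.array([0.650, 0.704, 0.286]))
#: Eosin absorption direction.
STAIN_E = _unit(np.array([0.072, 0.990, 0.105]))

_BASIS = np.stack([STAIN_H, STAIN_E])        # (2, 3)
_PINV = np.linalg.pinv(_BASIS)               # (3, 2), least-squares inverse


def od_to_rgb(od_h: np.ndarray, od_e: np.ndarray) -> np.ndarray:
    """Render per-pixel stain concentrations to an 8-bit RGB image.

    Parameters
    ----------
    od_h, od_e
        Arrays of identical shape ``(H, W)`` holding non-negative
        hematoxylin / eosin optical densities (natural-log scale).
    """
    od = np.multiply.outer(np.asarray(od_h, dtype=float), STAIN_H)
    od += np.multiply.outer(np.asarray(od_e, dtype=float), STAIN_E)
    rgb = 255.0 * np.exp(-od)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8)


def rgb_to_od(rgb: np.ndarray) -> np.ndarray:
    """Per-channel optical density of an 8-bit RGB image.

    Zero-valued (saturated) pixels are floored at 1 before the log so the
    output is always finite; pure white maps to OD 0.
    """
    intensity = np.maximum(np.asarray(rgb, dtype=float), 1.0)
    return -np.log(intensity / 255.0)


def deconvolve(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split an RGB H&E image into hematoxylin and eosin OD channels.

    Least-squares projection of each pixel's OD vector onto the two stain
    directions; negative concentrations (off-model colors) are clipped to 0.

    Returns
    -------
    (od_h, od_e)
        Two float arrays with the spatial shape of ``rgb``.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim != 3 or rgb.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {rgb.shape}")
    od = rgb_to_od(rgb)
    conc = od @ _PINV
    conc = np.maximum(conc, 0.0)
    return conc[..., 0], conc[..., 1]
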