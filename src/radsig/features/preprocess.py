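"""Preprocessing for higher-order features: isotropic resampling and
equal-probability gray-level quantization.

First-order features are computed on the raw in-mask intensities; every
texture family operates on the Ng-level quantized, isotropically resampled
grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


def resample_isotropic(
    image: np.ndarray,
    mask: np.ndarray,
    spacing_mm: tuple[float, float, float],
    target_spacing_mm: float,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float, float]]:
    """Resample image (trilinear) and mask (nearest neighbour) onto a common
    isotropic grid.

    Already-isotropic input at the target spacing is returned unchanged.
    """
    spacing = tuple(float(s) for s in spacing_mm)
    if any(s <= 0 for s in spacing) or target_spacing_mm <= 0:
        raise ValueError("spacings must be positive")
    if np.allclose(spacing, target_spacing_mm):
        return np.asarray(image, float), np.asarray(mask, bool), spacing
    zoom = [s / target_spacing_mm for s in spacing]
    out_img = ndimage.zoom(np.asarray(image, float), zoom, order=1, mode="nearest")
    out_mask = ndimage.zoom(
        np.asarray(mask, float), zoom, order=0, mode="nearest"
    ).astype(bool)
    if not out_mask.any():
        raise ValueError("mask vanished during resampling")
    iso = (target_spacing_mm,) * 3
    return out_img, out_mask, iso


@dataclass
class QuantizedImage:
    """Integer grid with in-mask levels in 1..n_levels; 0 outside the mask."""

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        inside = self.levels[self.mask]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("in-mask levels must lie in 1..n_levels")


def equalize_quantize(
    image: np.ndarray,
    mask: np.ndarray,
    n_levels: int = 64,
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> QuantizedImage:
    """Equal-probability (histogram-equalization) quantization within the mask.

    Each in-mask intensity v maps to ``ceil(F(v) * Ng)`` clipped to [1, Ng],
    with F the empirical CDF of the in-mask intensities. Bin occupancies are
    as uniform as ties permit, the mapping is monotone nondecreasing, and any
    strictly monotone intensity transform leaves the output unchanged.
    """
    mask = np.asarray(mask).astype(bool)
    vals = np.asarray(image, float)[mask]
    if vals.size == 0:
        raise ValueError("mask has no foreground voxel")
    order = np.argsort(vals, kind="mergesort")
    ranks = np.empty(vals.size, dtype=np.int64)
    # rank of the *last* occurrence of each tied value -> CDF with ties
    sorted_vals = vals[order]
    # highest index (1-based) among equal values
    last_of_value = np.searchsorted(sorted_vals, sorted_vals, side="right")
    ranks[order] = last_of_value
    cdf = ranks / vals.size
    lv = np.ceil(cdf * n_levels).astype(np.int64)
    np.clip(lv, 1, n_levels, out=lv)
    levels = np.zeros(mask.shape, dtype=np.int64)
    levels[mask] = lv
    return QuantizedImage(levels, mask, int(n_levels), tuple(float(s) for s in spacing_mm))
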