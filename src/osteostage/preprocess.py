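"""Conform CT volumes and masks to the fixed grid and 8-bit representation.

The classifiers consume volumes resampled to 0.7 x 0.7 x 1.0 mm voxels,
symmetrically zero-padded or cropped to 714 x 714 x 39, bone-window clipped
and mapped to 8-bit integers. Masks ride along with nearest-neighbour
interpolation so integer lesion labels survive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .types import CtVolume

TARGET_SPACING_MM = (0.7, 0.7, 1.0)
TARGET_SHAPE = (714, 714, 39)


@dataclass(frozen=True)
class WindowSpec:
    """A CT display window: center (level) and width in Hounsfield units.

    Defaults to a standard bone window (level 400, width 1800 HU).
    """

    level_hu: float = 400.0
    width_hu: float = 1800.0

    def __post_init__(self) -> None:
        if self.width_hu <= 0:
            raise ValueError("window width must be positive")

    @property
    def lo(self) -> float:
        return self.level_hu - self.width_hu / 2.0

    @property
    def hi(self) -> float:
        return self.level_hu + self.width_hu / 2.0


def resample_volume(
    vol: CtVolume,
    target_spacing: tuple[float, float, float] = TARGET_SPACING_MM,
    interpolation: str = "linear",
) -> CtVolume:
    """Resample to ``target_spacing`` preserving physical extent.

    ``interpolation`` is "linear" for images, "nearest" for (labeled) masks;
    nearest keeps the value set intact so binary masks stay binary.
    """
    if any(s <= 0 for s in target_spacing):
        raise ValueError(f"target spacing must be positive, got {target_spacing}")
    if interpolation not in ("linear", "nearest"):
        raise ValueError(f"interpolation must be linear or nearest, got {interpolation!r}")
    factors = [s / t for s, t in zip(vol.spacing_mm, target_spacing)]
    if all(abs(f - 1.0) < 1e-9 for f in factors):
        return vol.with_voxels(vol.voxels.copy(), spacing_mm=tuple(target_spacing))
    order = 1 if interpolation == "linear" else 0
    data = vol.voxels
    out = ndimage.zoom(
        data.astype(np.float32) if order == 1 else data,
        factors,
        order=order,
        mode="nearest",
        grid_mode=True,
    )
    if order == 1 and np.issubdtype(data.dtype, np.integer):
        out = np.rint(out).astype(data.dtype)
    return vol.with_voxels(out, spacing_mm=tuple(target_spacing))


def _pad_crop_axis(n: int, target: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Symmetric (pad, crop) amounts for one axis; odd remainder goes high."""
    if n < target:
        d = target - n
        return (d // 2, d - d // 2), (0, 0)
    d = n - target
    return (0, 0), (d // 2, d - d // 2)


def conform_extent(vol: CtVolume, target_shape: tuple[int, int, int] = TARGET_SHAPE) -> CtVolume:
    """Symmetrically zero-pad or crop each axis to ``target_shape``.

    When the pad/crop amount is odd the extra voxel goes to the high-index
    side, a fixed convention that makes outputs reproducible.
    """
    data = vol.voxels
    pads, crops = [], []
    for n, t in zip(data.shape, target_shape):
        p, c = _pad_crop_axis(n, t)
        pads.append(p)
        crops.append(c)
    sl = tuple(slice(c0, n - c1) for (c0, c1), n in zip(crops, data.shape))
    data = data[sl]
    if any(p != (0, 0) for p in pads):
        data = np.pad(data, pads, mode="constant", constant_values=0)
    assert data.shape == tuple(target_shape)
    return vol.with_voxels(data)


def window_and_quantize(vol: CtVolume, window: WindowSpec = WindowSpec()) -> CtVolume:
    """Clip HU to the window and map affinely to 8-bit [0, 255], half-up rounding."""
    if vol.quantized:
        raise ValueError("volume is already quantized")
    hu = vol.voxels.astype(np.float64)
    clipped = np.clip(hu, window.lo, window.hi)
    scaled = (clipped - window.lo) / window.width_hu * 255.0
    # round half-up (np.rint rounds half-to-even)
    q = np.floor(scaled + 0.5).astype(np.uint8)
    return vol.with_voxels(q, quantized=True)


def preprocess_case(
    vol: CtVolume,
    labeled_mask: CtVolume,
    target_spacing: tuple[float, float, float] = TARGET_SPACING_MM,
    target_shape: tuple[int, int, int] = TARGET_SHAPE,
    window: WindowSpec = WindowSpec(),
) -> tuple[CtVolume, CtVolume]:
    """Full conforming pipeline for one image + labeled-mask pair.

    Resamples (linear image / nearest mask), conforms the extent, then
    window-quantizes the image. Idempotent: feeding the output back through
    (mask plus an already-quantized image skips re-quantization) reproduces
    it exactly.
    """
    if vol.shape != labeled_mask.shape or vol.spacing_mm != labeled_mask.spacing_mm:
        raise ValueError(
            f"image and mask disagree: shapes {vol.shape} vs {labeled_mask.shape}, "
            f"spacings {vol.spacing_mm} vs {labeled_mask.spacing_mm}"
        )
    img = resample_volume(vol, target_spacing, "linear") if not vol.quantized else vol
    msk = resample_volume(labeled_mask, target_spacing, "nearest")
    img = conform_extent(img, target_shape)
    msk = conform_extent(msk, target_shape)
    if not img.quantized:
        img = window_and_quantize(img, window)
    return img, msk
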