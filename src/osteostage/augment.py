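"""Seeded training-time augmentation, including unfocused ROI extraction.

Transforms apply in a fixed order (horizontal flip, z flip, rotation, zoom)
so a recorded RNG state reproduces a sample exactly. Unfocused extraction
perturbs the ROI *before* extraction — shifting the crop centre and
dilating/eroding the delineation — to mimic the uncertainty of real lesion
delineation by a radiologist or detector.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import ball

from .extract import STRATEGIES, Strategy, extract_lesion_volume, extract_patch
from .types import CtVolume, LesionRecord, Sample

logger = logging.getLogger(__name__)


@dataclass
class UnfocusedConfig:
    p_apply: float = 0.5
    max_center_shift_frac: float = 0.15
    dilate_erode_range_vox: int = 2


@dataclass
class AugmentConfig:
    """Augmentation parameters; ranges follow the training recipe defaults."""

    p_hflip: float = 0.5
    p_zflip: float = 0.5
    zoom_range: tuple[float, float] = (0.75, 1.25)
    rotation_deg_range: tuple[float, float] = (-15.0, 15.0)
    unfocused: UnfocusedConfig = field(default_factory=UnfocusedConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.zoom_range[0] <= 0 or self.zoom_range[1] < self.zoom_range[0]:
            raise ValueError(f"bad zoom range {self.zoom_range}")
        for p in (self.p_hflip, self.p_zflip, self.unfocused.p_apply):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must lie in [0, 1]")


def _rotate_zoom_plane(plane: np.ndarray, angle_deg: float, zoom: float) -> np.ndarray:
    """Rotate then zoom one 2D plane about its centre, preserving shape."""
    out = plane.astype(np.float32)
    if angle_deg != 0.0:
        out = ndimage.rotate(out, angle_deg, reshape=False, order=1, mode="constant", cval=0.0)
    if zoom != 1.0:
        zoomed = ndimage.zoom(out, zoom, order=1, mode="grid-constant", cval=0.0, grid_mode=True)
        out = _center_fit(zoomed, plane.shape)
    return np.clip(np.rint(out), 0, 255).astype(plane.dtype)


def _center_fit(arr: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Center-crop or zero-pad ``arr`` to ``shape``."""
    out = np.zeros(shape, dtype=arr.dtype)
    src, dst = [], []
    for n, t in zip(arr.shape, shape):
        if n >= t:
            c0 = (n - t) // 2
            src.append(slice(c0, c0 + t))
            dst.append(slice(0, t))
        else:
            p0 = (t - n) // 2
            src.append(slice(0, n))
            dst.append(slice(p0, p0 + n))
    out[tuple(dst)] = arr[tuple(src)]
    return out


def augment_sample(sample: Sample, config: AugmentConfig, rng: np.random.Generator) -> Sample:
    """Apply flips, rotation and zoom; shape, dtype range and label survive.

    The same generator state yields the identical output; rotation is
    in-plane (about the axial z axis) for every dimensionality.
    """
    px = sample.pixels
    is_2d = px.ndim == 2
    is_25d = px.ndim == 3 and sample.strategy in STRATEGIES and (
        STRATEGIES[sample.strategy].dimensionality == "2.5D"
    )
    # draws happen unconditionally so the stream layout is state-independent
    do_h = rng.random() < config.p_hflip
    do_z = rng.random() < config.p_zflip
    angle = float(rng.uniform(*config.rotation_deg_range))
    zoom = float(rng.uniform(*config.zoom_range))

    if is_2d:
        planes = px[None]
        z_axis = None
    elif is_25d:
        planes = px  # channel axis is the z stack
        z_axis = 0
    else:  # 3D (X, Y, Z)
        planes = np.moveaxis(px, 2, 0)
        z_axis = 0

    out = planes
    if do_h:
        out = out[:, ::-1, :]
    if do_z:
        if z_axis is None:
            warnings.warn("z-flip requested on a 2D sample; ignored", RuntimeWarning)
        else:
            out = out[::-1]
    if angle != 0.0 or zoom != 1.0:
        out = np.stack([_rotate_zoom_plane(p, angle, zoom) for p in out], axis=0)
    else:
        out = out.copy()

    if is_2d:
        new_px = out[0]
    elif is_25d:
        new_px = out
    else:
        new_px = np.moveaxis(out, 0, 2)
    assert new_px.shape == px.shape
    return Sample(
        pixels=new_px.astype(px.dtype),
        lesion_id=sample.lesion_id,
        strategy=sample.strategy,
        z_index=sample.z_index,
        window_index=sample.window_index,
        weight=sample.weight,
        meta={**sample.meta, "augmented": True},
    )


def _perturb_mask(mask3d: np.ndarray, amount: int) -> np.ndarray:
    """Dilate (amount > 0) or erode (< 0) with a ball structuring element."""
    if amount == 0:
        return mask3d
    struct = ball(abs(amount))
    if amount > 0:
        return ndimage.binary_dilation(mask3d, struct)
    eroded = ndimage.binary_erosion(mask3d, struct)
    if not eroded.any():
        logger.info("unfocused erosion annihilated the mask; keeping the original")
        return mask3d
    return eroded


def unfocused_extract(
    volume: CtVolume,
    mask3d: np.ndarray,
    lesion: LesionRecord,
    z: int | None,
    strategy: Strategy | str,
    config: AugmentConfig,
    rng: np.random.Generator,
) -> Sample:
    """Extract with a randomly perturbed ROI (centre shift + mask morphology).

    The crop centre moves by up to ``max_center_shift_frac`` of the bbox
    side per axis (implemented by translating the mask used for ROI
    geometry); masked strategies additionally see the delineation dilated or
    eroded within ``dilate_erode_range_vox``. Shift 0 / perturbation 0
    reduces to focused extraction exactly.
    """
    if isinstance(strategy, str):
        strategy = STRATEGIES[strategy]
    ucfg = config.unfocused
    idx = np.argwhere(mask3d)
    if idx.size == 0:
        raise ValueError("empty lesion mask")
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    sides = hi - lo
    shift = np.array(
        [
            int(round(rng.uniform(-ucfg.max_center_shift_frac, ucfg.max_center_shift_frac) * s))
            for s in sides
        ]
    )
    shift[2] = 0  # slices are addressed explicitly; shift acts in-plane
    geo_mask = mask3d
    if shift.any():
        geo_mask = np.zeros_like(mask3d)
        src = idx + shift
        keep = (src >= 0).all(axis=1) & (src < np.array(mask3d.shape)).all(axis=1)
        src = src[keep]
        geo_mask[src[:, 0], src[:, 1], src[:, 2]] = True
        if not geo_mask.any():
            geo_mask = mask3d
    if strategy.masked and ucfg.dilate_erode_range_vox > 0:
        amount = int(rng.integers(-ucfg.dilate_erode_range_vox, ucfg.dilate_erode_range_vox + 1))
        geo_mask = _perturb_mask(geo_mask, amount)
    if strategy.dimensionality == "3D":
        return extract_lesion_volume(volume, geo_mask, lesion, strategy)
    zs = np.flatnonzero(geo_mask.any(axis=(0, 1)))
    z_use = z if z is not None and geo_mask[:, :, z].any() else int(zs[len(zs) // 2])
    return extract_patch(volume, geo_mask, lesion, z_use, strategy)
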