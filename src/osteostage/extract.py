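"""The 12 patch / lesion ROI extraction strategies.

Eight axial patch strategies come in a 2.5D flavour (A..H: the lesion slice
plus its two neighbours stacked as channels R = z-1, G = z, B = z+1) and a
2D flavour (A'..H': the lesion slice alone). Four volumetric strategies
(I, J, K, L) feed the 3D networks. Each strategy isolates a different mix
of lesion factors:

====  =========================================================  ==============
id    geometry                                                   factors
====  =========================================================  ==============
A     binary lesion mask, square crop (side = max bbox side)     morphology
B     binary lesion mask on the full canvas                      morphology, location
C     image * mask, square crop                                  morphology, texture
D     image * mask on the full canvas                            size, morphology, texture, location
E     image, square bbox crop                                    texture
F     image, fixed 173 x 173 canvas centred on the centroid      size, texture
G     full canvas, zeroed outside a 173 x 173 neighbourhood      size, texture, location
H     image, tight rectangular bbox crop                         texture (aspect distorted on resize)
I     image, 145 x 145 x full-z crop centred on the centroid     volumetric context
J     image * mask on the tight bounding volume                  morphology, texture
K     sliding 145 x 145 x 7 windows, stride 2 in z, weighted     morphology, texture
L     image on the tight bounding volume                         size, morphology, texture
====  =========================================================  ==============

The fixed side lengths (173 px, 145 px) are the 99th / 95th percentile
lesion dimensions of the cohort the pipeline was designed around and are
treated as constants, configurable per call.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .types import CtVolume, LesionRecord, Sample

FIXED_PATCH_PX = 173
FIXED_LESION_PX = 145
SLIDING_DEPTH = 7
SLIDING_STRIDE = 2  # depth 7 with overlap 5


@dataclass(frozen=True)
class Strategy:
    """One ROI extraction recipe and the lesion factors it exposes."""

    id: str
    dimensionality: str  # 2D, 2.5D or 3D
    masked: bool
    full_canvas: bool
    fixed_canvas_px: int | None
    channels: int
    factors: frozenset[str]

    def __post_init__(self) -> None:
        if self.dimensionality not in ("2D", "2.5D", "3D"):
            raise ValueError(f"bad dimensionality {self.dimensionality!r}")
        if self.dimensionality == "2.5D" and self.channels != 3:
            raise ValueError("2.5D strategies stack 3 slices as channels")


def _mk(sid, dim, masked, full, fixed, channels, factors):
    return Strategy(sid, dim, masked, full, fixed, channels, frozenset(factors))


_PATCH_FACTORS = {
    "A": {"morphology"},
    "B": {"morphology", "location"},
    "C": {"morphology", "texture"},
    "D": {"size", "morphology", "texture", "location"},
    "E": {"texture"},
    "F": {"size", "texture"},
    "G": {"size", "texture", "location"},
    "H": {"texture"},
}
_PATCH_GEOM = {
    # (masked, full_canvas, fixed_canvas_px)
    "A": (True, False, None),
    "B": (True, True, None),
    "C": (True, False, None),
    "D": (True, True, None),
    "E": (False, False, None),
    "F": (False, False, FIXED_PATCH_PX),
    "G": (False, True, FIXED_PATCH_PX),
    "H": (False, False, None),
}

STRATEGIES: dict[str, Strategy] = {}
for _sid, (_m, _f, _c) in _PATCH_GEOM.items():
    STRATEGIES[_sid] = _mk(_sid, "2.5D", _m, _f, _c, 3, _PATCH_FACTORS[_sid])
    STRATEGIES[_sid + "'"] = _mk(_sid + "'", "2D", _m, _f, _c, 1, _PATCH_FACTORS[_sid])
STRATEGIES["I"] = _mk("I", "3D", False, False, FIXED_LESION_PX, 1, {"volumetric"})
STRATEGIES["J"] = _mk("J", "3D", True, False, None, 1, {"morphology", "texture"})
STRATEGIES["K"] = _mk("K", "3D", False, False, FIXED_LESION_PX, 1, {"morphology", "texture"})
STRATEGIES["L"] = _mk("L", "3D", False, False, None, 1, {"size", "morphology", "texture"})


def lesion_slices(mask3d: np.ndarray) -> list[int]:
    """Ascending z indices where the lesion mask has at least one voxel."""
    mask3d = np.asarray(mask3d)
    if not mask3d.any():
        raise ValueError("empty lesion mask")
    return [int(z) for z in np.flatnonzero(mask3d.any(axis=(0, 1)))]


def mask_bbox(mask3d: np.ndarray) -> tuple[tuple[int, int], tuple[int, int], tuple[int, int]]:
    """Tight half-open bounding box ((x0,x1),(y0,y1),(z0,z1)) of a mask."""
    idx = np.argwhere(mask3d)
    if idx.size == 0:
        raise ValueError("empty lesion mask")
    lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
    return tuple((int(a), int(b)) for a, b in zip(lo, hi))  # type: ignore[return-value]


def mask_centroid(mask3d: np.ndarray) -> tuple[int, int, int]:
    """Voxel-mean of mask coordinates, rounded half-up per axis."""
    idx = np.argwhere(mask3d)
    if idx.size == 0:
        raise ValueError("empty lesion mask")
    c = idx.mean(axis=0)
    return tuple(int(math.floor(v + 0.5)) for v in c)  # type: ignore[return-value]


def _crop2d(plane: np.ndarray, x0: int, y0: int, w: int, h: int) -> np.ndarray:
    """Crop a (possibly out-of-bounds) window from a 2D plane, zero padded."""
    out = np.zeros((w, h), dtype=plane.dtype)
    sx0, sy0 = max(x0, 0), max(y0, 0)
    sx1, sy1 = min(x0 + w, plane.shape[0]), min(y0 + h, plane.shape[1])
    if sx1 > sx0 and sy1 > sy0:
        out[sx0 - x0 : sx1 - x0, sy0 - y0 : sy1 - y0] = plane[sx0:sx1, sy0:sy1]
    return out


def _patch_plane(
    img2d: np.ndarray,
    msk2d: np.ndarray,
    strategy: Strategy,
    bbox,
    centroid_xy: tuple[int, int],
    fixed_px: int,
) -> tuple[np.ndarray, tuple[int, int]]:
    """One slice of a patch strategy; returns the plane and its canvas origin."""
    sid = strategy.id.rstrip("'")
    (x0, x1), (y0, y1), _ = bbox
    bw, bh = x1 - x0, y1 - y0
    if sid in ("A", "B"):
        content = (msk2d > 0).astype(np.uint8) * 255
    elif sid in ("C", "D"):
        content = np.where(msk2d > 0, img2d, 0).astype(np.uint8)
    else:
        content = img2d.astype(np.uint8)
    if strategy.full_canvas:
        if sid == "G":
            cx, cy = centroid_xy
            gx0, gy0 = cx - fixed_px // 2, cy - fixed_px // 2
            out = np.zeros_like(content)
            sx0, sy0 = max(gx0, 0), max(gy0, 0)
            sx1 = min(gx0 + fixed_px, content.shape[0])
            sy1 = min(gy0 + fixed_px, content.shape[1])
            out[sx0:sx1, sy0:sy1] = content[sx0:sx1, sy0:sy1]
            return out, (0, 0)
        return content, (0, 0)
    if sid in ("A", "C", "E"):  # square crop, side = max bbox side, bbox-centred
        side = max(bw, bh)
        cx, cy = x0 + bw // 2, y0 + bh // 2
        ox, oy = cx - side // 2, cy - side // 2
        return _crop2d(content, ox, oy, side, side), (ox, oy)
    if sid == "F":  # fixed canvas centred on the lesion centroid
        if fixed_px < max(bw, bh):
            warnings.warn(
                f"fixed canvas {fixed_px} px smaller than lesion bbox "
                f"({bw} x {bh}); centre-cropping",
                RuntimeWarning,
            )
        cx, cy = centroid_xy
        ox, oy = cx - fixed_px // 2, cy - fixed_px // 2
        return _crop2d(content, ox, oy, fixed_px, fixed_px), (ox, oy)
    if sid == "H":  # tight rectangular bbox crop
        return content[x0:x1, y0:y1].copy(), (x0, y0)
    raise ValueError(f"unknown patch strategy {strategy.id!r}")


def extract_patch(
    volume: CtVolume,
    mask3d: np.ndarray,
    lesion: LesionRecord,
    z: int,
    strategy: Strategy | str,
    fixed_canvas_px: int | None = None,
) -> Sample:
    """Extract one 2D / 2.5D patch at slice ``z`` under a patch strategy.

    2.5D strategies stack slices (z-1, z, z+1) as channels, clamping at the
    volume boundary by edge replication. The sample's ``meta["origin"]``
    records the crop origin so full-canvas strategies are paste-back
    invertible against the source slice.
    """
    if isinstance(strategy, str):
        strategy = STRATEGIES[strategy]
    if strategy.dimensionality == "3D":
        raise ValueError(f"strategy {strategy.id} is volumetric; use extract_lesion_volume")
    zs = lesion_slices(mask3d)
    if z not in zs:
        raise ValueError(f"slice z={z} is outside the lesion (slices {zs[0]}..{zs[-1]})")
    fixed_px = fixed_canvas_px or strategy.fixed_canvas_px or FIXED_PATCH_PX
    bbox = mask_bbox(mask3d)
    cx, cy, _ = mask_centroid(mask3d)
    nz = volume.shape[2]
    if strategy.dimensionality == "2.5D":
        zz = [min(max(z + d, 0), nz - 1) for d in (-1, 0, 1)]
        planes = []
        origin = (0, 0)
        for zi in zz:
            plane, origin = _patch_plane(
                volume.voxels[:, :, zi], mask3d[:, :, zi], strategy, bbox, (cx, cy), fixed_px
            )
            planes.append(plane)
        pixels = np.stack(planes, axis=0)
    else:
        pixels, origin = _patch_plane(
            volume.voxels[:, :, z], mask3d[:, :, z], strategy, bbox, (cx, cy), fixed_px
        )
    return Sample(
        pixels=pixels,
        lesion_id=lesion.lesion_id,
        strategy=strategy.id,
        z_index=z,
        meta={"origin": origin, "bbox": bbox},
    )


def extract_lesion_volume(
    volume: CtVolume,
    mask3d: np.ndarray,
    lesion: LesionRecord,
    strategy: Strategy | str,
    fixed_canvas_px: int | None = None,
) -> Sample:
    """Extract a single 3D sample under strategy I, J or L.

    I: unmasked fixed-size x-y crop (default 145 x 145) centred on the
    lesion centroid, spanning the full z range. J: masked lesion on its
    tight bounding volume. L: unmasked tight bounding volume.
    """
    if isinstance(strategy, str):
        strategy = STRATEGIES[strategy]
    if strategy.id not in ("I", "J", "L"):
        raise ValueError(f"strategy {strategy.id} is not a single-volume 3D strategy")
    bbox = mask_bbox(mask3d)
    (x0, x1), (y0, y1), (z0, z1) = bbox
    if strategy.id == "I":
        side = fixed_canvas_px or strategy.fixed_canvas_px or FIXED_LESION_PX
        cx, cy, _ = mask_centroid(mask3d)
        ox, oy = cx - side // 2, cy - side // 2
        pixels = np.zeros((side, side, volume.shape[2]), dtype=volume.voxels.dtype)
        sx0, sy0 = max(ox, 0), max(oy, 0)
        sx1, sy1 = min(ox + side, volume.shape[0]), min(oy + side, volume.shape[1])
        pixels[sx0 - ox : sx1 - ox, sy0 - oy : sy1 - oy, :] = volume.voxels[sx0:sx1, sy0:sy1, :]
        origin = (ox, oy, 0)
    elif strategy.id == "J":
        sub = np.where(mask3d > 0, volume.voxels, 0)
        pixels = sub[x0:x1, y0:y1, z0:z1].copy()
        origin = (x0, y0, z0)
    else:  # L
        pixels = volume.voxels[x0:x1, y0:y1, z0:z1].copy()
        origin = (x0, y0, z0)
    return Sample(
        pixels=pixels,
        lesion_id=lesion.lesion_id,
        strategy=strategy.id,
        meta={"origin": origin, "bbox": bbox},
    )


def sliding_window_starts(z_extent: int, depth: int = SLIDING_DEPTH, stride: int = SLIDING_STRIDE):
    """Window start offsets covering [0, z_extent): stride-2 with a flush tail."""
    if z_extent <= depth:
        return [0]
    n = math.ceil((z_extent - depth) / stride) + 1
    starts = [min(i * stride, z_extent - depth) for i in range(n)]
    return starts


def sliding_subvolumes(
    volume: CtVolume,
    mask3d: np.ndarray,
    lesion: LesionRecord,
    fixed_canvas_px: int | None = None,
    depth: int = SLIDING_DEPTH,
    stride: int = SLIDING_STRIDE,
) -> list[Sample]:
    """Strategy K: sliding fixed x-y windows of ``depth`` slices along z.

    The lesion's z extent is edge-replicated out to at least ``depth``
    slices; windows advance by ``stride`` (depth 7, overlap 5). Each window
    is weighted by the fraction of the lesion's voxels it contains, so
    marginal windows count less in the weighted lesion vote.
    """
    strategy = STRATEGIES["K"]
    side = fixed_canvas_px or strategy.fixed_canvas_px or FIXED_LESION_PX
    bbox = mask_bbox(mask3d)
    (_, _), (_, _), (z0, z1) = bbox
    ext = z1 - z0
    # padded z index list (edge replication below depth)
    if ext < depth:
        pad_lo = (depth - ext) // 2
        pad_hi = depth - ext - pad_lo
        zlist = [z0] * pad_lo + list(range(z0, z1)) + [z1 - 1] * pad_hi
    else:
        zlist = list(range(z0, z1))
    per_slice = mask3d.sum(axis=(0, 1)).astype(float)
    padded_total = float(sum(per_slice[zi] for zi in zlist))
    cx, cy, _ = mask_centroid(mask3d)
    ox, oy = cx - side // 2, cy - side // 2
    sx0, sy0 = max(ox, 0), max(oy, 0)
    sx1, sy1 = min(ox + side, volume.shape[0]), min(oy + side, volume.shape[1])
    out = []
    for wi, s in enumerate(sliding_window_starts(len(zlist), depth, stride)):
        zw = zlist[s : s + depth]
        pixels = np.zeros((side, side, depth), dtype=volume.voxels.dtype)
        pixels[sx0 - ox : sx1 - ox, sy0 - oy : sy1 - oy, :] = volume.voxels[
            sx0:sx1, sy0:sy1, :
        ][:, :, zw]
        weight = float(sum(per_slice[zi] for zi in zw)) / padded_total
        out.append(
            Sample(
                pixels=pixels,
                lesion_id=lesion.lesion_id,
                strategy="K",
                window_index=wi,
                weight=weight,
                meta={"origin": (ox, oy), "z_window": (int(zw[0]), int(zw[-1]) + 1)},
            )
        )
    return out


def paste_back(sample: Sample, canvas_shape: tuple[int, int]) -> np.ndarray:
    """Re-embed a 2D plane (or the G channel of a 2.5D patch) in the canvas."""
    plane = sample.pixels if sample.pixels.ndim == 2 else sample.pixels[1]
    ox, oy = sample.meta["origin"][:2]
    canvas = np.zeros(canvas_shape, dtype=plane.dtype)
    x0, y0 = max(ox, 0), max(oy, 0)
    x1 = min(ox + plane.shape[0], canvas_shape[0])
    y1 = min(oy + plane.shape[1], canvas_shape[1])
    canvas[x0:x1, y0:y1] = plane[x0 - ox : x1 - ox, y0 - oy : y1 - oy]
    return canvas
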