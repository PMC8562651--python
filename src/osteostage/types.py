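"""Core domain containers shared across the pipeline.

Axis convention: all voxel grids are indexed ``(x, y, z)`` with 0-based
indices; images and their masks live in the same index space. ``z`` is the
axial (slice) direction with the coarsest spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

BENIGN = "benign"
MALIGNANT = "malignant"
LABELS = (BENIGN, MALIGNANT)

#: benign-side lesion subcategories (10) and malignant-side (3)
BENIGN_SUBCATEGORIES = (
    "degenerative_joint_disease",
    "schmorl_nodule",
    "bone_island",
    "exostosis",
    "deformity",
    "fracture",
    "fibrous_dysplasia",
    "hemangioma",
    "lipoma",
    "avascular_necrosis",
)
MALIGNANT_SUBCATEGORIES = ("osteoblastic", "osteolytic", "mixed")
SUBCATEGORY_SIDE = {s: BENIGN for s in BENIGN_SUBCATEGORIES} | {
    s: MALIGNANT for s in MALIGNANT_SUBCATEGORIES
}


@dataclass
class CtVolume:
    """A rank-3 CT intensity grid with voxel spacing metadata.

    ``voxels`` holds Hounsfield units while ``quantized`` is False and 8-bit
    integers in [0, 255] after bone-window quantization.
    """

    voxels: np.ndarray
    spacing_mm: tuple[float, float, float]
    patient_id: str
    quantized: bool = False

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"voxels must be rank 3, got rank {self.voxels.ndim}")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be 3 strictly positive values, got {self.spacing_mm}")
        if self.quantized:
            lo, hi = self.voxels.min(initial=0), self.voxels.max(initial=0)
            if lo < 0 or hi > 255:
                raise ValueError("quantized volume has values outside [0, 255]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)  # type: ignore[return-value]

    def with_voxels(self, voxels: np.ndarray, **kw) -> "CtVolume":
        return replace(self, voxels=voxels, **kw)


@dataclass
class LesionRecord:
    """One annotated lesion: identity, label, subcategory, mask bookkeeping.

    ``mask_label`` is the integer value that selects this lesion in the
    patient's labeled mask volume. ``bbox`` is ((x0, x1), (y0, y1), (z0, z1)),
    half-open on the high side.
    """

    lesion_id: str
    patient_id: str
    label: str
    subcategory: str
    mask_label: int
    bbox: Optional[tuple[tuple[int, int], tuple[int, int], tuple[int, int]]] = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if self.subcategory in SUBCATEGORY_SIDE and SUBCATEGORY_SIDE[self.subcategory] != self.label:
            raise ValueError(
                f"subcategory {self.subcategory!r} is on the "
                f"{SUBCATEGORY_SIDE[self.subcategory]} side but label is {self.label!r}"
            )


@dataclass
class Sample:
    """A network-ready extracted patch or sub-volume with provenance.

    ``pixels`` is (H, W) for 2D, (3, H, W) for 2.5D (channels = z-1, z, z+1),
    or (X, Y, Z) for 3D, 8-bit valued. ``weight`` is 1 except for sliding
    sub-volume windows, where marginal windows weigh less.
    """

    pixels: np.ndarray
    lesion_id: str
    strategy: str
    z_index: Optional[int] = None
    window_index: Optional[int] = None
    weight: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("sample weight must be non-negative")


@dataclass
class ConfusionMatrix:
    """Binary confusion counts at a stated granularity.

    Malignant is the positive class: ``tp`` = malignant predicted malignant,
    ``fn`` = malignant predicted benign, ``tn``/``fp`` the benign analogues.
    ``level`` is SL (slice), LL (lesion) or PL (patient).
    """

    tn: int
    fn: int
    tp: int
    fp: int
    level: str = "LL"

    def __post_init__(self) -> None:
        for name in ("tn", "fn", "tp", "fp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.level not in ("SL", "LL", "PL"):
            raise ValueError(f"level must be SL, LL or PL, got {self.level!r}")

    @property
    def total(self) -> int:
        return self.tn + self.fn + self.tp + self.fp
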