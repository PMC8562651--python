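"""Seeded synthetic CT phantom cohorts with annotated bone lesions.

Stands in for a private clinical dataset of 114 prostate-cancer patients
with 2,880 annotated bone lesions (53.5% malignant across 3 malignant and
10 benign subcategories). Each phantom volume is piecewise-constant soft
tissue with embedded cortical "bone" columns plus Gaussian noise; lesions
are axis-aligned ellipsoids that are hyperdense (blastic), hypodense
(lytic), half-and-half (mixed) or mildly dense (benign) relative to bone.
Benign lesion centers are biased toward the midline column (vertebral
clustering); malignant centers fall uniformly over all bone. No anatomical
realism is claimed — the phantom exists so that texture-, morphology-,
size- and location-bearing ROI strategies have signal to detect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    BENIGN,
    BENIGN_SUBCATEGORIES,
    MALIGNANT,
    MALIGNANT_SUBCATEGORIES,
    SUBCATEGORY_SIDE,
    CtVolume,
    LesionRecord,
)

#: cohort-wide malignant lesion fraction (1541 of 2880)
DEFAULT_MALIGNANT_FRACTION = 1541.0 / 2880.0

_BENIGN_WITHIN = {
    "degenerative_joint_disease": 0.40,
    "schmorl_nodule": 0.15,
    "bone_island": 0.15,
    "exostosis": 0.08,
    "deformity": 0.07,
    "fracture": 0.06,
    "hemangioma": 0.05,
    "avascular_necrosis": 0.03,
    "fibrous_dysplasia": 0.005,  # rare: ~7 lesions in a 2880-lesion cohort
    "lipoma": 0.005,  # rare
}
_MALIGNANT_WITHIN = {"osteoblastic": 0.55, "mixed": 0.25, "osteolytic": 0.20}


def default_prevalence(malignant_fraction: float = DEFAULT_MALIGNANT_FRACTION) -> dict[str, float]:
    """Skewed 13-subcategory prevalence (sums to 1) with two rare benign kinds."""
    prev = {s: p * (1 - malignant_fraction) for s, p in _BENIGN_WITHIN.items()}
    prev.update({s: p * malignant_fraction for s, p in _MALIGNANT_WITHIN.items()})
    return prev


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    ``lesions_per_patient_mean`` / ``dispersion`` parameterize a negative
    binomial count (dispersion = NB size r; smaller r = heavier tail),
    zero-truncated so every patient carries at least one lesion.
    ``lesion_size_mm`` maps label -> per-axis (median diameter mm) with a
    shared log-normal sigma per label; malignant lesions are larger and more
    variable. ``contrast`` holds HU offsets relative to cortical bone.
    """

    n_patients: int = 114
    lesions_per_patient_mean: float = 2880.0 / 114.0
    lesions_per_patient_dispersion: float = 0.8
    subcategory_prevalence: dict[str, float] = field(default_factory=default_prevalence)
    malignant_fraction: float = DEFAULT_MALIGNANT_FRACTION
    lesion_size_mm: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {BENIGN: (19.0, 19.0, 9.5), MALIGNANT: (34.0, 34.0, 15.0)}
    )
    lesion_size_sigma: dict[str, float] = field(
        default_factory=lambda: {BENIGN: 0.35, MALIGNANT: 0.45}
    )
    contrast: dict[str, float] = field(
        default_factory=lambda: {"blastic": 300.0, "lytic": -300.0, "benign": 120.0}
    )
    noise_sd: float = 25.0
    volume_shape: tuple[int, int, int] = (128, 128, 32)
    spacing_mm: tuple[float, float, float] = (1.4, 1.4, 1.0)
    soft_tissue_hu: float = 40.0
    bone_hu: float = 700.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ValueError(f"n_patients must be positive, got {self.n_patients}")
        total = sum(self.subcategory_prevalence.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"subcategory_prevalence must sum to 1, got {total}")
        for sub in self.subcategory_prevalence:
            if sub not in SUBCATEGORY_SIDE:
                raise ValueError(f"unknown subcategory {sub!r}")
        for label, dims in self.lesion_size_mm.items():
            if any(d <= 0 for d in dims):
                raise ValueError(f"lesion sizes must be positive, got {dims} for {label}")
        if not (0.0 <= self.malignant_fraction <= 1.0):
            raise ValueError("malignant_fraction must be a probability")
        if self.lesions_per_patient_mean <= 0 or self.lesions_per_patient_dispersion <= 0:
            raise ValueError("lesion count parameters must be positive")


def _sample_count(rng: np.random.Generator, mean: float, r: float) -> int:
    """Zero-truncated negative binomial draw with mean ``mean`` and size ``r``."""
    p = r / (r + mean)
    for _ in range(1000):
        k = int(rng.negative_binomial(r, p))
        if k > 0:
            return k
    return 1


def _sample_subcategory(rng: np.random.Generator, prevalence: dict[str, float], side: str) -> str:
    names = [s for s in prevalence if SUBCATEGORY_SIDE[s] == side]
    probs = np.array([prevalence[s] for s in names], dtype=float)
    if probs.sum() <= 0:
        raise ValueError(f"no prevalence mass on the {side} side")
    return str(rng.choice(names, p=probs / probs.sum()))


def generate_annotations(config: CohortConfig) -> pd.DataFrame:
    """Sample the per-lesion annotation table only (no voxel rendering).

    Columns: patient_id, lesion_id, label, subcategory, mask_label plus the
    sampled per-axis diameters (mm). Deterministic for a fixed config seed,
    and identical to the table produced by :func:`generate_cohort`.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for i in range(config.n_patients):
        pid = f"P{i:03d}"
        n = _sample_count(
            rng, config.lesions_per_patient_mean, config.lesions_per_patient_dispersion
        )
        for k in range(1, n + 1):
            label = MALIGNANT if rng.random() < config.malignant_fraction else BENIGN
            sub = _sample_subcategory(rng, config.subcategory_prevalence, label)
            med = np.array(config.lesion_size_mm[label], dtype=float)
            sigma = config.lesion_size_sigma[label]
            diam = med * np.exp(rng.normal(0.0, sigma, size=3))
            rows.append(
                {
                    "patient_id": pid,
                    "lesion_id": f"{pid}_L{k:03d}",
                    "label": label,
                    "subcategory": sub,
                    "mask_label": k,
                    "dx_mm": float(diam[0]),
                    "dy_mm": float(diam[1]),
                    "dz_mm": float(diam[2]),
                }
            )
    return pd.DataFrame(rows)


def _bone_mask(shape: tuple[int, int, int]) -> tuple[np.ndarray, np.ndarray]:
    """(all-bone mask, midline-bone mask): one midline and two lateral columns."""
    nx, ny, nz = shape
    x = np.arange(nx)[:, None]
    y = np.arange(ny)[None, :]
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    r_mid = 0.18 * min(nx, ny)
    mid2d = (x - cx) ** 2 + (y - cy) ** 2 <= r_mid**2
    r_lat = 0.12 * min(nx, ny)
    lat = np.zeros((nx, ny), dtype=bool)
    for fx in (0.2, 0.8):
        lat |= (x - fx * (nx - 1)) ** 2 + (y - cy) ** 2 <= r_lat**2
    mid = np.repeat(mid2d[:, :, None], nz, axis=2)
    allb = np.repeat((mid2d | lat)[:, :, None], nz, axis=2)
    return allb, mid


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d = sum(((g - c) / max(r, 0.5)) ** 2 for g, c, r in zip(grids, center, radii))
    return d <= 1.0


def _place_lesions(
    rng: np.random.Generator,
    annotations: pd.DataFrame,
    config: CohortConfig,
) -> tuple[np.ndarray, np.ndarray, dict[int, tuple]]:
    """Render one patient's HU volume and integer-labeled lesion mask."""
    shape = tuple(config.volume_shape)
    allb, mid = _bone_mask(shape)
    hu = np.full(shape, config.soft_tissue_hu, dtype=np.float32)
    hu[allb] = config.bone_hu
    labeled = np.zeros(shape, dtype=np.int16)
    bboxes: dict[int, tuple] = {}
    vox = np.asarray(config.spacing_mm, dtype=float)
    all_idx = np.argwhere(allb)
    mid_idx = np.argwhere(mid)
    for row in annotations.itertuples():
        base_radii = np.array([row.dx_mm, row.dy_mm, row.dz_mm]) / 2.0 / vox
        pool = mid_idx if row.label == BENIGN else all_idx
        placed = False
        # rejection-sample a non-overlapping position, shrinking the lesion
        # if the volume is too crowded to host it at full size
        for shrink in (1.0, 0.8, 0.6, 0.4, 0.25, 0.15):
            radii = np.clip(base_radii * shrink, 1.0, (np.array(shape) - 1) / 2.0)
            for _ in range(60):
                center = pool[rng.integers(len(pool))].astype(float)
                center = np.clip(center, radii, np.array(shape) - 1 - radii)
                ell = _ellipsoid(shape, center, radii)
                if not ell.any() or (labeled[ell] != 0).any():
                    continue
                labeled[ell] = row.mask_label
                if row.label == MALIGNANT:
                    if row.subcategory == "osteoblastic":
                        hu[ell] = config.bone_hu + config.contrast["blastic"]
                    elif row.subcategory == "osteolytic":
                        hu[ell] = config.bone_hu + config.contrast["lytic"]
                    else:  # mixed: blastic above the center plane, lytic below
                        zg = np.zeros(shape, dtype=bool)
                        zg[:, :, int(round(center[2])) :] = True
                        hu[ell & zg] = config.bone_hu + config.contrast["blastic"]
                        hu[ell & ~zg] = config.bone_hu + config.contrast["lytic"]
                else:
                    hu[ell] = config.bone_hu + config.contrast["benign"]
                idx = np.argwhere(ell)
                lo, hi = idx.min(axis=0), idx.max(axis=0) + 1
                bboxes[int(row.mask_label)] = tuple((int(a), int(b)) for a, b in zip(lo, hi))
                placed = True
                break
            if placed:
                break
        if not placed:
            raise RuntimeError(
                f"could not place lesion {row.lesion_id}: volume too crowded for "
                f"the configured lesion sizes"
            )
    if config.noise_sd > 0:
        hu += rng.normal(0.0, config.noise_sd, size=shape).astype(np.float32)
    return hu, labeled, bboxes


def generate_cohort(
    config: CohortConfig,
) -> list[tuple[CtVolume, CtVolume, list[LesionRecord]]]:
    """Generate the full cohort: (image, labeled mask, lesion records) per patient.

    Bit-identical for identical seeds. The annotation sampling stream is
    drawn first, so :func:`generate_annotations` with the same config yields
    exactly the table embedded here.
    """
    annotations = generate_annotations(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    out = []
    for i in range(config.n_patients):
        pid = f"P{i:03d}"
        pat = annotations[annotations.patient_id == pid]
        hu, labeled, bboxes = _place_lesions(rng, pat, config)
        vol = CtVolume(hu, config.spacing_mm, pid)
        msk = CtVolume(labeled, config.spacing_mm, pid)
        records = [
            LesionRecord(
                lesion_id=row.lesion_id,
                patient_id=pid,
                label=row.label,
                subcategory=row.subcategory,
                mask_label=int(row.mask_label),
                bbox=bboxes.get(int(row.mask_label)),
            )
            for row in pat.itertuples()
            if int(row.mask_label) in bboxes
        ]
        out.append((vol, msk, records))
    return out


def separable_config(n_patients: int = 6, seed: int = 0, **overrides) -> CohortConfig:
    """A small high-contrast, low-noise cohort for end-to-end toy training.

    All malignant lesions are osteoblastic with a large positive offset and
    benign lesions a mild one, so the classes are linearly separable by mean
    ROI intensity — a threshold on that mean is the oracle baseline that a
    trained network must at least approach.
    """
    prev = {s: 0.0 for s in default_prevalence()}
    for s, p in _BENIGN_WITHIN.items():
        prev[s] = 0.465 * p
    prev["osteoblastic"] = 0.535
    defaults = dict(
        n_patients=n_patients,
        lesions_per_patient_mean=8.0,
        lesions_per_patient_dispersion=20.0,
        subcategory_prevalence=prev,
        malignant_fraction=0.5,
        contrast={"blastic": 450.0, "lytic": -450.0, "benign": 60.0},
        noise_sd=5.0,
        volume_shape=(96, 96, 24),
        seed=seed,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)
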