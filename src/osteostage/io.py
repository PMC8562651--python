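"""NIfTI and cohort serialization.

Volumes are written as ``.nii.gz`` with a diagonal affine carrying the voxel
spacing; labeled masks use int16. The annotation table is a flat CSV with
one row per lesion. Grids are stored in the package's native (x, y, z)
index order, 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import CtVolume, LesionRecord

ANNOTATION_COLUMNS = ["patient_id", "lesion_id", "label", "subcategory", "mask_label"]


def write_nifti(vol: CtVolume, path: Path) -> None:
    affine = np.diag(list(vol.spacing_mm) + [1.0])
    img = nib.Nifti1Image(np.asarray(vol.voxels), affine)
    img.header.set_zooms(vol.spacing_mm)
    nib.save(img, str(path))


def read_nifti(path: Path, patient_id: str = "", quantized: bool = False) -> CtVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CtVolume(data, spacing, patient_id or Path(path).name.split(".")[0], quantized=quantized)


def write_cohort(
    cohort: list[tuple[CtVolume, CtVolume, list[LesionRecord]]],
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Write one image + labeled mask NIfTI per patient plus an annotations CSV.

    Returns (and writes) a manifest listing every path and the seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows, cases = [], []
    for vol, mask, records in cohort:
        img_path = out_dir / f"{vol.patient_id}_image.nii.gz"
        msk_path = out_dir / f"{vol.patient_id}_mask.nii.gz"
        write_nifti(vol, img_path)
        write_nifti(mask.with_voxels(mask.voxels.astype(np.int16)), msk_path)
        cases.append(
            {"patient_id": vol.patient_id, "image": img_path.name, "mask": msk_path.name}
        )
        for r in records:
            rows.append(
                {
                    "patient_id": r.patient_id,
                    "lesion_id": r.lesion_id,
                    "label": r.label,
                    "subcategory": r.subcategory,
                    "mask_label": r.mask_label,
                }
            )
    ann_path = out_dir / "annotations.csv"
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(ann_path, index=False)
    manifest = {
        "seed": seed,
        "n_patients": len(cohort),
        "annotations": ann_path.name,
        "cases": cases,
    }
    with open(out_dir / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=1)
    return manifest


def read_cohort(in_dir: str | Path) -> list[tuple[CtVolume, CtVolume, list[LesionRecord]]]:
    """Inverse of :func:`write_cohort` (voxel data, spacing and annotations)."""
    in_dir = Path(in_dir)
    with open(in_dir / "manifest.json") as f:
        manifest = json.load(f)
    ann = pd.read_csv(in_dir / manifest["annotations"])
    out = []
    for case in manifest["cases"]:
        pid = case["patient_id"]
        vol = read_nifti(in_dir / case["image"], pid)
        mask = read_nifti(in_dir / case["mask"], pid)
        records = [
            LesionRecord(
                lesion_id=str(r.lesion_id),
                patient_id=pid,
                label=str(r.label),
                subcategory=str(r.subcategory),
                mask_label=int(r.mask_label),
            )
            for r in ann[ann.patient_id == pid].itertuples()
        ]
        out.append((vol, mask, records))
    return out
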