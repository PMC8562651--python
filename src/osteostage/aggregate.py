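"""Lesion- and patient-level decision rules over patch/sub-volume scores.

Probability convention: networks emit (p_benign, p_malignant) pairs; all
votes reduce the malignant component. The decision threshold is 0.5 with
ties resolved toward malignant — when sensitivity and specificity trade
off exactly, the clinically costlier miss is the false negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .types import BENIGN, MALIGNANT

#: below this axial extent a lesion counts as "small" for the 2D/3D ensemble
SMALL_LESION_Z_MM = 5.0


@dataclass
class LesionPrediction:
    lesion_id: str
    p_malignant: float
    source: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_malignant <= 1.0):
            raise ValueError(f"p_malignant must be in [0,1], got {self.p_malignant}")

    @property
    def label(self) -> str:
        return MALIGNANT if self.p_malignant >= 0.5 else BENIGN

    @property
    def tied(self) -> bool:
        return self.p_malignant == 0.5


def _p_mal(prob) -> float:
    """Malignant component of a scalar probability or a (benign, malignant) pair."""
    arr = np.atleast_1d(np.asarray(prob, dtype=float))
    return float(arr[-1]) if arr.size == 2 else float(arr[0])


def lesion_average_vote(patch_probs: Sequence, lesion_id: str = "") -> LesionPrediction:
    """Arithmetic mean of per-patch malignant probabilities (permutation-invariant)."""
    if len(patch_probs) == 0:
        raise ValueError("cannot vote over an empty patch list")
    p = float(np.mean([_p_mal(q) for q in patch_probs]))
    return LesionPrediction(lesion_id, p, "avg_vote")


def lesion_majority_vote(slice_labels: Sequence[str]) -> str:
    """Most frequent slice label; an exact tie resolves to malignant."""
    if len(slice_labels) == 0:
        raise ValueError("cannot vote over an empty label list")
    n_mal = sum(1 for s in slice_labels if s == MALIGNANT)
    return MALIGNANT if n_mal * 2 >= len(slice_labels) else BENIGN


def weighted_volume_vote(
    window_probs: Sequence, window_weights: Sequence[float], lesion_id: str = ""
) -> LesionPrediction:
    """Weighted mean of sliding-window scores; marginal windows weigh less."""
    if len(window_probs) != len(window_weights):
        raise ValueError("probs and weights must be equal length")
    w = np.asarray(window_weights, dtype=float)
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    if w.sum() <= 0:
        raise ValueError("weight sum must be positive")
    p = np.array([_p_mal(q) for q in window_probs])
    return LesionPrediction(lesion_id, float((w * p).sum() / w.sum()), "weighted_volume")


def ensemble_policy(
    p2d: float, p3d: float | None, lesion_z_extent_mm: float, lesion_id: str = ""
) -> LesionPrediction:
    """Rule-based 2D/3D fusion by lesion axial extent.

    Small lesions (z extent < 5 mm) mix votes 1:2 in favour of the 3D model,
    whose volumetric context matters most when few slices exist; otherwise
    the 2D model decides alone.
    """
    if lesion_z_extent_mm < 0:
        raise ValueError("z extent must be non-negative")
    if lesion_z_extent_mm < SMALL_LESION_Z_MM:
        if p3d is None:
            raise ValueError("small lesion requires a 3D probability")
        p = (1.0 * _p_mal(p2d) + 2.0 * _p_mal(p3d)) / 3.0
    else:
        p = _p_mal(p2d)
    return LesionPrediction(lesion_id, p, "ensemble")


def patient_rule(lesion_labels: Sequence[str]) -> str:
    """Patient is metastatic iff >= 3 malignant lesions or >= 20% malignant.

    Both boundaries inclusive; monotone in the lesion labels.
    """
    if len(lesion_labels) == 0:
        raise ValueError("patient has no lesion labels")
    n_mal = sum(1 for s in lesion_labels if s == MALIGNANT)
    if n_mal >= 3 or n_mal / len(lesion_labels) >= 0.20:
        return MALIGNANT
    return BENIGN
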