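"""Confusion matrices and accuracy / F1 at slice, lesion and patient level.

Metrics are reported as percentages rounded half-up to one decimal, the
precision used in clinical imaging result tables. Malignant is the positive
class throughout.
"""

from __future__ import annotations

import json
import math
import warnings
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

from .types import BENIGN, LABELS, MALIGNANT, ConfusionMatrix


def _round_half_up(x: float, decimals: int = 1) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1") ** decimals, rounding=ROUND_HALF_UP))


def confusion(
    truth_labels: Sequence[str], predicted_labels: Sequence[str], level: str = "LL"
) -> ConfusionMatrix:
    """Tally a binary confusion matrix from aligned truth/prediction lists."""
    if len(truth_labels) != len(predicted_labels):
        raise ValueError(
            f"length mismatch: {len(truth_labels)} truths vs {len(predicted_labels)} predictions"
        )
    tn = fn = tp = fp = 0
    for t, p in zip(truth_labels, predicted_labels):
        if t not in LABELS or p not in LABELS:
            raise ValueError(f"labels must be in {LABELS}, got ({t!r}, {p!r})")
        if t == MALIGNANT:
            if p == MALIGNANT:
                tp += 1
            else:
                fn += 1
        else:
            if p == BENIGN:
                tn += 1
            else:
                fp += 1
    return ConfusionMatrix(tn=tn, fn=fn, tp=tp, fp=fp, level=level)


def accuracy(cm: ConfusionMatrix) -> float:
    """Percent correct, (TP+TN)/total * 100, rounded half-up to 1 decimal."""
    if cm.total == 0:
        raise ValueError("accuracy undefined on an empty confusion matrix")
    return _round_half_up(100.0 * (cm.tp + cm.tn) / cm.total)


def f1(cm: ConfusionMatrix) -> float:
    """F1 percent with malignant positive: 2TP/(2TP+FP+FN) * 100.

    Returns NaN with a warning when the denominator degenerates (no positive
    truths or predictions at all).
    """
    denom = 2 * cm.tp + cm.fp + cm.fn
    if denom == 0:
        warnings.warn("F1 undefined: no malignant truths or predictions", RuntimeWarning)
        return math.nan
    return _round_half_up(100.0 * 2 * cm.tp / denom)


def evaluate_run(
    truth: dict[str, Sequence[str]],
    predictions: dict[str, Sequence[str]],
    levels: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Per-level metrics table from aligned truth/prediction label lists.

    ``truth`` and ``predictions`` map level codes (SL/LL/PL) to aligned label
    lists; lesion- and patient-level reduction from finer predictions is the
    caller's job (see :mod:`osteostage.aggregate`).
    """
    levels = list(levels) if levels is not None else list(truth)
    rows = []
    for level in levels:
        if level not in truth or level not in predictions:
            raise KeyError(f"missing truth or predictions for level {level!r}")
        cm = confusion(truth[level], predictions[level], level=level)
        rows.append(
            {
                "level": level,
                "tn": cm.tn,
                "fn": cm.fn,
                "tp": cm.tp,
                "fp": cm.fp,
                "accuracy": accuracy(cm),
                "f1": f1(cm),
            }
        )
    return pd.DataFrame(rows)


def load_reference_confusions() -> dict:
    """Curated published confusion-matrix rows with their verified metrics.

    Each entry carries the raw TN/FN/TP/FP counts at one level plus the
    printed accuracy/F1 values that the counts reproduce to 0.1. Printed
    cells that contradict their own counts are excluded; the fixture lists
    those exclusions under ``"excluded"`` for transparency.
    """
    text = resources.files("osteostage.data").joinpath("reference_confusions.json").read_text()
    return json.loads(text)
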