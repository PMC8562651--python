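"""Lesion-aware patient-level train/validation/test stratification.

Patients are partitioned into three splits so that (1) the split is at
patient level, (2) the benign:malignant lesion ratio of each split tracks
the cohort's, (3) every lesion from a very rare subcategory (fewer than a
threshold of lesions cohort-wide) lands in training, and (4) the lesion
subcategory distribution of each split tracks the cohort's. Rules 2 and 4
are soft and combined into an L1 divergence objective minimised by seeded
randomized restarts with greedy swap refinement; rules 1 and 3 are hard
constraints asserted on every output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import BENIGN, MALIGNANT, SUBCATEGORY_SIDE

SPLITS = ("train", "valid", "test")


@dataclass
class PatientSummary:
    """Per-patient lesion counts by subcategory."""

    patient_id: str
    subcategory_counts: dict[str, int]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.subcategory_counts.values()):
            raise ValueError("subcategory counts must be non-negative")

    @property
    def n_lesions(self) -> int:
        return sum(self.subcategory_counts.values())

    def n_side(self, side: str) -> int:
        return sum(
            c for s, c in self.subcategory_counts.items() if SUBCATEGORY_SIDE.get(s, BENIGN) == side
        )


@dataclass
class SplitAssignment:
    """A patient → split mapping plus its objective score and diagnostics."""

    assignment: dict[str, str]
    objective_value: float
    diagnostics: pd.DataFrame = field(default_factory=pd.DataFrame)

    def patients(self, split: str) -> list[str]:
        return [p for p, s in self.assignment.items() if s == split]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"patient_id": list(self.assignment), "split": list(self.assignment.values())}
        )


def summaries_from_annotations(annotations: pd.DataFrame) -> list[PatientSummary]:
    """Build per-patient summaries from an annotation table.

    Expects columns ``patient_id`` and ``subcategory`` (one row per lesion).
    Patients keep their first-appearance order so results are reproducible.
    """
    out = []
    for pid, grp in annotations.groupby("patient_id", sort=False):
        out.append(PatientSummary(str(pid), grp["subcategory"].value_counts().to_dict()))
    return out


def allocate_counts(n_patients: int, ratios: Sequence[float]) -> tuple[int, int, int]:
    """Largest-remainder apportionment of patients over (train, valid, test).

    Floors the quotas then hands remaining seats to the splits with the
    largest fractional parts, ties broken in split order train > valid > test.
    """
    if n_patients < 3:
        raise ValueError(f"need at least 3 patients to fill 3 splits, got {n_patients}")
    ratios = [float(r) for r in ratios]
    if len(ratios) != 3 or any(r <= 0 for r in ratios):
        raise ValueError("ratios must be 3 positive values")
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    quotas = [n_patients * r for r in ratios]
    counts = [math.floor(q) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    for _ in range(n_patients - sum(counts)):
        # max remainder; ties favour the earliest split
        i = max(range(3), key=lambda j: (remainders[j], -j))
        counts[i] += 1
        remainders[i] = -1.0
    return tuple(counts)  # type: ignore[return-value]


def find_rare_subcategories(
    summaries: Iterable[PatientSummary], threshold: int = 20
) -> set[str]:
    """Subcategories with strictly fewer than ``threshold`` lesions cohort-wide."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    totals: dict[str, int] = {}
    for s in summaries:
        for sub, c in s.subcategory_counts.items():
            totals[sub] = totals.get(sub, 0) + c
    return {sub for sub, c in totals.items() if c < threshold}


def split_objective(
    assignment: Mapping[str, str],
    summaries: Sequence[PatientSummary],
    class_balance_weight: float = 1.0,
) -> float:
    """L1 divergence of per-split subcategory and class proportions from the cohort.

    ``+inf`` when any split holds no lesions, which rejects degenerate
    partitions outright.
    """
    by_id = {s.patient_id: s for s in summaries}
    subcats = sorted({sub for s in summaries for sub in s.subcategory_counts})
    cohort = {sub: 0 for sub in subcats}
    split_counts = {sp: {sub: 0 for sub in subcats} for sp in SPLITS}
    for pid, sp in assignment.items():
        if sp not in SPLITS:
            raise ValueError(f"unknown split {sp!r}")
        for sub, c in by_id[pid].subcategory_counts.items():
            split_counts[sp][sub] += c
            cohort[sub] += c
    total = sum(cohort.values())
    if total == 0:
        raise ValueError("no lesions in cohort")
    score = 0.0
    cohort_mal = sum(c for sub, c in cohort.items() if SUBCATEGORY_SIDE.get(sub) == MALIGNANT)
    for sp in SPLITS:
        sp_total = sum(split_counts[sp].values())
        if sp_total == 0:
            return math.inf
        for sub in subcats:
            score += abs(split_counts[sp][sub] / sp_total - cohort[sub] / total)
        sp_mal = sum(
            c for sub, c in split_counts[sp].items() if SUBCATEGORY_SIDE.get(sub) == MALIGNANT
        )
        score += class_balance_weight * abs(sp_mal / sp_total - cohort_mal / total)
    return score


def _diagnostics(assignment: Mapping[str, str], summaries: Sequence[PatientSummary]) -> pd.DataFrame:
    by_id = {s.patient_id: s for s in summaries}
    subcats = sorted({sub for s in summaries for sub in s.subcategory_counts})
    rows = []
    for sp in SPLITS:
        counts = {sub: 0 for sub in subcats}
        for pid, s in assignment.items():
            if s == sp:
                for sub, c in by_id[pid].subcategory_counts.items():
                    counts[sub] += c
        tot = sum(counts.values())
        row = {"split": sp, "n_lesions": tot}
        row.update({sub: (counts[sub] / tot if tot else 0.0) for sub in subcats})
        rows.append(row)
    return pd.DataFrame(rows)


def assign_splits(
    summaries: Sequence[PatientSummary],
    ratios: Sequence[float] = (0.75, 0.12, 0.13),
    rare_threshold: int = 20,
    seed: int = 0,
    n_restarts: int = 50,
    n_swap_rounds: int = 200,
    class_balance_weight: float = 1.0,
) -> SplitAssignment:
    """Search for the lowest-objective valid patient partition.

    Patients owning any rare-subcategory lesion are pinned to train; the
    remainder are shuffled into the apportioned counts ``n_restarts`` times,
    each restart refined by greedy cross-split patient swaps, and the best
    assignment found is returned. Deterministic for a fixed seed.
    """
    counts = allocate_counts(len(summaries), ratios)
    rare = find_rare_subcategories(summaries, rare_threshold)
    pinned = [
        s.patient_id for s in summaries if any(sub in rare for sub in s.subcategory_counts)
    ]
    free = [s.patient_id for s in summaries if s.patient_id not in set(pinned)]
    if len(pinned) > counts[0]:
        raise ValueError(
            f"{len(pinned)} patients own rare-subcategory lesions but train holds only "
            f"{counts[0]} patients: infeasible"
        )
    n_free_train = counts[0] - len(pinned)
    rng = np.random.default_rng(seed)

    def build(order: list[str]) -> dict[str, str]:
        a = {p: "train" for p in pinned}
        a.update({p: "train" for p in order[:n_free_train]})
        a.update({p: "valid" for p in order[n_free_train : n_free_train + counts[1]]})
        a.update({p: "test" for p in order[n_free_train + counts[1] :]})
        return a

    best: Optional[dict[str, str]] = None
    best_score = math.inf
    for _ in range(max(1, n_restarts)):
        order = list(free)
        rng.shuffle(order)
        a = build(order)
        score = split_objective(a, summaries, class_balance_weight)
        # greedy swap refinement over free patients only
        improved = True
        rounds = 0
        while improved and rounds < n_swap_rounds:
            improved = False
            rounds += 1
            for i in range(len(free)):
                for j in range(i + 1, len(free)):
                    pi, pj = free[i], free[j]
                    if a[pi] == a[pj]:
                        continue
                    a[pi], a[pj] = a[pj], a[pi]
                    s2 = split_objective(a, summaries, class_balance_weight)
                    if s2 < score - 1e-12:
                        score = s2
                        improved = True
                    else:
                        a[pi], a[pj] = a[pj], a[pi]
        if score < best_score:
            best_score, best = score, dict(a)
    assert best is not None
    # order mapping by input patient order for stable serialization
    ordered = {s.patient_id: best[s.patient_id] for s in summaries}
    return SplitAssignment(ordered, best_score, _diagnostics(ordered, summaries))
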