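"""End-to-end orchestration: simulate -> preprocess -> split -> extract ->
train -> predict -> aggregate -> evaluate.

Each stage is a pure function of (inputs, config, seed); a run directory
collects the split table, predictions, metrics and a manifest tying them
together. Configs are plain nested dicts (YAML on disk) with one section
per stage. An optional ensemble section trains a second (3D) branch on the
same split and fuses per-lesion probabilities with the z-extent policy.
"""

from __future__ import annotations

import json
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import aggregate as agg
from . import evaluate as ev
from .augment import AugmentConfig, augment_sample
from .extract import (
    STRATEGIES,
    extract_lesion_volume,
    extract_patch,
    lesion_slices,
    mask_bbox,
    sliding_subvolumes,
)
from .model_zoo import ArchSpec, TrainConfig, batch_inputs, build_model, predict_batch, train
from .preprocess import WindowSpec, preprocess_case, window_and_quantize
from .stratify import assign_splits, summaries_from_annotations
from .synthetic import CohortConfig, generate_cohort, separable_config
from .types import BENIGN, MALIGNANT, Sample

DEFAULT_CONFIG: dict = {
    "cohort": {"preset": "separable", "n_patients": 6, "seed": 0},
    "preprocess": {
        "enabled": False,  # synthetic phantoms are already on a uniform grid
        "target_spacing": [0.7, 0.7, 1.0],
        "target_shape": [714, 714, 39],
        "window": {"level_hu": 400.0, "width_hu": 1800.0},
    },
    # rare_threshold 0 at toy scale: with a few dozen lesions every
    # subcategory would otherwise count as rare and pin all patients to train
    "split": {"ratios": [0.75, 0.12, 0.13], "rare_threshold": 0, "seed": 0, "n_restarts": 8},
    "extract": {"strategy": "C", "fixed_canvas_px": None, "target_hw": 32},
    "augment": {"enabled": False},
    "train": {
        "arch": "resnet50_2d",
        "width_mult": 0.125,
        "lr0": 1e-2,
        "lr_drop_factor": 0.8,
        "lr_drop_every_epochs": 7,
        "weight_decay": 2e-4,
        "max_epochs": 2,
        "batch_size": 16,
        "seed": 0,
    },
    "ensemble": {
        "enabled": False,
        "extract": {"strategy": "I", "fixed_canvas_px": 33, "target_hw": None},
        "train": {
            "arch": "resnet18_3d",
            "width_mult": 0.125,
            "lr0": 1e-2,
            "lr_drop_factor": 0.85,
            "lr_drop_every_epochs": 5,
            "weight_decay": 2e-4,
            "max_epochs": 2,
            "batch_size": 4,
            "seed": 0,
        },
    },
    "evaluate": {"aggregation": "average"},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: Optional[str | Path] = None, overrides: Optional[dict] = None) -> dict:
    cfg = DEFAULT_CONFIG
    if path is not None:
        with open(path) as f:
            cfg = _merge(cfg, yaml.safe_load(f) or {})
    if overrides:
        cfg = _merge(cfg, overrides)
    for section in ("extract", ("ensemble", "extract")):
        sub = cfg[section] if isinstance(section, str) else cfg[section[0]][section[1]]
        if sub["strategy"] not in STRATEGIES:
            name = section if isinstance(section, str) else ".".join(section)
            raise ValueError(f"{name}.strategy: unknown strategy id {sub['strategy']!r}")
    return cfg


def _build_cohort(ccfg: dict):
    kw = {k: v for k, v in ccfg.items() if k != "preset"}
    if ccfg.get("preset") == "separable":
        return generate_cohort(separable_config(**kw))
    if "volume_shape" in kw:
        kw["volume_shape"] = tuple(kw["volume_shape"])
    return generate_cohort(CohortConfig(**kw))


def _extract_for_lesion(volume, mask3d, lesion, strategy, fixed_px) -> list[Sample]:
    sdef = STRATEGIES[strategy]
    if strategy == "K":
        return sliding_subvolumes(volume, mask3d, lesion, fixed_canvas_px=fixed_px)
    if sdef.dimensionality == "3D":
        return [extract_lesion_volume(volume, mask3d, lesion, sdef, fixed_canvas_px=fixed_px)]
    return [
        extract_patch(volume, mask3d, lesion, z, sdef, fixed_canvas_px=fixed_px)
        for z in lesion_slices(mask3d)
    ]


def _extract_split_samples(cohort, assignment, ecfg) -> dict[str, list[tuple[Sample, str]]]:
    per_split: dict[str, list[tuple[Sample, str]]] = {"train": [], "valid": [], "test": []}
    for vol, mask, recs in cohort:
        sp = assignment.assignment[vol.patient_id]
        for r in recs:
            m3 = np.asarray(mask.voxels) == r.mask_label
            if not m3.any():
                continue
            for s in _extract_for_lesion(vol, m3, r, ecfg["strategy"], ecfg["fixed_canvas_px"]):
                per_split[sp].append((s, r.label))
    return per_split


def _train_branch(per_split, ecfg, tcfg_d, augment_cfg=None):
    """Train one classifier branch; returns (model, history, test probs)."""
    if augment_cfg is not None:
        rng = np.random.default_rng(augment_cfg.seed)
        per_split = dict(per_split)
        per_split["train"] = [
            (augment_sample(s, augment_cfg, rng), lab) for s, lab in per_split["train"]
        ]
    arch = ArchSpec(tcfg_d["arch"], width_mult=tcfg_d["width_mult"], seed=tcfg_d["seed"])
    model = build_model(arch)
    tcfg = TrainConfig(
        lr0=tcfg_d["lr0"],
        lr_drop_factor=tcfg_d["lr_drop_factor"],
        lr_drop_every_epochs=tcfg_d["lr_drop_every_epochs"],
        weight_decay=tcfg_d["weight_decay"],
        max_epochs=tcfg_d["max_epochs"],
        batch_size=tcfg_d["batch_size"],
        seed=tcfg_d["seed"],
    )
    hw = ecfg["target_hw"]
    tx = batch_inputs([s for s, _ in per_split["train"]], hw)
    ty = [lab for _, lab in per_split["train"]]
    vx = batch_inputs([s for s, _ in per_split["valid"]], hw) if per_split["valid"] else None
    vy = [lab for _, lab in per_split["valid"]] if per_split["valid"] else None
    tw = np.array([s.weight for s, _ in per_split["train"]])
    history = train(model, tx, ty, vx, vy, tcfg, sample_weight=tw)
    test = per_split["test"]
    probs = (
        predict_batch(model, batch_inputs([s for s, _ in test], hw))
        if test
        else np.zeros((0, 2))
    )
    return model, history, probs


def _lesion_probs(test, probs, strategy, aggregation) -> dict[str, agg.LesionPrediction]:
    by_lesion: dict[str, list[tuple[Sample, float]]] = {}
    for (s, _), p in zip(test, probs):
        by_lesion.setdefault(s.lesion_id, []).append((s, float(p[1])))
    out = {}
    for lid, items in by_lesion.items():
        if strategy == "K":
            out[lid] = agg.weighted_volume_vote(
                [p for _, p in items], [s.weight for s, _ in items], lid
            )
        elif aggregation == "majority":
            lab = agg.lesion_majority_vote(
                [MALIGNANT if p >= 0.5 else BENIGN for _, p in items]
            )
            out[lid] = agg.LesionPrediction(lid, 1.0 if lab == MALIGNANT else 0.0, "majority_vote")
        else:
            out[lid] = agg.lesion_average_vote([p for _, p in items], lid)
    return out


def run_pipeline(
    config: dict | str | Path | None = None, out_dir: str | Path = "runs/latest"
) -> dict:
    """Execute the full pipeline per config; returns the run manifest."""
    cfg = config if isinstance(config, dict) else load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": cfg, "started": time.time(), "stages": {}}

    def stage(name):
        manifest["stages"][name] = {"t": time.time()}

    try:
        stage("simulate")
        cohort = _build_cohort(cfg["cohort"])

        stage("preprocess")
        pcfg = cfg["preprocess"]
        win = WindowSpec(**pcfg["window"])
        if pcfg.get("enabled"):
            cohort = [
                (*preprocess_case(v, m, tuple(pcfg["target_spacing"]),
                                  tuple(pcfg["target_shape"]), win), r)
                for v, m, r in cohort
            ]
        else:  # phantoms are generated on a uniform grid; quantize in place
            cohort = [(window_and_quantize(v, win), m, r) for v, m, r in cohort]

        stage("split")
        ann = pd.DataFrame(
            [
                {"patient_id": r.patient_id, "lesion_id": r.lesion_id,
                 "label": r.label, "subcategory": r.subcategory}
                for _, _, recs in cohort
                for r in recs
            ]
        )
        scfg = cfg["split"]
        assignment = assign_splits(
            summaries_from_annotations(ann),
            ratios=scfg["ratios"],
            rare_threshold=scfg["rare_threshold"],
            seed=scfg["seed"],
            n_restarts=scfg["n_restarts"],
        )
        assignment.to_frame().to_csv(out / "split.csv", index=False)
        manifest["split_objective"] = assignment.objective_value

        stage("extract")
        lesion_meta: dict[str, dict] = {}
        for vol, mask, recs in cohort:
            sp = assignment.assignment[vol.patient_id]
            for r in recs:
                m3 = np.asarray(mask.voxels) == r.mask_label
                if not m3.any():
                    continue
                (_, _), (_, _), (z0, z1) = mask_bbox(m3)
                lesion_meta[r.lesion_id] = {
                    "patient_id": r.patient_id,
                    "label": r.label,
                    "z_extent_mm": (z1 - z0) * vol.spacing_mm[2],
                    "split": sp,
                }
        per_split = _extract_split_samples(cohort, assignment, cfg["extract"])

        stage("augment")
        aug_cfg = None
        if cfg["augment"].get("enabled"):
            aug_cfg = AugmentConfig(
                **{k: v for k, v in cfg["augment"].items() if k != "enabled"}
            )

        stage("train")
        _, history, probs = _train_branch(per_split, cfg["extract"], cfg["train"], aug_cfg)
        manifest["history"] = {
            "train_loss": history.train_loss,
            "valid_loss": history.valid_loss,
            "lr": history.lr,
        }

        stage("predict")
        test = per_split["test"]

        stage("aggregate")
        lesion_preds = _lesion_probs(
            test, probs, cfg["extract"]["strategy"], cfg["evaluate"]["aggregation"]
        )
        if cfg["ensemble"]["enabled"]:
            ens = cfg["ensemble"]
            per_split_3d = _extract_split_samples(cohort, assignment, ens["extract"])
            _, hist3d, probs3d = _train_branch(per_split_3d, ens["extract"], ens["train"])
            manifest["history_3d"] = {
                "train_loss": hist3d.train_loss,
                "valid_loss": hist3d.valid_loss,
            }
            preds3d = _lesion_probs(per_split_3d["test"], probs3d, ens["extract"]["strategy"],
                                    cfg["evaluate"]["aggregation"])
            lesion_preds = {
                lid: agg.ensemble_policy(
                    p.p_malignant,
                    preds3d[lid].p_malignant if lid in preds3d else None,
                    lesion_meta[lid]["z_extent_mm"],
                    lid,
                )
                for lid, p in lesion_preds.items()
            }
        rows = [
            {
                "lesion_id": lid,
                "patient_id": lesion_meta[lid]["patient_id"],
                "p_malignant": p.p_malignant,
                "label": p.label,
                "source": p.source,
            }
            for lid, p in lesion_preds.items()
        ]
        pd.DataFrame(rows).to_csv(out / "lesion_predictions.csv", index=False)

        stage("evaluate")
        truth, preds = {}, {}
        truth["SL"] = [lesion_meta[s.lesion_id]["label"] for s, _ in test]
        preds["SL"] = [MALIGNANT if p[1] >= 0.5 else BENIGN for p in probs]
        truth["LL"] = [lesion_meta[r["lesion_id"]]["label"] for r in rows]
        preds["LL"] = [r["label"] for r in rows]
        pat_truth, pat_pred = {}, {}
        for r in rows:
            pid = r["patient_id"]
            pat_pred.setdefault(pid, []).append(r["label"])
            pat_truth.setdefault(pid, []).append(lesion_meta[r["lesion_id"]]["label"])
        pids = sorted(pat_pred)
        truth["PL"] = [agg.patient_rule(pat_truth[p]) for p in pids]
        preds["PL"] = [agg.patient_rule(pat_pred[p]) for p in pids]
        metrics = ev.evaluate_run(truth, preds, ["SL", "LL", "PL"])
        metrics.to_csv(out / "metrics.csv", index=False)
        manifest["metrics"] = metrics.to_dict(orient="records")
        manifest["finished"] = time.time()
        with open(out / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=1, default=float)
        return manifest
    except Exception as e:  # annotate which stage failed, keep partial outputs
        failed = list(manifest["stages"])[-1] if manifest["stages"] else "config"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {e}") from e
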