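"""Configuration-driven orchestration of the full workflow.

Stages (``synth`` → ``split`` → ``augment`` → ``train-backbone`` →
``extract`` → ``fuse`` → ``train-svm`` → ``evaluate``) read and write plain
artifacts under a run directory.  Every stage writes a manifest recording
its seed and a hash of the configuration slice it depends on; stages that
combine artifacts (``fuse``) refuse inputs whose split provenance differs.
The stage DAG is enforced explicitly: a stage whose prerequisite artifact is
missing raises a :class:`~beakfusion.errors.StageOrderError` naming it.

Artifacts
---------
``images/``                     synthetic dataset in class/view layout
``ground_truth.csv``            generator parameters per class
``split.json``                  train/val/test source ids
``augmented/`` + index          augmented copies of *training* images only
``backbone.npz`` + history      trained backbone weights and loss curves
``features_<kind>.csv``         one row per image: id, label, view, split, v0...
``model_<kind>.joblib(.json)``  fitted SVM with metadata
``metrics_<kind>.csv`` etc.     confusion matrices and metric tables
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from beakfusion.augmentation import AugmentSpec, sample_augmentations
from beakfusion.deep_backbone import (
    BackboneConfig,
    build_backbone,
    extract_deep,
    resize_for_backbone,
    train_backbone,
)
from beakfusion.errors import ConfigError, ProvenanceError, StageOrderError
from beakfusion.evaluation import confusion, metrics
from beakfusion.fusion_classify import SVMConfig, TrainedClassifier, fit_classifier, predict
from beakfusion.hog import HOGConfig, hog_descriptor
from beakfusion.io_dataset import DatasetSplit, LabeledImage, load_dataset, split_dataset, to_gray_resized
from beakfusion.lbp import LBPConfig, lbp_descriptor
from beakfusion.synthetic_beaks import SynthConfig, describe_ground_truth, generate_dataset, write_dataset

logger = logging.getLogger(__name__)

SHALLOW_SIDES = {"lbp": 512, "hog": 256}  # canonical descriptor input sizes


class PipelineConfig:
    """Validated pipeline configuration loaded from a YAML/JSON document."""

    def __init__(self, raw: dict[str, Any], base_dir: Path | None = None):
        if not isinstance(raw, dict):
            raise ConfigError("pipeline config must be a mapping")
        self.raw = raw
        base = Path(base_dir) if base_dir else Path.cwd()
        self.out_dir = (base / raw.get("out_dir", "run")).resolve()
        self.seed = int(raw.get("seed", 0))
        dataset = raw.get("dataset", {})
        self.dataset_root = Path(dataset.get("root", self.out_dir / "images"))
        if not self.dataset_root.is_absolute():
            self.dataset_root = base / self.dataset_root
        synth = dict(raw.get("synth", {}))
        synth.setdefault("seed", self.seed)
        if "views" in synth:
            synth["views"] = tuple(synth["views"])
        if "classes" in synth:
            synth["classes"] = tuple(synth["classes"])
        self.synth = SynthConfig(**synth)
        split = raw.get("split", {})
        self.test_frac = float(split.get("test_frac", 0.2))
        self.val_frac_of_rest = float(split.get("val_frac_of_rest", 0.2))
        aug = dict(raw.get("augment", {}))
        aug.setdefault("seed", self.seed)
        for key in ("rotation_range_deg", "crop_frac_range", "aspect_range"):
            if key in aug:
                aug[key] = tuple(aug[key])
        self.augment = AugmentSpec(**aug)
        lbp = dict(raw.get("lbp", {}))
        self.lbp_side = int(lbp.pop("side", SHALLOW_SIDES["lbp"]))
        self.lbp = LBPConfig(**lbp)
        hog = dict(raw.get("hog", {}))
        self.hog_side = int(hog.pop("side", SHALLOW_SIDES["hog"]))
        self.hog = HOGConfig(**hog)
        backbone = dict(raw.get("backbone", {}))
        backbone.setdefault("seed", self.seed)
        backbone.setdefault("n_classes", len(self.synth.classes))
        if "lr_schedule" in backbone:
            backbone["lr_schedule"] = [
                ((int(lo), int(hi)), float(r)) for (lo, hi), r in backbone["lr_schedule"]
            ]
        self.backbone = BackboneConfig(**backbone)
        self.svm = SVMConfig(**raw.get("svm", {}))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        return cls(raw, base_dir=path.parent)

    def stage_hash(self, *sections: str) -> str:
        """Stable hash of the named config sections plus the seed."""
        payload = {"seed": self.seed}
        for s in sections:
            payload[s] = self.raw.get(s, {})
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_manifest(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def _read_manifest(path: Path, stage: str) -> dict:
    if not path.exists():
        raise StageOrderError(f"missing artifact {path.name}; run the {stage!r} stage first")
    return json.loads(path.read_text())


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise StageOrderError(f"missing artifact {path}; run the {producer!r} stage first")
    return path


def stage_synth(cfg: PipelineConfig) -> None:
    images = generate_dataset(cfg.synth)
    write_dataset(images, cfg.dataset_root)
    describe_ground_truth(cfg.synth).to_csv(cfg.out_dir / "ground_truth.csv", index=False)
    _write_manifest(
        cfg.out_dir / "synth.manifest.json",
        {"stage": "synth", "seed": cfg.synth.seed, "config_hash": cfg.stage_hash("synth"),
         "n_images": len(images)},
    )
    logger.info("synth: wrote %d images under %s", len(images), cfg.dataset_root)


def stage_split(cfg: PipelineConfig) -> None:
    images = load_dataset(_require(cfg.dataset_root, "synth"))
    ids_by_class: dict[str, list[str]] = {}
    for im in images:
        ids_by_class.setdefault(im.label, []).append(im.source_id)
    split = split_dataset(ids_by_class, cfg.test_frac, cfg.val_frac_of_rest, cfg.seed)
    split.to_json(cfg.out_dir / "split.json")
    _write_manifest(
        cfg.out_dir / "split.manifest.json",
        {"stage": "split", "seed": cfg.seed, "config_hash": cfg.stage_hash("split"),
         "counts": {"train": len(split.train_ids), "val": len(split.val_ids),
                    "test": len(split.test_ids)}},
    )
    logger.info("split: %d train / %d val / %d test",
                len(split.train_ids), len(split.val_ids), len(split.test_ids))


def stage_augment(cfg: PipelineConfig) -> None:
    split = DatasetSplit.from_json(_require(cfg.out_dir / "split.json", "split"))
    images = {im.source_id: im for im in load_dataset(cfg.dataset_root)}
    aug_root = cfg.out_dir / "augmented"
    produced = []
    for j, sid in enumerate(sorted(split.train_ids)):  # training images only
        spec = AugmentSpec(**{**_spec_dict(cfg.augment), "seed": cfg.augment.seed * 100_003 + j})
        for aug in sample_augmentations(images[sid], spec):
            produced.append(aug)
    write_dataset(
        [LabeledImage(a.pixels, a.label, a.view, a.source_id.replace("#", "_")) for a in produced],
        aug_root,
    )
    index = sorted(f"{a.label}/{a.view}/" + a.source_id.replace("#", "_").split("/")[-1]
                   for a in produced)
    (cfg.out_dir / "augmented_ids.json").write_text(json.dumps(index, indent=1))
    _write_manifest(
        cfg.out_dir / "augment.manifest.json",
        {"stage": "augment", "seed": cfg.augment.seed, "config_hash": cfg.stage_hash("augment"),
         "n_augmented": len(produced), "train_only": True},
    )
    logger.info("augment: %d augmented training images", len(produced))


def _spec_dict(spec: AugmentSpec) -> dict:
    return asdict(spec)


def _load_split(cfg: PipelineConfig) -> DatasetSplit:
    return DatasetSplit.from_json(_require(cfg.out_dir / "split.json", "split"))


def _augmented_images(cfg: PipelineConfig) -> list[LabeledImage]:
    aug_root = cfg.out_dir / "augmented"
    if not aug_root.exists():
        return []
    out = []
    for im in load_dataset(aug_root):
        im.source_id = "aug/" + im.source_id
        out.append(im)
    return out


def stage_train_backbone(cfg: PipelineConfig) -> None:
    split = _load_split(cfg)
    images = {im.source_id: im for im in load_dataset(cfg.dataset_root)}
    backbone = build_backbone(cfg.backbone)
    train_imgs = [images[i] for i in sorted(split.train_ids)]
    train_imgs += _augmented_images(cfg)  # empty when augment was not run
    val_imgs = [images[i] for i in sorted(split.val_ids)]
    trained = train_backbone(
        backbone,
        resize_for_backbone(train_imgs, backbone),
        resize_for_backbone(val_imgs, backbone),
    )
    backbone.save(cfg.out_dir / "backbone.npz")
    trained.history.to_csv(cfg.out_dir / "loss_history.csv", index=False)
    _write_manifest(
        cfg.out_dir / "backbone.manifest.json",
        {"stage": "train-backbone", "seed": cfg.backbone.seed,
         "config_hash": cfg.stage_hash("backbone"),
         "split_hash": _read_manifest(cfg.out_dir / "split.manifest.json", "split")["config_hash"],
         "profile": cfg.backbone.profile, "feature_dim": backbone.feature_dim,
         "best_val_loss": float(trained.history["val_loss"].min())},
    )
    logger.info("train-backbone: best val loss %.4f", trained.history["val_loss"].min())


def stage_extract(cfg: PipelineConfig, kind: str) -> None:
    if kind not in ("lbp", "hog", "deep"):
        raise ConfigError(f"unknown feature kind {kind!r}")
    split = _load_split(cfg)
    images = load_dataset(cfg.dataset_root)
    rows = []
    if kind == "deep":
        backbone = build_backbone(cfg.backbone)
        backbone.load(_require(cfg.out_dir / "backbone.npz", "train-backbone"))
        feats = extract_deep(backbone, resize_for_backbone(images, backbone))
        vectors = {f.source_id: f.values for f in feats}
        config_hash = cfg.stage_hash("backbone")
    else:
        side = cfg.lbp_side if kind == "lbp" else cfg.hog_side
        desc = (lambda g: lbp_descriptor(g, cfg.lbp)) if kind == "lbp" else (
            lambda g: hog_descriptor(g, cfg.hog))
        vectors = {im.source_id: desc(to_gray_resized(im, side)) for im in images}
        config_hash = cfg.stage_hash(kind)
    of = {i: "train" for i in split.train_ids}
    of.update({i: "val" for i in split.val_ids})
    of.update({i: "test" for i in split.test_ids})
    for im in images:
        v = vectors[im.source_id]
        rows.append({"source_id": im.source_id, "label": im.label, "view": im.view,
                     "split": of[im.source_id],
                     **{f"v{k}": x for k, x in enumerate(v)}})
    table = pd.DataFrame(rows).sort_values("source_id").reset_index(drop=True)
    table.to_csv(cfg.out_dir / f"features_{kind}.csv", index=False)
    _write_manifest(
        cfg.out_dir / f"features_{kind}.manifest.json",
        {"stage": "extract", "kind": kind, "seed": cfg.seed, "config_hash": config_hash,
         "split_hash": _read_manifest(cfg.out_dir / "split.manifest.json", "split")["config_hash"],
         "dim": len(next(iter(vectors.values()))), "n_rows": len(table)},
    )
    logger.info("extract %s: %d rows x %d dims", kind, len(table),
                len(next(iter(vectors.values()))))


def stage_fuse(cfg: PipelineConfig, part_a: str = "hog", part_b: str = "deep") -> None:
    name = f"{part_a}+{part_b}"
    tables, hashes = [], []
    for part in (part_a, part_b):
        man = _read_manifest(cfg.out_dir / f"features_{part}.manifest.json", f"extract {part}")
        hashes.append(man["split_hash"])
        tables.append(pd.read_csv(cfg.out_dir / f"features_{part}.csv"))
    if hashes[0] != hashes[1]:
        raise ProvenanceError(
            f"cannot fuse {part_a} and {part_b}: feature tables come from different splits"
        )
    a, b = tables
    meta_cols = ["source_id", "label", "view", "split"]
    bv = b.drop(columns=["label", "view", "split"])
    merged = a.merge(bv, on="source_id", suffixes=("_a", "_b"))
    if len(merged) != len(a) or len(merged) != len(b):
        raise ProvenanceError(f"{part_a} and {part_b} tables cover different images")
    value_cols = [c for c in merged.columns if c not in meta_cols]
    renamed = {c: f"v{k}" for k, c in enumerate(value_cols)}
    merged = merged[meta_cols + value_cols].rename(columns=renamed)
    merged.to_csv(cfg.out_dir / f"features_{name}.csv", index=False)
    _write_manifest(
        cfg.out_dir / f"features_{name}.manifest.json",
        {"stage": "fuse", "kind": name, "seed": cfg.seed, "split_hash": hashes[0],
         "config_hash": hashlib.sha256("|".join(sorted(hashes)).encode()).hexdigest()[:16],
         "dim": len(value_cols), "n_rows": len(merged)},
    )
    logger.info("fuse: %s -> %d dims", name, len(value_cols))


def _feature_table(cfg: PipelineConfig, kind: str) -> pd.DataFrame:
    return pd.read_csv(_require(cfg.out_dir / f"features_{kind}.csv", f"extract/fuse {kind}"))


def stage_train_svm(cfg: PipelineConfig, kind: str) -> None:
    table = _feature_table(cfg, kind)
    fit = table[table["split"].isin(["train", "val"])]  # test held out
    vcols = [c for c in table.columns if re.fullmatch(r"v\d+", c)]
    clf = fit_classifier(fit[vcols].to_numpy(), fit["label"].tolist(), cfg.svm, seed=cfg.seed)
    clf.tag = "fused" if "+" in kind else kind
    clf.save(cfg.out_dir / f"model_{kind}.joblib")
    logger.info("train-svm %s: %d fit rows, %d machines", kind, len(fit), clf.n_machines)


def stage_evaluate(cfg: PipelineConfig, kind: str) -> dict[str, float]:
    table = _feature_table(cfg, kind)
    clf = TrainedClassifier.load(_require(cfg.out_dir / f"model_{kind}.joblib", "train-svm"))
    test = table[table["split"] == "test"]
    vcols = [c for c in table.columns if re.fullmatch(r"v\d+", c)]
    class_order = sorted(test["label"].unique())
    frames, report_parts, out = [], [], {}
    views = ["all"] + sorted(v for v in test["view"].unique() if len(test["view"].unique()) > 1)
    for view in views:
        part = test if view == "all" else test[test["view"] == view]
        pred = predict(clf, part[vcols].to_numpy())
        cm = confusion(part["label"].tolist(), pred, class_order)
        rep = metrics(cm)
        frame = rep.to_frame()
        frame.insert(0, "view", view)
        frames.append(frame)
        report_parts.append(f"== view: {view} ==\n{rep.to_text()}")
        out[view] = rep.aggregate.accuracy
        if view == "all":
            cm.to_frame().to_csv(cfg.out_dir / f"confusion_{kind}.csv")
    pd.concat(frames).to_csv(cfg.out_dir / f"metrics_{kind}.csv", index=False)
    (cfg.out_dir / f"report_{kind}.txt").write_text("\n\n".join(report_parts) + "\n")
    logger.info("evaluate %s: test accuracy %.4f", kind, out["all"])
    return out


STAGES = {
    "synth": stage_synth,
    "split": stage_split,
    "augment": stage_augment,
    "train-backbone": stage_train_backbone,
}


def run_stage(stage: str, cfg: PipelineConfig, **kwargs):
    """Run one named stage; see the module docstring for the DAG."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    if stage in STAGES:
        return STAGES[stage](cfg)
    if stage == "extract":
        return stage_extract(cfg, kwargs["kind"])
    if stage == "fuse":
        return stage_fuse(cfg, kwargs.get("part_a", "hog"), kwargs.get("part_b", "deep"))
    if stage == "train-svm":
        return stage_train_svm(cfg, kwargs["kind"])
    if stage == "evaluate":
        return stage_evaluate(cfg, kwargs["kind"])
    raise ConfigError(f"unknown stage {stage!r}")
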