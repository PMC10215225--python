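"""End-to-end experiment orchestration behind the command-line interface.

A YAML/dict config drives the full stage order: phantom generation →
patch extraction → patch-classifier training (one per patch size) →
whole-image extension and training → multi-patch-size fusion →
evaluation table. Stages write into separate subdirectories of the output
root, are stamped with the config hash and the global seed, and are
skipped on re-runs when their `_done` marker exists (idempotent resume).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import models, training
from .data_model import CANCER, read_annotated_image, read_manifest
from .evaluation import summarize_runs
from .patch_extraction import ExtractionConfig, build_patch_dataset
from .phantom import PhantomConfig, generate_dataset

log = logging.getLogger("mammoscale")

_REQUIRED_SECTIONS = ("phantom", "extraction", "model", "training", "evaluation")


class ConfigError(ValueError):
    pass


def validate_config(config: dict) -> dict:
    """Schema-check an experiment config before any stage runs."""
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    missing = [s for s in _REQUIRED_SECTIONS if s not in config]
    if missing:
        raise ConfigError(f"config missing sections: {missing}")
    for s in _REQUIRED_SECTIONS:
        if not isinstance(config[s], dict):
            raise ConfigError(f"config section {s!r} must be a mapping")
    ph = config["phantom"]
    for key in ("image_height_px", "image_width_px", "n_images", "class_mix"):
        if key not in ph:
            raise ConfigError(f"phantom section missing {key!r}")
    if "patch_sizes_px" not in config["extraction"]:
        raise ConfigError("extraction section missing 'patch_sizes_px'")
    if "backbone" not in config["model"]:
        raise ConfigError("model section missing 'backbone'")
    config.setdefault("seed", 0)
    config.setdefault("output_root", "runs/experiment")
    return config


def config_hash(config: dict) -> str:
    return hashlib.sha1(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _stage_dir(root: Path, name: str) -> Path:
    d = root / name
    d.mkdir(parents=True, exist_ok=True)
    return d


def _stamp(d: Path, cfg_hash: str, seed: int):
    (d / "_done").write_text(json.dumps({"config_hash": cfg_hash, "seed": seed}))


def _done(d: Path) -> bool:
    return (d / "_done").exists()


def _load_images(manifest: pd.DataFrame):
    images, labels, splits = [], [], []
    for _, row in manifest.iterrows():
        img = read_annotated_image(row["image_path"], row["annotation_path"])
        images.append(img.pixels)
        labels.append(1.0 if row["label"] == CANCER else 0.0)
        splits.append(row["split"])
    return images, np.asarray(labels), np.asarray(splits)


def run_experiment(config: dict, resume: bool = True) -> Path:
    """Execute all stages; returns the results directory.

    Stage failures raise with the stage name; artifacts carry the config
    hash + seed stamp so re-runs with the same config are idempotent."""
    config = validate_config(config)
    seed = int(config["seed"])
    chash = config_hash(config)
    root = Path(config["output_root"])
    root.mkdir(parents=True, exist_ok=True)
    (root / "config.json").write_text(json.dumps(config, indent=2, default=str))
    log.info("experiment config=%s seed=%d root=%s", chash, seed, root)

    def stage(name):
        d = _stage_dir(root, name)
        skip = resume and _done(d)
        log.info("stage=%s config=%s seed=%d %s", name, chash, seed,
                 "skipped (done)" if skip else "running")
        return d, skip

    try:
        # ---- phantoms ----
        d, skip = stage("phantom")
        ph = config["phantom"]
        if not skip:
            generate_dataset(
                PhantomConfig(
                    image_height_px=int(ph["image_height_px"]),
                    image_width_px=int(ph["image_width_px"]),
                    pixel_spacing_um=float(ph.get("pixel_spacing_um", 100.0)),
                ),
                n_images=int(ph["n_images"]),
                class_mix=dict(ph["class_mix"]),
                seed=seed,
                out_dir=d,
            )
            _stamp(d, chash, seed)
        manifest = read_manifest(d / "manifest.csv")

        # ---- patches ----
        ex = config["extraction"]
        patch_sizes = [int(s) for s in ex["patch_sizes_px"]]
        d, skip = stage("patches")
        patch_frames = {}
        for size in patch_sizes:
            path = d / f"patches_{size}.csv"
            if not skip or not path.exists():
                ec = ExtractionConfig(
                    patch_size_px=size,
                    n_background=int(ex.get("n_background", 10)),
                    min_lesion_patches=int(ex.get("min_lesion_patches", 10)),
                    iou_max=float(ex.get("iou_max", 0.5)),
                    seed=seed,
                )
                df, _ = build_patch_dataset(manifest, ec)
                df.to_csv(path, index=False)
            patch_frames[size] = pd.read_csv(path)
        if not skip:
            _stamp(d, chash, seed)

        # ---- patch training + image training ----
        tr = config["training"]
        backbone = config["model"]["backbone"]
        lookup = {
            str(row["image_path"]): read_annotated_image(
                row["image_path"], row["annotation_path"]
            )
            for _, row in manifest.iterrows()
        }
        images, labels, splits = _load_images(manifest)
        tr_idx, va_idx = splits == "train", splits == "val"
        patch_cfg = training.TrainConfig(
            lr0=float(tr.get("lr0", 0.05)),
            epochs=int(tr.get("epochs_patch", 4)),
            batch_size=int(tr.get("batch_size", 16)),
            n_runs=int(tr.get("n_runs_patch", 1)),
            seed_base=seed,
        )
        image_cfg = training.TrainConfig(
            lr0=float(tr.get("lr0_image", 0.02)),
            epochs=int(tr.get("epochs_image", 8)),
            batch_size=int(tr.get("batch_size", 8)),
            n_runs=int(tr.get("n_runs_image", 2)),
            seed_base=seed + 1000,
        )
        results_by_model: dict[str, list] = {}
        branches = []
        for size in patch_sizes:
            d, skip = stage(f"train_patch_{size}")
            df = patch_frames[size]
            df_tr = df[df["split"] == "train"]
            df_va = df[df["split"] == "val"]
            X_tr, y_tr = training.load_patches(df_tr, lookup)
            X_va, y_va = training.load_patches(df_va, lookup)
            data = training.PatchData(X_tr, y_tr, X_va, y_va)
            runs = training.train_patch_classifier(
                data,
                lambda s: models.build_patch_classifier(
                    backbone, seed=s, patch_size_px=size
                ),
                patch_cfg,
                checkpoint_dir=d,
            )
            if not skip:
                _stamp(d, chash, seed)
            patch_model = runs[0].model

            d, skip = stage(f"train_image_{size}")
            img_runs = training.train_image_classifier(
                [im for im, k in zip(images, tr_idx) if k],
                labels[tr_idx],
                [im for im, k in zip(images, va_idx) if k],
                labels[va_idx],
                lambda s: models.extend_to_image_classifier(patch_model, seed=s),
                image_cfg,
            )
            results_by_model[f"patch_size_{size}"] = img_runs
            branches.append(img_runs[0].model)
            if not skip:
                _stamp(d, chash, seed)

        # ---- fusion ----
        if len(branches) > 1:
            d, skip = stage("fusion")
            fusion_runs = training.train_fusion_classifier(
                [im for im, k in zip(images, tr_idx) if k],
                labels[tr_idx],
                [im for im, k in zip(images, va_idx) if k],
                labels[va_idx],
                lambda s: models.build_multi_patch_size(
                    branches, allow_any_count=True, seed=s
                ),
                image_cfg,
            )
            results_by_model["multi_patch_size"] = fusion_runs
            if not skip:
                _stamp(d, chash, seed)

        # ---- evaluation ----
        d, _ = stage("evaluation")
        ev = config["evaluation"]
        baseline = ev.get("baseline") or next(iter(results_by_model))
        if all(len(r) >= 2 for r in results_by_model.values()):
            table = summarize_runs(
                results_by_model, baseline, target_se=float(ev.get("target_se", 0.75))
            )
            table.insert(1, "config_hash", chash)
            table.to_csv(d / "summary.csv", index=False)
            table.to_json(d / "summary.json", orient="records", indent=2)
        _stamp(d, chash, seed)
    except Exception as e:
        raise RuntimeError(f"experiment stage failed under {root}: {e}") from e
    return root
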