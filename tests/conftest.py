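"""Shared fixtures: phantom images and a trained tiny patch classifier.

Everything is generated programmatically and cached per session so that
the expensive pieces (CPU training) run once.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mammoscale import models, training
from mammoscale.data_model import read_annotated_image
from mammoscale.patch_extraction import ExtractionConfig, build_patch_dataset
from mammoscale.phantom import (
    LesionSpec,
    PhantomConfig,
    default_lesion_spec,
    generate_dataset,
    generate_phantom,
)


@pytest.fixture(scope="session")
def two_lesion_phantom():
    """A phantom with one malignant mass and one benign calcification."""
    cfg = PhantomConfig(
        image_height_px=768,
        image_width_px=640,
        pixel_spacing_um=100.0,
        lesion_specs=(
            default_lesion_spec("mass", "malignant", 30.0),
            default_lesion_spec("calcification", "benign", 15.0),
        ),
        seed=3,
    )
    return generate_phantom(cfg)


@pytest.fixture(scope="session")
def normal_phantom():
    return generate_phantom(PhantomConfig(320, 256, pixel_spacing_um=200.0, seed=11))


@pytest.fixture(scope="session")
def phantom_dataset(tmp_path_factory):
    """Small mixed dataset (all 4 lesion classes + normals) on disk."""
    out = tmp_path_factory.mktemp("phantoms")
    mix = {
        "normal": 0.2,
        "benign_mass_small": 0.2,
        "malignant_mass_small": 0.2,
        "benign_calc_small": 0.2,
        "malignant_calc_small": 0.2,
    }
    manifest = generate_dataset(
        PhantomConfig(320, 256, pixel_spacing_um=400.0), 20, mix, seed=5, out_dir=out
    )
    lookup = {
        str(r.image_path): read_annotated_image(r.image_path, r.annotation_path)
        for r in manifest.itertuples()
    }
    return manifest, lookup


@pytest.fixture(scope="session")
def trained_patch_model(phantom_dataset):
    """tinycnn patch classifier trained on easy phantom patches, with its
    held-out evaluation patches. Shared by training/explain/model tests."""
    manifest, lookup = phantom_dataset
    config = ExtractionConfig(patch_size_px=64, seed=2)
    patches, _ = build_patch_dataset(manifest, config)
    df_tr = patches[patches["split"] == "train"]
    df_va = patches[patches["split"] == "val"]
    X_tr, y_tr = training.load_patches(df_tr, lookup)
    X_va, y_va = training.load_patches(df_va, lookup)
    data = training.PatchData(X_tr, y_tr, X_va, y_va)
    cfg = training.TrainConfig(lr0=0.05, epochs=12, batch_size=16, n_runs=1, seed_base=0)
    runs = training.train_patch_classifier(
        data,
        lambda s: models.build_patch_classifier("tinycnn", seed=s, patch_size_px=64),
        cfg,
    )
    return {
        "model": runs[0].model,
        "run": runs[0],
        "patches": patches,
        "val": (df_va.reset_index(drop=True), X_va, y_va),
        "lookup": lookup,
        "manifest": manifest,
    }
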