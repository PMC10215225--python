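"""Training recipe: schedule, oversampling, reproducibility, fine-tuning."""

import numpy as np
import pytest
from scipy.stats import chisquare

from mammoscale import models, training
from mammoscale.training import (
    DivergenceError,
    PatchData,
    TrainConfig,
    augment_patch,
    cosine_lr,
    finetune,
    oversample_weights,
)


class TestCosineLr:
    def test_endpoints_and_midpoint(self):
        assert cosine_lr(0, 100, 0.1) == pytest.approx(0.1)
        assert cosine_lr(100, 100, 0.1) == pytest.approx(0.0, abs=1e-12)
        assert cosine_lr(50, 100, 0.1) == pytest.approx(0.05)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            cosine_lr(0, 0, 0.1)
        with pytest.raises(ValueError):
            cosine_lr(11, 10, 0.1)


class TestOversampling:
    def test_inverse_frequency_weights(self):
        labels = [0] * 50 + [1] * 5 + [2] * 5 + [3] * 5 + [4] * 5
        w = oversample_weights(labels)
        assert np.allclose(w[:50], 1 / 50)
        assert np.allclose(w[50:], 1 / 5)

    def test_balanced_labels_uniform(self):
        w = oversample_weights([0, 1, 2, 0, 1, 2])
        assert np.allclose(w, w[0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            oversample_weights([])

    def test_draw_frequencies_uniform(self):
        """10⁴ weighted draws: each class frequency 0.2 ± 0.02 and a χ²
        test does not reject uniformity."""
        rng = np.random.default_rng(0)
        labels = np.array([0] * 200 + [1] * 20 + [2] * 10 + [3] * 40 + [4] * 5)
        w = oversample_weights(labels)
        draws = rng.choice(labels, size=10_000, replace=True, p=w / w.sum())
        freqs = np.bincount(draws, minlength=5) / 10_000
        assert np.all(np.abs(freqs - 0.2) < 0.02)
        assert chisquare(np.bincount(draws, minlength=5)).pvalue > 0.01


def test_augmentation_preserves_patch_content():
    """Flips/90° rotations permute pixels only (class-preserving by
    construction): the multiset of values is unchanged."""
    rng = np.random.default_rng(1)
    patch = rng.normal(size=(1, 12, 12)).astype(np.float32)
    out = augment_patch(patch, rng)
    assert out.shape == patch.shape
    assert np.allclose(np.sort(out.ravel()), np.sort(patch.ravel()))


@pytest.fixture(scope="module")
def tiny_patch_data():
    """Small synthetic 5-class patch problem (blob intensity/shape codes
    the class) learnable by tinycnn in a few epochs."""
    rng = np.random.default_rng(0)
    X, y = [], []
    for i in range(200):
        cls = i % 5
        img = rng.normal(0, 0.15, (32, 32)).astype(np.float32)
        if cls > 0:
            rr, cc = np.mgrid[0:32, 0:32]
            blob = ((rr - 16) ** 2 + (cc - 16) ** 2) < (3 + 3 * cls) ** 2
            img[blob] += 0.5 + 0.2 * cls
        X.append(img)
        y.append(cls)
    X = np.stack(X)[:, None]
    y = np.asarray(y)
    return PatchData(X[:160], y[:160], X[160:], y[160:])


def _builder(size=32):
    return lambda s: models.build_patch_classifier("tinycnn", seed=s, patch_size_px=size)


class TestPatchTraining:
    def test_loss_decreases_in_most_runs(self, tiny_patch_data):
        cfg = TrainConfig(lr0=0.05, epochs=3, batch_size=16, n_runs=5, seed_base=0)
        runs = training.train_patch_classifier(tiny_patch_data, _builder(), cfg)
        assert len(runs) == 5
        improved = sum(
            np.mean(r.loss_history[-5:]) < np.mean(r.loss_history[:5]) for r in runs
        )
        assert improved >= 4
        for r in runs:
            assert r.scores.shape == (40, 5)
            assert np.allclose(r.scores.sum(axis=1), 1.0, atol=1e-4)

    def test_n_runs_distinct_seeds_and_checkpoints(self, tiny_patch_data, tmp_path):
        cfg = TrainConfig(lr0=0.05, epochs=1, batch_size=32, n_runs=3, seed_base=7)
        runs = training.train_patch_classifier(
            tiny_patch_data, _builder(), cfg, checkpoint_dir=tmp_path
        )
        assert [r.seed for r in runs] == [7, 8, 9]
        assert all((tmp_path / f"run_{i:02d}" / "checkpoint.npz").exists() for i in range(3))

    def test_seeded_run_is_bit_reproducible(self, tiny_patch_data):
        cfg = TrainConfig(lr0=0.05, epochs=1, batch_size=16, n_runs=1, seed_base=3)
        a = training.train_patch_classifier(tiny_patch_data, _builder(), cfg)[0]
        b = training.train_patch_classifier(tiny_patch_data, _builder(), cfg)[0]
        assert a.loss_history == b.loss_history
        assert np.array_equal(a.scores, b.scores)

    def test_divergence_raises(self, tiny_patch_data):
        cfg = TrainConfig(lr0=1e20, epochs=2, batch_size=16, n_runs=1)
        with pytest.raises(DivergenceError):
            training.train_patch_classifier(tiny_patch_data, _builder(), cfg)


class TestFinetune:
    def test_frozen_layers_unchanged_after_training(self, tiny_patch_data):
        model = models.build_patch_classifier("tinycnn", seed=0)
        finetune(model, "last_two_blocks")
        before = {n: p.data.copy() for n, p in model.named_parameters()}
        cfg = TrainConfig(lr0=0.05, epochs=1, batch_size=16, n_runs=1)
        rng = np.random.default_rng(0)
        training._fit_softmax(model, tiny_patch_data.X_train, tiny_patch_data.y_train, cfg, rng)
        for name, p in model.named_parameters():
            frozen = name.startswith("backbone.stage0.")
            if frozen:
                assert np.array_equal(p.data, before[name]), name
            else:
                assert not np.array_equal(p.data, before[name]), name

    def test_full_scope_trains_everything(self, tiny_patch_data):
        model = models.build_patch_classifier("tinycnn", seed=0)
        finetune(model, "all")
        before = {n: p.data.copy() for n, p in model.named_parameters()}
        cfg = TrainConfig(lr0=0.05, epochs=1, batch_size=16, n_runs=1)
        training._fit_softmax(
            model, tiny_patch_data.X_train, tiny_patch_data.y_train, cfg,
            np.random.default_rng(0),
        )
        changed = [n for n, p in model.named_parameters() if not np.array_equal(p.data, before[n])]
        assert len(changed) == len(before)

    def test_unknown_scope_rejected(self):
        model = models.build_patch_classifier("tinycnn", seed=0)
        with pytest.raises(ValueError, match="no parameters"):
            finetune(model, ["decoder."])

    def test_incompatible_checkpoint_rejected(self, tmp_path):
        small = models.build_patch_classifier("tinycnn", seed=0)
        np.savez(tmp_path / "ckpt.npz", **small.state_dict())
        other = models.build_fpn_classifier("tinycnn", seed=0)
        with pytest.raises(ValueError, match="incompatible"):
            training.load_checkpoint(other, tmp_path / "ckpt.npz")


class TestImageTraining:
    def test_runs_complete_scores_in_range(self, trained_patch_model):
        fix = trained_patch_model
        manifest, lookup = fix["manifest"], fix["lookup"]
        images = [lookup[str(p)].pixels for p in manifest["image_path"]]
        labels = (manifest["label"] == "cancer").to_numpy(dtype=float)
        cfg = TrainConfig(lr0=0.02, epochs=2, batch_size=8, n_runs=2, seed_base=0)
        runs = training.train_image_classifier(
            images[:14], labels[:14], images[14:], labels[14:],
            lambda s: models.extend_to_image_classifier(fix["model"], seed=s),
            cfg,
        )
        assert len(runs) == 2
        for r in runs:
            assert ((r.scores >= 0) & (r.scores <= 1)).all()
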