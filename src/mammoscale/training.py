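"""Training recipes: SGD + cosine annealing, oversampling, augmentation,
fine-tuning scopes and the repeated-run protocol.

Patch classifiers are trained with softmax cross-entropy over the 5 patch
classes; lesion patches are oversampled (inverse class frequency) to
counter the strong background imbalance. Whole-image classifiers are
trained with binary cross-entropy on the cancer score; by default the
patch-trained extractor is frozen and only the aggregation block and head
learn, which keeps CPU training feasible. Error bars come from repeating
each training `n_runs` times with seeds ``seed_base + i`` (10 runs for
patch classifiers and 5 for whole-image classifiers in the reference
protocol).

Learning rate, batch size and epoch counts have no published reference
values; the defaults here are working values for the synthetic phantoms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import SGD, Tensor
from .patch_extraction import CLASSES


class DivergenceError(RuntimeError):
    """Raised when a training run produces a non-finite loss."""


def cosine_lr(step: int, total_steps: int, lr0: float) -> float:
    """Cosine annealing from lr0 (step 0) to 0 (step = total_steps)."""
    if total_steps <= 0:
        raise ValueError("total_steps must be positive")
    if not 0 <= step <= total_steps:
        raise ValueError("step must lie in [0, total_steps]")
    return lr0 * 0.5 * (1.0 + math.cos(math.pi * step / total_steps))


def oversample_weights(labels) -> np.ndarray:
    """Per-example weights ∝ 1/class frequency; expected draw frequencies
    are uniform over the classes present."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label list")
    _, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
    return 1.0 / counts[inverse]


def augment_patch(patch: np.ndarray, rng: np.random.Generator,
                  flips: bool = True, rotations: bool = True) -> np.ndarray:
    """Random horizontal/vertical flips and 90° rotations (class-preserving)."""
    out = patch
    if flips:
        if rng.integers(2):
            out = out[..., ::-1, :]
        if rng.integers(2):
            out = out[..., :, ::-1]
    if rotations:
        k = int(rng.integers(4))
        if k:
            out = np.rot90(out, k, axes=(-2, -1))
    return np.ascontiguousarray(out)


def normalize_image(pixels: np.ndarray) -> np.ndarray:
    """Map stored intensities to a roughly centred float32 range."""
    x = np.asarray(pixels, dtype=np.float32)
    if np.issubdtype(pixels.dtype, np.integer):
        x = x / 65535.0
    return (x - 0.4) * 4.0


@dataclass(frozen=True)
class TrainConfig:
    lr0: float = 0.05
    momentum: float = 0.9
    epochs: int = 5
    batch_size: int = 16
    augment: bool = True
    oversample: bool = True
    n_runs: int = 1
    seed_base: int = 0
    freeze_extractor: bool = True

    def __post_init__(self):
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class RunResult:
    run_id: int
    seed: int
    scores: np.ndarray  # (N,5) probabilities or (N,) cancer scores
    labels: np.ndarray
    loss_history: list[float] = field(default_factory=list)
    model: object | None = None


@dataclass
class PatchData:
    """Patch pixel arrays: X (N,1,H,W) float32, y integer class indices."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray


def load_patches(patch_df, image_lookup) -> tuple[np.ndarray, np.ndarray]:
    """Crop and normalise the patches of a patch manifest.

    `image_lookup` maps image_id → AnnotatedImage (or 2D array)."""
    xs, ys = [], []
    for _, row in patch_df.iterrows():
        img = image_lookup[row["image_id"]]
        pixels = img.pixels if hasattr(img, "pixels") else img
        r0, c0, s = int(row["r0"]), int(row["c0"]), int(row["size"])
        xs.append(normalize_image(pixels[r0 : r0 + s, c0 : c0 + s]))
        ys.append(CLASSES.index(row["label"]))
    return np.stack(xs)[:, None], np.asarray(ys, dtype=np.int64)


def _check_finite(loss: float):
    if not np.isfinite(loss):
        raise DivergenceError(f"non-finite training loss: {loss}")


def train_patch_classifier(
    data: PatchData,
    builder,
    config: TrainConfig,
    checkpoint_dir=None,
) -> list[RunResult]:
    """Train `config.n_runs` patch classifiers; `builder(seed)` must return
    a freshly initialised model. Returns one RunResult per run with 5-class
    probabilities on the validation split."""
    results = []
    for run in range(config.n_runs):
        seed = config.seed_base + run
        rng = np.random.default_rng(seed)
        model = builder(seed)
        losses = _fit_softmax(model, data.X_train, data.y_train, config, rng)
        model.eval()
        scores = _predict_proba_batched(model, data.X_val)
        if checkpoint_dir is not None:
            path = Path(checkpoint_dir) / f"run_{run:02d}"
            path.mkdir(parents=True, exist_ok=True)
            np.savez(path / "checkpoint.npz", **model.state_dict())
        results.append(RunResult(run, seed, scores, data.y_val.copy(), losses, model))
    return results


def _fit_softmax(model, X, y, config: TrainConfig, rng) -> list[float]:
    model.train()
    n = len(y)
    p = None
    if config.oversample:
        w = oversample_weights(y)
        p = w / w.sum()
    steps_per_epoch = max(1, math.ceil(n / config.batch_size))
    total = config.epochs * steps_per_epoch
    opt = SGD(model.parameters(), config.lr0, config.momentum)
    losses, step = [], 0
    for _ in range(config.epochs):
        for _ in range(steps_per_epoch):
            idx = rng.choice(n, size=min(config.batch_size, n), replace=True, p=p)
            xb = X[idx]
            if config.augment:
                xb = np.stack([augment_patch(x, rng) for x in xb])
            opt.lr = cosine_lr(step, total, config.lr0)
            loss = nn.cross_entropy(model(Tensor(xb)), y[idx])
            _check_finite(loss.item())
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            step += 1
    return losses


def _predict_proba_batched(model, X, batch: int = 32) -> np.ndarray:
    outs = []
    for i in range(0, len(X), batch):
        outs.append(model.predict_proba(X[i : i + batch]))
    return np.concatenate(outs)


# -- fine-tuning scopes -----------------------------------------------------

def finetune(model, trainable_scope="last_two_blocks"):
    """Freeze everything outside `trainable_scope`.

    The scope is either a list of parameter-name prefixes or the preset
    ``"last_two_blocks"``: the last two backbone blocks plus every
    non-backbone parameter (head, aggregation). Frozen parameters get
    ``requires_grad = False`` and receive exactly zero updates."""
    names = [n for n, _ in model.named_parameters()]
    if trainable_scope == "all":
        prefixes = names
    elif trainable_scope == "last_two_blocks":
        stages = model.backbone._order
        prefixes = [f"backbone.{s}." for s in stages[-2:]]
        prefixes += [n for n in names if not n.startswith("backbone.")]
    else:
        prefixes = list(trainable_scope)
        matched = [
            pref for pref in prefixes if any(n.startswith(pref) for n in names)
        ]
        if len(matched) != len(prefixes):
            missing = sorted(set(prefixes) - set(matched))
            raise ValueError(f"scope prefixes match no parameters: {missing}")
    for name, p in model.named_parameters():
        p.requires_grad = any(name.startswith(pref) or name == pref for pref in prefixes)
    return model


def load_checkpoint(model, path):
    """Initialise `model` from an .npz checkpoint; shape mismatches raise."""
    state = dict(np.load(path))
    model.load_state_dict(state)
    return model


# -- whole-image / fusion training ------------------------------------------

def _cache_feature_maps(backbone_fn, images) -> list[np.ndarray]:
    feats = []
    with nn.no_grad():
        for img in images:
            feats.append(backbone_fn(normalize_image(img)).data)
    return feats


def train_image_classifier(
    train_images,
    train_labels,
    val_images,
    val_labels,
    builder,
    config: TrainConfig,
) -> list[RunResult]:
    """Train whole-image classifiers on top of a frozen patch-trained
    extractor. `builder(seed)` returns a fresh WholeImageClassifier sharing
    the extractor; because the extractor is frozen, its feature maps are
    computed once and reused across runs and epochs."""
    if not config.freeze_extractor:
        raise NotImplementedError("end-to-end whole-image fine-tuning is not provided")
    train_labels = np.asarray(train_labels, dtype=np.float32)
    val_labels = np.asarray(val_labels, dtype=np.float32)
    probe = builder(config.seed_base)
    f_train = _cache_feature_maps(probe.extractor_features, train_images)
    f_val = _cache_feature_maps(probe.extractor_features, val_images)
    results = []
    for run in range(config.n_runs):
        seed = config.seed_base + run
        rng = np.random.default_rng(seed)
        model = builder(seed)
        losses = _fit_binary_on_features(
            model.head_from_feature_map, model, f_train, train_labels, config, rng
        )
        model.eval()
        scores = _score_on_features(model.head_from_feature_map, f_val)
        results.append(RunResult(run, seed, scores, val_labels.copy(), losses, model))
    return results


def _fit_binary_on_features(head_fn, model, feats, labels, config, rng) -> list[float]:
    model.train()
    n = len(labels)
    same_shape = len({f.shape for f in feats}) == 1
    steps_per_epoch = max(1, math.ceil(n / config.batch_size))
    total = config.epochs * steps_per_epoch
    params = [p for p in model.parameters() if p.requires_grad]
    opt = SGD(params, config.lr0, config.momentum)
    losses, step = [], 0
    for _ in range(config.epochs):
        for _ in range(steps_per_epoch):
            idx = rng.integers(0, n, size=min(config.batch_size, n))
            opt.lr = cosine_lr(step, total, config.lr0)
            if same_shape:
                logits = head_fn(Tensor(np.concatenate([feats[i] for i in idx])))
                loss = nn.bce_with_logits(logits, labels[idx])
            else:  # variable spatial dims: accumulate per-example grads
                per = [head_fn(Tensor(feats[i])) for i in idx]
                loss = nn.bce_with_logits(nn.concat(per, axis=0), labels[idx])
            _check_finite(loss.item())
            model.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item())
            step += 1
    return losses


def _score_on_features(head_fn, feats) -> np.ndarray:
    scores = []
    with nn.no_grad():
        for f in feats:
            logit = head_fn(Tensor(f)).data.reshape(-1)[0]
            scores.append(1.0 / (1.0 + np.exp(-logit)))
    return np.asarray(scores, dtype=np.float64)


def train_fusion_classifier(
    train_images,
    train_labels,
    val_images,
    val_labels,
    builder,
    config: TrainConfig,
) -> list[RunResult]:
    """Train the fusion MLP of a multi-scale classifier with its branches
    frozen. `builder(seed)` returns a fresh MultiScaleClassifier whose
    branches are already trained. With `config.augment`, every training
    image contributes the feature vectors of its 8 flip/rotation
    orientations (branch features are not augmentation-invariant, so this
    multiplies the effective fusion training set)."""
    train_labels = np.asarray(train_labels, dtype=np.float32)
    val_labels = np.asarray(val_labels, dtype=np.float32)
    probe = builder(config.seed_base)

    def pooled_vec(image) -> np.ndarray:
        with nn.no_grad():
            vecs = [
                b.pooled_features(normalize_image(x))
                for b, x in zip(probe.branches, probe.branch_inputs(image))
            ]
            return np.concatenate([v.data for v in vecs], axis=1)

    def orientations(image):
        for k in range(4):
            rot = np.rot90(image, k)
            yield np.ascontiguousarray(rot)
            yield np.ascontiguousarray(rot[:, ::-1])

    vt, yt = [], []
    for im, lab in zip(train_images, train_labels):
        views = orientations(im) if config.augment else [im]
        for view in views:
            vt.append(pooled_vec(view))
            yt.append(lab)
    v_train = np.concatenate(vt)
    train_labels = np.asarray(yt, dtype=np.float32)
    v_val = np.concatenate([pooled_vec(im) for im in val_images])
    results = []
    for run in range(config.n_runs):
        seed = config.seed_base + run
        rng = np.random.default_rng(seed)
        model = builder(seed)
        model.train()
        n = len(train_labels)
        steps_per_epoch = max(1, math.ceil(n / config.batch_size))
        total = config.epochs * steps_per_epoch
        opt = SGD(model.mlp.parameters(), config.lr0, config.momentum)
        losses, step = [], 0
        for _ in range(config.epochs):
            for _ in range(steps_per_epoch):
                if config.batch_size >= n:  # full-batch gradient step
                    idx = np.arange(n)
                else:
                    idx = rng.integers(0, n, size=config.batch_size)
                opt.lr = cosine_lr(step, total, config.lr0)
                loss = nn.bce_with_logits(
                    model.mlp(Tensor(v_train[idx])), train_labels[idx]
                )
                _check_finite(loss.item())
                model.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
                step += 1
        model.eval()
        with nn.no_grad():
            logits = model.mlp(Tensor(v_val)).data.reshape(-1)
        scores = 1.0 / (1.0 + np.exp(-logits))
        results.append(RunResult(run, seed, scores, val_labels.copy(), losses, model))
    return results
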