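"""Patch classifiers, whole-image extensions and multi-scale fusion models.

A *patch classifier* is a backbone feature extractor followed by global
average pooling (GAP) and a fully connected layer producing 5 class scores
(background, benign/malignant calcification, benign/malignant mass).

The *whole-image* extension strips the GAP/FC head, applies the extractor
fully convolutionally to the entire mammogram (feature maps scale with the
input: 16×16×1024 for a 512×512 patch with DenseNet-121, 89×74×1024 for a
2850×2394 image under floor rounding), then aggregates patch-level
evidence with a spatially striding bottleneck residual block that keeps
the channel count, and finishes with GAP and a single sigmoid "cancer
score".

Multi-scale variants fuse three whole-image branches — either three patch
sizes (256/512/768 px) at one resolution, or one patch size at three
resolutions (100/150/200 μm via 1×/1.5×/2× downsampling) — by
concatenating the three pooled feature vectors into an MLP. An FPN
classifier taps the backbone at strides 8/16/32 with lateral projections
and a top-down pathway instead.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .backbones import (
    Backbone,
    BackboneSpec,
    backbone_spec,
    build_backbone,
    count_backbone_params,
    feature_map_shape,
)
from .data_model import AnnotatedImage
from .nn import BatchNorm2d, Conv2d, Linear, Module, ReLU, Sequential, Tensor
from .patch_extraction import CLASSES

__all__ = [
    "BackboneSpec",
    "backbone_spec",
    "feature_map_shape",
    "count_backbone_params",
    "PatchClassifier",
    "build_patch_classifier",
    "BottleneckResidual",
    "WholeImageClassifier",
    "extend_to_image_classifier",
    "MultiScaleClassifier",
    "build_multi_patch_size",
    "build_multi_resolution",
    "FpnPatchClassifier",
    "FpnImageClassifier",
    "build_fpn_classifier",
    "downsample",
]


def _as_batch(x) -> Tensor:
    """Accept a Tensor, a 2D image or an (N,1,H,W) array."""
    if isinstance(x, Tensor):
        return x
    x = np.asarray(x, dtype=np.float32)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[:, None]
    return Tensor(x)


class PatchClassifier(Module):
    """Backbone → GAP → FC with `n_classes` softmax outputs."""

    def __init__(self, backbone: Backbone, n_classes: int = len(CLASSES),
                 input_patch_size_px: int | None = None,
                 input_resolution_um: float = 100.0):
        super().__init__()
        self.backbone = backbone
        self.fc = Linear(backbone.spec.feature_channels, n_classes)
        self.n_classes = n_classes
        self.input_patch_size_px = input_patch_size_px
        self.input_resolution_um = input_resolution_um

    @property
    def spec(self) -> BackboneSpec:
        return self.backbone.spec

    def features(self, x) -> Tensor:
        """Final convolutional feature map (N, C, h', w')."""
        return self.backbone(_as_batch(x))

    def forward(self, x) -> Tensor:
        return self.fc(nn.global_avg_pool(self.features(x)))

    def forward_with_features(self, x) -> tuple[Tensor, Tensor]:
        fmap = self.features(x)
        return self.fc(nn.global_avg_pool(fmap)), fmap

    def predict_proba(self, x) -> np.ndarray:
        with nn.no_grad():
            logits = self.forward(x)
        return nn.softmax(logits.data, axis=1)


def build_patch_classifier(
    spec: BackboneSpec | str,
    n_classes: int = len(CLASSES),
    seed: int | None = None,
    in_channels: int = 1,
    patch_size_px: int | None = None,
    resolution_um: float = 100.0,
) -> PatchClassifier:
    name = spec if isinstance(spec, str) else spec.name
    if seed is not None:
        nn.seed_init(seed)
    backbone = build_backbone(name, in_channels=in_channels)
    return PatchClassifier(
        backbone,
        n_classes=n_classes,
        input_patch_size_px=patch_size_px,
        input_resolution_um=resolution_um,
    )


class BottleneckResidual(Module):
    """1×1 (stride s) C→C/4 → 3×3 C/4→C/4 → 1×1 C/4→C bottleneck with a
    strided projection shortcut; halves spatial dims (s=2 default), keeps
    the channel count."""

    def __init__(self, channels: int, stride: int = 2):
        super().__init__()
        mid = max(channels // 4, 1)
        self.conv1 = Conv2d(channels, mid, 1, stride=stride)
        self.bn1 = BatchNorm2d(mid)
        self.conv2 = Conv2d(mid, mid, 3, padding=1)
        self.bn2 = BatchNorm2d(mid)
        self.conv3 = Conv2d(mid, channels, 1)
        self.bn3 = BatchNorm2d(channels)
        self.proj = Conv2d(channels, channels, 1, stride=stride)
        self.proj_bn = BatchNorm2d(channels)

    def forward(self, x):
        y = nn.relu(self.bn1(self.conv1(x)))
        y = nn.relu(self.bn2(self.conv2(y)))
        y = self.bn3(self.conv3(y))
        return nn.relu(nn.add(y, self.proj_bn(self.proj(x))))


class WholeImageClassifier(Module):
    """Patch-classifier extractor + aggregation block(s) + GAP + sigmoid FC."""

    def __init__(self, patch_classifier: PatchClassifier, n_agg_blocks: int = 1):
        super().__init__()
        # shared object: extractor weights are the patch classifier's
        self.backbone = patch_classifier.backbone
        c = self.backbone.spec.feature_channels
        self.agg = Sequential(*[BottleneckResidual(c) for _ in range(n_agg_blocks)])
        self.fc = Linear(c, 1)
        self.input_patch_size_px = patch_classifier.input_patch_size_px
        self.input_resolution_um = patch_classifier.input_resolution_um

    @property
    def spec(self) -> BackboneSpec:
        return self.backbone.spec

    def extractor_features(self, x) -> Tensor:
        return self.backbone(_as_batch(x))

    def pooled_features(self, x) -> Tensor:
        """Aggregated, pooled feature vector (N, C) — the fusion input."""
        return nn.global_avg_pool(self.agg(self.extractor_features(x)))

    def head_from_feature_map(self, fmap: Tensor) -> Tensor:
        return self.fc(nn.global_avg_pool(self.agg(fmap)))

    def forward(self, x) -> Tensor:
        return self.head_from_feature_map(self.extractor_features(x))

    def predict_score(self, x) -> np.ndarray:
        """Cancer score(s) in [0, 1]."""
        with nn.no_grad():
            logits = self.forward(x)
        return 1.0 / (1.0 + np.exp(-logits.data.reshape(-1)))


def extend_to_image_classifier(
    patch_clf: PatchClassifier, n_agg_blocks: int = 1, seed: int | None = None
) -> WholeImageClassifier:
    """Strip GAP/FC, keep (share) the extractor weights, append the
    aggregation block and a binary head."""
    if seed is not None:
        nn.seed_init(seed)
    return WholeImageClassifier(patch_clf, n_agg_blocks=n_agg_blocks)


class MultiScaleClassifier(Module):
    """Three whole-image branches fused by an MLP on concatenated pooled
    feature vectors. `factors` present ⇒ multi-resolution variant (each
    branch consumes the image downsampled by its factor)."""

    def __init__(self, branches, hidden: int = 512, factors=None):
        super().__init__()
        branches = list(branches)
        self.n_branches = len(branches)
        for i, b in enumerate(branches):
            setattr(self, f"branch{i}", b)
        channels = [b.spec.feature_channels for b in branches]
        self.concat_length = int(sum(channels))
        self.mlp = Sequential(Linear(self.concat_length, hidden), ReLU(), Linear(hidden, 1))
        self.factors = list(factors) if factors is not None else None
        if self.factors is not None:
            if len(self.factors) != self.n_branches:
                raise ValueError("one downsampling factor per branch required")
            if self.factors[0] != 1 or any(
                a >= b for a, b in zip(self.factors, self.factors[1:])
            ):
                raise ValueError("factors must be strictly increasing and start at 1")
            if min(self.factors) <= 0:
                raise ValueError("factors must be positive")

    @property
    def branches(self):
        return [getattr(self, f"branch{i}") for i in range(self.n_branches)]

    def branch_inputs(self, image: np.ndarray):
        if self.factors is None:
            return [image] * self.n_branches
        return [downsample(image, f) for f in self.factors]

    def fuse(self, pooled: list[Tensor]) -> Tensor:
        return self.mlp(nn.concat(pooled, axis=1))

    def forward(self, image) -> Tensor:
        image = image.data if isinstance(image, Tensor) else np.asarray(image)
        pooled = [
            b.pooled_features(x) for b, x in zip(self.branches, self.branch_inputs(image))
        ]
        return self.fuse(pooled)

    def predict_score(self, image) -> np.ndarray:
        with nn.no_grad():
            logits = self.forward(image)
        return 1.0 / (1.0 + np.exp(-logits.data.reshape(-1)))


def build_multi_patch_size(branches, hidden: int = 512, allow_any_count: bool = False,
                           seed: int | None = None) -> MultiScaleClassifier:
    branches = list(branches)
    if len(branches) != 3 and not allow_any_count:
        raise ValueError("multi-patch-size fusion expects exactly 3 branches")
    res = {b.input_resolution_um for b in branches}
    if len(res) > 1:
        raise ValueError("multi-patch-size branches must share the input resolution")
    if seed is not None:
        nn.seed_init(seed)
    return MultiScaleClassifier(branches, hidden=hidden)


def build_multi_resolution(branches, factors=(1, 1.5, 2), hidden: int = 512,
                           seed: int | None = None) -> MultiScaleClassifier:
    if seed is not None:
        nn.seed_init(seed)
    return MultiScaleClassifier(list(branches), hidden=hidden, factors=list(factors))


# -- FPN --------------------------------------------------------------------

class FpnPatchClassifier(Module):
    """Backbone taps at three strides, lateral 1×1 projections to a common
    width, top-down pathway, per-level GAP, concatenated → FC (5 classes)."""

    def __init__(self, backbone: Backbone, width: int = 64,
                 n_classes: int = len(CLASSES), input_patch_size_px: int | None = 768):
        super().__init__()
        taps = backbone.tap_channels
        if len(taps) != 3:
            raise ValueError("backbone must expose 3 stage taps")
        self.backbone = backbone
        self.width = width
        for i, c in enumerate(taps):
            setattr(self, f"lateral{i}", Conv2d(c, width, 1))
            setattr(self, f"smooth{i}", Conv2d(width, width, 3, padding=1))
        self.fc = Linear(3 * width, n_classes)
        self.n_classes = n_classes
        self.input_patch_size_px = input_patch_size_px
        self.input_resolution_um = 100.0

    @property
    def spec(self) -> BackboneSpec:
        return self.backbone.spec

    def level_maps(self, x) -> list[Tensor]:
        """Fused pyramid levels, shallow (high-res) → deep (low-res)."""
        c3, c4, c5 = self.backbone.forward_taps(_as_batch(x))
        p5 = self.lateral2(c5)
        p4 = nn.add(self.lateral1(c4), nn.upsample_nearest(p5, c4.shape[2:]))
        p3 = nn.add(self.lateral0(c3), nn.upsample_nearest(p4, c3.shape[2:]))
        return [self.smooth0(p3), self.smooth1(p4), self.smooth2(p5)]

    def forward(self, x) -> Tensor:
        pooled = [nn.global_avg_pool(p) for p in self.level_maps(x)]
        return self.fc(nn.concat(pooled, axis=1))

    def predict_proba(self, x) -> np.ndarray:
        with nn.no_grad():
            logits = self.forward(x)
        return nn.softmax(logits.data, axis=1)


class FpnImageClassifier(Module):
    """FPN patch stage extended to whole images: per-level aggregation
    blocks, per-level GAP, concatenation, sigmoid FC."""

    def __init__(self, patch_stage: FpnPatchClassifier, n_agg_blocks: int = 1):
        super().__init__()
        self.patch_stage = patch_stage
        w = patch_stage.width
        for i in range(3):
            setattr(
                self, f"agg{i}",
                Sequential(*[BottleneckResidual(w) for _ in range(n_agg_blocks)]),
            )
        self.fc = Linear(3 * w, 1)

    @property
    def spec(self) -> BackboneSpec:
        return self.patch_stage.spec

    def forward(self, x) -> Tensor:
        levels = self.patch_stage.level_maps(x)
        pooled = [
            nn.global_avg_pool(getattr(self, f"agg{i}")(p)) for i, p in enumerate(levels)
        ]
        return self.fc(nn.concat(pooled, axis=1))

    def predict_score(self, x) -> np.ndarray:
        with nn.no_grad():
            logits = self.forward(x)
        return 1.0 / (1.0 + np.exp(-logits.data.reshape(-1)))


def build_fpn_classifier(
    spec: BackboneSpec | str,
    patch_size: int = 768,
    width: int | None = None,
    seed: int | None = None,
    in_channels: int = 1,
) -> FpnPatchClassifier:
    name = spec if isinstance(spec, str) else spec.name
    if seed is not None:
        nn.seed_init(seed)
    backbone = build_backbone(name, in_channels=in_channels)
    if width is None:
        width = 64 if name == "tinycnn" else 256
    return FpnPatchClassifier(backbone, width=width, input_patch_size_px=patch_size)


# -- resolution -------------------------------------------------------------

def downsample(image, factor: float):
    """Anti-aliased downsampling by `factor` ≥ 1; output dims are
    floor(input/factor) and the pixel spacing is multiplied by the factor.

    Accepts a 2D array (returns a 2D array) or an :class:`AnnotatedImage`
    (returns a new one with rescaled lesion masks)."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if isinstance(image, AnnotatedImage):
        new_pixels = downsample(image.pixels, factor)
        scale = 1.0 / factor
        lesions = []
        for les in image.lesions:
            full = les.full_mask(image.shape)
            small = _sk_resize(
                full.astype(np.float64),
                new_pixels.shape,
                order=0,
                anti_aliasing=False,
                preserve_range=True,
            ) > 0.5
            if not small.any():  # a lesion vanished below one pixel
                r0, c0, _, _ = les.bbox
                small[int(r0 * scale), int(c0 * scale)] = True
            lesions.append(
                type(les).from_full_mask(small, les.lesion_type, les.pathology)
            )
        return AnnotatedImage(
            pixels=new_pixels,
            pixel_spacing_um=image.pixel_spacing_um * factor,
            lesions=lesions,
        )
    image = np.asarray(image)
    if factor == 1:
        return image.copy()
    out_shape = (int(image.shape[0] // factor), int(image.shape[1] // factor))
    if min(out_shape) < 1:
        raise ValueError("downsampled image would be empty")
    out = _sk_resize(
        image.astype(np.float64), out_shape, anti_aliasing=True, preserve_range=True
    )
    return out.astype(image.dtype) if np.issubdtype(image.dtype, np.integer) else out.astype(
        image.dtype, copy=False
    )
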