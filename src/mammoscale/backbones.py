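"""Convolutional backbones and their shape contracts.

The patch classifiers in this package are built on a fully convolutional
feature extractor ("backbone"): an input image of H×W pixels is mapped to a
feature map of roughly (H/r)×(W/r)×C, where ``r`` is the backbone's spatial
reduction factor and ``C`` its feature channel count. DenseNet-121 (r=32,
C=1024) is the production backbone; ResNet-34 is kept for parameter-count
comparison, and ``tinycnn`` (r=8, C=64) is a deliberately small backbone so
the full pipeline runs on a CPU in seconds.

All spatial arithmetic uses floor rounding: a conv/pool layer with kernel
``k``, stride ``s`` and padding ``p`` maps a side of ``n`` pixels to
``floor((n + 2p - k)/s) + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import (
    Module,
    Sequential,
    Conv2d,
    BatchNorm2d,
    ReLU,
    MaxPool2d,
    AvgPool2d,
    Identity,
    Tensor,
)


@dataclass(frozen=True)
class BackboneSpec:
    """Identity and analytic contract of a backbone architecture."""

    name: str
    reduction_factor: int
    feature_channels: int
    pretrained_checkpoint: str | None = None

    def __post_init__(self):
        r = self.reduction_factor
        if r <= 0 or (r & (r - 1)) != 0:
            raise ValueError("reduction_factor must be a positive power of 2")
        if self.feature_channels <= 0:
            raise ValueError("feature_channels must be positive")


# (kernel, stride, padding) of every size-changing layer, in order.
_SIZE_LAYERS = {
    "densenet121": [(7, 2, 3), (3, 2, 1), (2, 2, 0), (2, 2, 0), (2, 2, 0)],
    "resnet34": [(7, 2, 3), (3, 2, 1), (3, 2, 1), (3, 2, 1), (3, 2, 1)],
    "tinycnn": [(2, 2, 0), (2, 2, 0), (2, 2, 0)],
}

_SPECS = {
    "densenet121": BackboneSpec("densenet121", 32, 1024),
    "resnet34": BackboneSpec("resnet34", 32, 512),
    "tinycnn": BackboneSpec("tinycnn", 8, 64),
}


def backbone_spec(name: str) -> BackboneSpec:
    try:
        return _SPECS[name]
    except KeyError:
        raise ValueError(f"unknown backbone {name!r}; known: {sorted(_SPECS)}") from None


def feature_map_shape(h: int, w: int, spec: BackboneSpec | str) -> tuple[int, int, int]:
    """Analytic output shape (h', w', channels) of a backbone's feature map.

    Must agree with an actual forward pass (tested as such); raises if the
    input is smaller than the reduction factor in either dimension.
    """
    if isinstance(spec, str):
        spec = backbone_spec(spec)
    if h < spec.reduction_factor or w < spec.reduction_factor:
        raise ValueError(
            f"input {h}x{w} smaller than reduction factor {spec.reduction_factor}"
        )
    for k, s, p in _SIZE_LAYERS[spec.name]:
        h = (h + 2 * p - k) // s + 1
        w = (w + 2 * p - k) // s + 1
    return h, w, spec.feature_channels


# -- DenseNet ---------------------------------------------------------------

class _DenseLayer(Module):
    def __init__(self, in_channels: int, growth: int = 32, bn_size: int = 4):
        super().__init__()
        self.norm1 = BatchNorm2d(in_channels)
        self.conv1 = Conv2d(in_channels, bn_size * growth, 1)
        self.norm2 = BatchNorm2d(bn_size * growth)
        self.conv2 = Conv2d(bn_size * growth, growth, 3, padding=1)

    def forward(self, x):
        y = self.conv1(nn.relu(self.norm1(x)))
        y = self.conv2(nn.relu(self.norm2(y)))
        return nn.concat([x, y], axis=1)


class _DenseBlock(Module):
    def __init__(self, n_layers: int, in_channels: int, growth: int = 32):
        super().__init__()
        self._order = []
        for i in range(n_layers):
            name = f"layer{i}"
            setattr(self, name, _DenseLayer(in_channels + i * growth, growth))
            self._order.append(name)

    def forward(self, x):
        for name in self._order:
            x = getattr(self, name)(x)
        return x


class _Transition(Module):
    def __init__(self, in_channels: int, out_channels: int):
        super().__init__()
        self.norm = BatchNorm2d(in_channels)
        self.conv = Conv2d(in_channels, out_channels, 1)
        self.pool = AvgPool2d(2, 2)

    def forward(self, x):
        return self.pool(self.conv(nn.relu(self.norm(x))))


class Backbone(Module):
    """A feature extractor split into stages; the last 3 stages are FPN taps.

    ``stage_channels``/``stage_strides`` describe each stage's output.
    """

    def __init__(self, spec: BackboneSpec, stages, stage_channels, stage_strides):
        super().__init__()
        self.spec = spec
        self._order = []
        for i, st in enumerate(stages):
            name = f"stage{i}"
            setattr(self, name, st)
            self._order.append(name)
        self.stage_channels = list(stage_channels)
        self.stage_strides = list(stage_strides)

    def forward(self, x: Tensor) -> Tensor:
        for name in self._order:
            x = getattr(self, name)(x)
        return x

    def forward_taps(self, x: Tensor):
        """Feature maps of the last three stages (shallow → deep)."""
        outs = []
        for name in self._order:
            x = getattr(self, name)(x)
            outs.append(x)
        return outs[-3:]

    @property
    def tap_channels(self):
        return self.stage_channels[-3:]


class _FinalNorm(Module):
    def __init__(self, channels):
        super().__init__()
        self.norm = BatchNorm2d(channels)

    def forward(self, x):
        return nn.relu(self.norm(x))


def _densenet121(in_channels: int) -> Backbone:
    growth, cfg = 32, (6, 12, 24, 16)
    stem = Sequential(
        Conv2d(in_channels, 64, 7, stride=2, padding=3),
        BatchNorm2d(64),
        ReLU(),
        MaxPool2d(3, 2, 1),
    )
    c = 64
    stages, chans, strides = [stem], [64], [4]
    stride = 4
    for i, n_layers in enumerate(cfg):
        block = _DenseBlock(n_layers, c, growth)
        c += n_layers * growth
        if i < len(cfg) - 1:
            trans = _Transition(c, c // 2)
            c //= 2
            stride *= 2
            stages.append(Sequential(block, trans))
        else:
            stages.append(Sequential(block, _FinalNorm(c)))
        chans.append(c)
        strides.append(stride)
    # stage list: stem(s4), block1+t(s8,128), block2+t(s16,256),
    # block3+t(s32,512), block4+norm(s32,1024)
    strides[-1] = stride  # final block keeps stride 32
    return Backbone(_SPECS["densenet121"], stages, chans, strides)


# -- ResNet -----------------------------------------------------------------

class _BasicBlock(Module):
    def __init__(self, in_channels, out_channels, stride=1):
        super().__init__()
        self.conv1 = Conv2d(in_channels, out_channels, 3, stride=stride, padding=1)
        self.bn1 = BatchNorm2d(out_channels)
        self.conv2 = Conv2d(out_channels, out_channels, 3, padding=1)
        self.bn2 = BatchNorm2d(out_channels)
        if stride != 1 or in_channels != out_channels:
            self.down = Sequential(
                Conv2d(in_channels, out_channels, 1, stride=stride), BatchNorm2d(out_channels)
            )
        else:
            self.down = Identity()

    def forward(self, x):
        y = self.bn2(self.conv2(nn.relu(self.bn1(self.conv1(x)))))
        return nn.relu(nn.add(y, self.down(x)))


def _resnet34(in_channels: int) -> Backbone:
    stem = Sequential(
        Conv2d(in_channels, 64, 7, stride=2, padding=3),
        BatchNorm2d(64),
        ReLU(),
        MaxPool2d(3, 2, 1),
    )
    cfg = [(3, 64, 1), (4, 128, 2), (6, 256, 2), (3, 512, 2)]
    stages, chans, strides = [stem], [64], [4]
    c, stride = 64, 4
    for n_blocks, width, first_stride in cfg:
        blocks = []
        for b in range(n_blocks):
            s = first_stride if b == 0 else 1
            blocks.append(_BasicBlock(c, width, s))
            c = width
        stride *= first_stride
        stages.append(Sequential(*blocks))
        chans.append(c)
        strides.append(stride)
    return Backbone(_SPECS["resnet34"], stages, chans, strides)


# -- tinycnn ----------------------------------------------------------------

def _tinycnn(in_channels: int) -> Backbone:
    widths = [16, 32, 64]
    stages, chans, strides = [], [], []
    c, stride = in_channels, 1
    for w in widths:
        stages.append(
            Sequential(Conv2d(c, w, 3, padding=1), BatchNorm2d(w), ReLU(), MaxPool2d(2, 2))
        )
        c = w
        stride *= 2
        chans.append(c)
        strides.append(stride)
    return Backbone(_SPECS["tinycnn"], stages, chans, strides)


_BUILDERS = {"densenet121": _densenet121, "resnet34": _resnet34, "tinycnn": _tinycnn}


def build_backbone(name: str, in_channels: int = 1, seed: int | None = None) -> Backbone:
    """Build a backbone feature extractor with seeded weight initialisation."""
    if name not in _BUILDERS:
        raise ValueError(f"unknown backbone {name!r}; known: {sorted(_BUILDERS)}")
    if seed is not None:
        nn.seed_init(seed)
    return _BUILDERS[name](in_channels)


def count_backbone_params(model_or_name: Backbone | str) -> int:
    """Trainable parameters of the convolutional feature extractor alone
    (no classification head)."""
    if isinstance(model_or_name, str):
        model_or_name = build_backbone(model_or_name)
    return int(model_or_name.num_parameters())


def tinycnn_param_count_closed_form(in_channels: int = 1) -> int:
    """Closed-form parameter count of tinycnn (conv kernels + BN affine)."""
    widths = [16, 32, 64]
    total, c = 0, in_channels
    for w in widths:
        total += c * w * 9 + 2 * w
        c = w
    return total
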