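"""Module system: parameter containers and layers over the autodiff core."""

from __future__ import annotations

import numpy as np

from . import tensor as T
from .tensor import Tensor

_INIT_RNG = [np.random.default_rng(0)]


def seed_init(seed: int) -> None:
    """Seed the weight-initialisation stream used by subsequently built layers."""
    _INIT_RNG[0] = np.random.default_rng(int(seed))


def _init_rng() -> np.random.Generator:
    return _INIT_RNG[0]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Minimal torch-like module: registration by attribute assignment."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, value):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (prefix + name, p)
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield (prefix + name, b)
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        out.update({name: b.copy() for name, b in self.named_buffers()})
        return out

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        missing = (set(own) | set(bufs)) - set(state)
        extra = set(state) - (set(own) | set(bufs))
        if missing or extra:
            raise ValueError(
                f"incompatible state dict: missing={sorted(missing)} unexpected={sorted(extra)}"
            )
        for name, p in own.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data[...] = state[name]
        for name, b in bufs.items():
            b[...] = state[name]
        return self

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return T.relu(x)


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1, padding=0):
        super().__init__()
        k = int(kernel_size)
        fan_in = in_channels * k * k
        std = float(np.sqrt(2.0 / fan_in))  # Kaiming for ReLU nets
        w = _init_rng().normal(0.0, std, size=(out_channels, in_channels, k, k))
        self.weight = Parameter(w)
        self.stride = int(stride)
        self.padding = int(padding)

    def forward(self, x):
        return T.conv2d(x, self.weight, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        return T.batch_norm2d(
            x, self.weight, self.bias, self.running_mean, self.running_var,
            training=self.training, momentum=self.momentum, eps=self.eps,
        )


class MaxPool2d(Module):
    def __init__(self, kernel_size, stride=None, padding=0):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x):
        return T.max_pool2d(x, self.kernel_size, self.stride, self.padding)


class AvgPool2d(Module):
    def __init__(self, kernel_size, stride=None):
        super().__init__()
        self.kernel_size, self.stride = kernel_size, stride

    def forward(self, x):
        return T.avg_pool2d(x, self.kernel_size, self.stride)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True):
        super().__init__()
        bound = float(1.0 / np.sqrt(in_features))
        self.weight = Parameter(_init_rng().uniform(-bound, bound, (out_features, in_features)))
        self.bias = Parameter(_init_rng().uniform(-bound, bound, out_features)) if bias else None
        if self.bias is None:
            object.__setattr__(self, "bias", None)

    def forward(self, x):
        return T.linear(x, self.weight, self.bias)


class Sequential(Module):
    def __init__(self, *layers, names=None):
        super().__init__()
        self._order = []
        for i, layer in enumerate(layers):
            name = names[i] if names else str(i)
            setattr(self, name, layer)
            self._order.append(name)

    def __iter__(self):
        return (getattr(self, n) for n in self._order)

    def __len__(self):
        return len(self._order)

    def forward(self, x):
        for name in self._order:
            x = getattr(self, name)(x)
        return x


class SGD:
    """SGD with classical momentum; learning rate mutable between steps."""

    def __init__(self, parameters, lr: float, momentum: float = 0.9):
        self.params = [p for p in parameters]
        self.lr = float(lr)
        self.momentum = float(momentum)
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if not p.requires_grad or p.grad is None:
                continue
            v *= self.momentum
            v += p.grad
            p.data -= self.lr * v
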