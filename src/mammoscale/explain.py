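"""Grad-CAM heatmaps of the ground-truth class from the last conv layer.

Channel weights are the spatial means of ∂(class logit)/∂(feature map);
the heatmap is the ReLU of the weighted channel sum, max-normalised and
bilinearly upsampled to the input patch size. An all-zero gradient yields
an all-zero heatmap, flagged rather than rejected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .models import PatchClassifier
from .nn import Tensor
from .training import normalize_image


@dataclass
class Cam:
    heatmap: np.ndarray  # feature-map resolution, >= 0, max 1 unless zero
    upsampled: np.ndarray  # input-patch resolution
    target_class: int
    is_zero: bool


def grad_cam(model: PatchClassifier, patch: np.ndarray, target_class: int) -> Cam:
    """Grad-CAM for `target_class` (index into the 5 classes) on one patch."""
    if not 0 <= target_class < model.n_classes:
        raise ValueError(f"target_class {target_class} out of range")
    model.eval()
    patch = np.asarray(patch)
    x = normalize_image(patch) if patch.ndim == 2 else np.asarray(patch, dtype=np.float32)
    while x.ndim < 4:
        x = x[None]
    logits, fmap = model.forward_with_features(Tensor(x))
    grad_seed = np.zeros_like(logits.data)
    grad_seed[:, target_class] = 1.0
    logits.backward(grad_seed)
    grads = fmap.grad  # (1, C, h, w)
    weights = grads.mean(axis=(2, 3))  # spatial mean per channel
    cam = np.maximum((weights[:, :, None, None] * fmap.data).sum(axis=1), 0.0)[0]
    peak = cam.max()
    is_zero = peak <= 0
    if not is_zero:
        cam = cam / peak
    up = _sk_resize(cam, patch.shape[-2:], order=1, anti_aliasing=False, preserve_range=True)
    return Cam(heatmap=cam, upsampled=up, target_class=target_class, is_zero=bool(is_zero))


def cam_overlay(patch: np.ndarray, cam: Cam, alpha: float = 0.4) -> np.ndarray:
    """RGB overlay for inspection (presentation only)."""
    import matplotlib

    base = np.asarray(patch, dtype=np.float64)
    base = (base - base.min()) / max(np.ptp(base), 1e-9)
    heat = matplotlib.colormaps["jet"](cam.upsampled)[..., :3]
    rgb = (1 - alpha) * base[..., None] + alpha * heat
    return np.clip(rgb, 0, 1)
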