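"""Synthetic mammogram-like phantoms with controlled lesions.

Every downstream stage of the pipeline (patch extraction, patch/whole-image
training, per-lesion-size evaluation, grad-CAM) is exercisable on these
phantoms without any external data. A phantom is a breast-shaped half-
ellipse of textured tissue on a dark background, into which masses
(soft-edged ellipses with a sinusoidally perturbed border) and
calcification clusters (groups of small bright dots) are inserted.

Malignancy is made learnable by construction: malignant masses get a more
irregular border and higher contrast than benign ones, malignant
calcification clusters get finer and denser dots. The generated lesion's
measured maximal dimension (larger tight-bbox side) is guaranteed to lie
within ±10% of the requested physical size; masses are rasterised, measured
and rescaled once to stay well inside that band.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .data_model import (
    BENIGN,
    CALCIFICATION,
    MALIGNANT,
    MASS,
    AnnotatedImage,
    LesionAnnotation,
    mm_to_px,
    size_group_from_mm,
    write_annotated_image,
    write_manifest,
)

# Intensity model (fractions of the 16-bit dynamic range). The source data
# carry no published intensity statistics, so these are free parameters of
# the phantom; see docs/methods.md.
AIR_LEVEL = 0.02
BREAST_LEVEL = 0.38
TEXTURE_STD = 0.06
MASS_GAIN = 0.55
CALC_GAIN = 0.90

# Malignancy proxies used by `default_lesion_spec`.
CONTRAST_MARGIN = 0.15
BENIGN_CONTRAST = 0.30
BENIGN_IRREGULARITY = 0.2
MALIGNANT_IRREGULARITY = 0.7
BENIGN_DOTS, BENIGN_DOT_RADIUS = 8, 3
MALIGNANT_DOTS, MALIGNANT_DOT_RADIUS = 18, 2

_PLACEMENT_RETRIES = 200


class PlacementError(RuntimeError):
    """A lesion could not be placed inside the breast without overlap."""


@dataclass(frozen=True)
class LesionSpec:
    lesion_type: str
    pathology: str
    max_dim_mm: float
    contrast: float = BENIGN_CONTRAST
    border_irregularity: float = BENIGN_IRREGULARITY  # masses only
    n_dots: int = BENIGN_DOTS  # calcification clusters only
    dot_radius_px: int = BENIGN_DOT_RADIUS

    def __post_init__(self):
        if self.lesion_type not in (MASS, CALCIFICATION):
            raise ValueError(f"unknown lesion_type {self.lesion_type!r}")
        if self.pathology not in (BENIGN, MALIGNANT):
            raise ValueError(f"unknown pathology {self.pathology!r}")
        if self.max_dim_mm <= 0:
            raise ValueError("max_dim_mm must be positive")
        if not 0 < self.contrast <= 1:
            raise ValueError("contrast must be in (0, 1]")
        if not 0 <= self.border_irregularity <= 1:
            raise ValueError("border_irregularity must be in [0, 1]")
        if self.n_dots < 2 or self.dot_radius_px < 1:
            raise ValueError("calcification cluster needs >= 2 dots of radius >= 1")


def default_lesion_spec(
    lesion_type: str, pathology: str, max_dim_mm: float, contrast: float | None = None
) -> LesionSpec:
    """Lesion spec with the package's malignancy proxies applied."""
    malignant = pathology == MALIGNANT
    if contrast is None:
        contrast = BENIGN_CONTRAST + (CONTRAST_MARGIN if malignant else 0.0)
    return LesionSpec(
        lesion_type=lesion_type,
        pathology=pathology,
        max_dim_mm=max_dim_mm,
        contrast=contrast,
        border_irregularity=MALIGNANT_IRREGULARITY if malignant else BENIGN_IRREGULARITY,
        n_dots=MALIGNANT_DOTS if malignant else BENIGN_DOTS,
        dot_radius_px=MALIGNANT_DOT_RADIUS if malignant else BENIGN_DOT_RADIUS,
    )


@dataclass(frozen=True)
class PhantomConfig:
    image_height_px: int
    image_width_px: int
    pixel_spacing_um: float = 100.0
    background_texture_scale: float = 8.0
    lesion_specs: tuple[LesionSpec, ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "lesion_specs", tuple(self.lesion_specs))
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.pixel_spacing_um <= 0:
            raise ValueError("pixel_spacing_um must be positive")
        if self.background_texture_scale <= 0:
            raise ValueError("background_texture_scale must be positive")
        for spec in self.lesion_specs:
            ext = mm_to_px(spec.max_dim_mm, self.pixel_spacing_um)
            if 2 * ext > min(self.image_height_px, self.image_width_px):
                raise ValueError(
                    f"image dimensions must be at least twice the largest lesion "
                    f"extent ({ext:.0f} px requested by {spec})"
                )


def breast_mask(height: int, width: int) -> np.ndarray:
    """Half-ellipse breast foreground attached to the left image edge."""
    rr, cc = np.mgrid[0:height, 0:width]
    cy = (height - 1) / 2.0
    semi_r = 0.46 * height
    semi_c = 0.85 * width
    return ((cc / semi_c) ** 2 + ((rr - cy) / semi_r) ** 2) <= 1.0


def _mass_mask(d_px: int, irregularity: float, rng: np.random.Generator):
    """Rasterise a perturbed ellipse; returns (mask, soft intensity profile).

    The larger bbox side is corrected towards `d_px` with one re-raster.
    """
    aspect = rng.uniform(0.85, 1.0)
    k = int(rng.integers(5, 10))
    phase = rng.uniform(0, 2 * np.pi)
    amp = 0.06 * irregularity
    transpose = bool(rng.integers(0, 2))

    def raster(a, b):
        half = int(np.ceil(a * (1 + amp))) + 2
        y, x = np.mgrid[-half : half + 1, -half : half + 1]
        r = np.sqrt((x / a) ** 2 + (y / b) ** 2)
        theta = np.arctan2(y, x)
        limit = 1.0 + amp * np.sin(k * theta + phase)
        return r <= limit, r / np.maximum(limit, 1e-6)

    a = d_px / 2.0
    b = a * aspect
    mask, rnorm = raster(a, b)
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    measured = max(rows[-1] - rows[0] + 1, cols[-1] - cols[0] + 1)
    scale = d_px / measured
    if abs(scale - 1.0) > 0.04:
        mask, rnorm = raster(a * scale, b * scale)
        rows = np.flatnonzero(mask.any(axis=1))
        cols = np.flatnonzero(mask.any(axis=0))
    mask = mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    rnorm = rnorm[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    # soft-edged radial profile: 1 in the core, fading to 0 at the border
    profile = np.clip((1.0 - rnorm) / 0.35, 0.0, 1.0) * mask
    if transpose:
        mask, profile = mask.T, profile.T
    return mask, profile


def _calc_mask(d_px: int, n_dots: int, radius: int, rng: np.random.Generator):
    """Cluster of hard dots whose bbox width is exactly `d_px`."""
    w = max(d_px, 2 * (2 * radius + 1) + 1)
    h = max(int(round(w * rng.uniform(0.6, 1.0))), 2 * radius + 1)
    mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]

    def stamp(r, c):
        mask[(yy - r) ** 2 + (xx - c) ** 2 <= radius**2] = True

    # anchor dots pin the horizontal extent to d_px
    stamp(int(rng.integers(radius, h - radius)), radius)
    stamp(int(rng.integers(radius, h - radius)), w - 1 - radius)
    for _ in range(max(n_dots - 2, 0)):
        stamp(int(rng.integers(radius, h - radius)), int(rng.integers(radius, w - radius)))
    rows = np.flatnonzero(mask.any(axis=1))
    mask = mask[rows[0] : rows[-1] + 1]
    profile = ndimage.gaussian_filter(mask.astype(np.float64), 0.5)
    profile /= profile.max()
    if rng.integers(0, 2):  # random orientation
        mask, profile = mask.T, profile.T
    return mask, profile


def generate_phantom(config: PhantomConfig) -> AnnotatedImage:
    """Deterministic phantom for `config`; raises :class:`PlacementError`
    naming the offending lesion spec when placement fails."""
    rng = np.random.default_rng(config.seed)
    h, w = config.image_height_px, config.image_width_px
    breast = breast_mask(h, w)
    noise = ndimage.gaussian_filter(rng.standard_normal((h, w)), config.background_texture_scale)
    std = noise.std()
    if std > 0:
        noise *= TEXTURE_STD / std
    pixels = np.where(breast, BREAST_LEVEL + noise, AIR_LEVEL)
    pixels += rng.normal(0, 0.004, size=(h, w))  # sensor-like white noise

    core = ndimage.binary_erosion(breast, iterations=3)
    occupied = np.zeros((h, w), dtype=bool)
    lesions: list[LesionAnnotation] = []
    for spec in config.lesion_specs:
        d_px = int(round(mm_to_px(spec.max_dim_mm, config.pixel_spacing_um)))
        if spec.lesion_type == MASS:
            mask, profile = _mass_mask(d_px, spec.border_irregularity, rng)
            gain = MASS_GAIN
        else:
            mask, profile = _calc_mask(d_px, spec.n_dots, spec.dot_radius_px, rng)
            gain = CALC_GAIN
        mh, mw = mask.shape
        placed = False
        for _ in range(_PLACEMENT_RETRIES):
            if mh >= h or mw >= w:
                break
            r0 = int(rng.integers(0, h - mh))
            c0 = int(rng.integers(0, w - mw))
            region_core = core[r0 : r0 + mh, c0 : c0 + mw]
            region_occ = occupied[r0 : r0 + mh, c0 : c0 + mw]
            if np.all(region_core[mask]) and not region_occ[mask].any():
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place lesion after {_PLACEMENT_RETRIES} retries: {spec}"
            )
        pixels[r0 : r0 + mh, c0 : c0 + mw] += spec.contrast * gain * profile
        occupied[r0 : r0 + mh, c0 : c0 + mw] |= ndimage.binary_dilation(mask, iterations=2)
        lesions.append(
            LesionAnnotation(
                mask=mask,
                bbox=(r0, c0, r0 + mh, c0 + mw),
                lesion_type=spec.lesion_type,
                pathology=spec.pathology,
            )
        )

    pixels = np.clip(pixels, 0.0, 1.0)
    pixels = np.round(pixels * 65535).astype(np.uint16)
    return AnnotatedImage(
        pixels=pixels, pixel_spacing_um=config.pixel_spacing_um, lesions=lesions
    )


# -- dataset generation -----------------------------------------------------

NORMAL = "normal"

# physical size ranges (mm) the generator samples per size group
_SIZE_RANGES_MM = {"small": (8.0, 24.0), "medium": (27.0, 50.0), "large": (53.0, 78.0)}


def _largest_remainder_counts(class_mix: dict[str, float], n: int) -> dict[str, int]:
    keys = list(class_mix)
    total = sum(class_mix.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError("class_mix proportions must sum to 1")
    raw = {k: class_mix[k] * n for k in keys}
    counts = {k: int(np.floor(raw[k])) for k in keys}
    rem = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: (raw[k] - counts[k]), reverse=True)[:rem]:
        counts[k] += 1
    return counts


def _category_spec(category: str, config: PhantomConfig, rng) -> LesionSpec | None:
    """Parse a class-mix key: "normal" or "<pathology>_<type>_<sizegroup>"."""
    if category == NORMAL:
        return None
    try:
        pathology, lesion_type, group = category.split("_")
        lesion_type = {"calc": CALCIFICATION, "calcification": CALCIFICATION, "mass": MASS}[
            lesion_type
        ]
        lo, hi = _SIZE_RANGES_MM[group]
    except (ValueError, KeyError):
        raise ValueError(
            f"unknown class-mix category {category!r}; expected 'normal' or "
            "'<pathology>_<type>_<sizegroup>' e.g. 'malignant_mass_large'"
        ) from None
    max_mm = min(
        hi,
        0.45 * min(config.image_height_px, config.image_width_px)
        * config.pixel_spacing_um / 1000.0,
    )
    if max_mm < lo:
        raise ValueError(f"image too small for {group} lesions at this spacing")
    mm = float(rng.uniform(lo, max_mm))
    assert size_group_from_mm(mm) == group
    return default_lesion_spec(lesion_type, pathology, mm)


def generate_dataset(
    config_template: PhantomConfig,
    n_images: int,
    class_mix: dict[str, float],
    seed: int,
    out_dir,
    val_fraction: float = 0.3,
) -> pd.DataFrame:
    """Write `n_images` phantoms + sidecars + a CSV manifest to `out_dir`.

    `class_mix` maps image categories ("normal" or
    "<pathology>_<type>_<sizegroup>") to proportions summing to 1. The
    train/val split is stratified within each category.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    counts = _largest_remainder_counts(class_mix, n_images)
    seeds = rng.integers(0, 2**31 - 1, size=n_images)

    rows = []
    idx = 0
    for category in counts:
        n_cat = counts[category]
        n_train = int(np.ceil((1.0 - val_fraction) * n_cat))
        for j in range(n_cat):
            spec = _category_spec(category, config_template, rng)
            cfg = replace(
                config_template,
                lesion_specs=() if spec is None else (spec,),
                seed=int(seeds[idx]),
            )
            img = generate_phantom(cfg)
            image_path = out_dir / f"phantom_{idx:04d}.png"
            annotation_path = out_dir / f"phantom_{idx:04d}.json"
            write_annotated_image(img, image_path, annotation_path)
            rows.append(
                {
                    "image_path": str(image_path),
                    "annotation_path": str(annotation_path),
                    "split": "train" if j < n_train else "val",
                    "label": img.image_label,
                    "category": category,
                }
            )
            idx += 1
    manifest = pd.DataFrame(rows)
    write_manifest(manifest, out_dir / "manifest.csv")
    return manifest
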