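"""Patch-dataset construction from lesion-annotated images.

From every image containing a lesion, the extractor produces:

* one "fixed" patch centred on each lesion — or, when the lesion exceeds
  the patch in some dimension, a grid of non-overlapping patches tiling
  the lesion's bounding box so that every part of the lesion is seen;
* "random" lesion patches centred on random lesion-mask pixels, accepted
  greedily only while the pairwise IoU with previously accepted lesion
  patches stays below ``iou_max`` (default 0.5), topping the per-lesion
  count up to the configured floor (at least ten lesion patches for a
  single-lesion image);
* exactly ``n_background`` (default ten) background patches whose boxes
  intersect no lesion mask and lie at least half inside the breast
  foreground.

Patches are labelled into five classes: background, benign/malignant
calcification, benign/malignant mass. A patch overlapping several lesions
takes the class of the lesion with the largest mask overlap (ties go to
annotation order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .data_model import AnnotatedImage, LesionAnnotation, read_annotated_image

BACKGROUND = "background"
CLASSES = ["background", "benign_calc", "malignant_calc", "benign_mass", "malignant_mass"]

FIXED, GRID, RANDOM = "fixed", "grid", "random"

Box = tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open


class PatchPlacementError(RuntimeError):
    pass


@dataclass(frozen=True)
class PatchRecord:
    source_image_id: str
    box: Box
    label: str
    provenance: str
    lesion_type: str | None = None  # of the labelling lesion
    size_group: str | None = None

    def __post_init__(self):
        if self.label not in CLASSES:
            raise ValueError(f"unknown label {self.label!r}")


@dataclass(frozen=True)
class ExtractionConfig:
    patch_size_px: int = 512
    n_background: int = 10
    min_lesion_patches: int = 10  # per-image floor of lesion patches
    iou_max: float = 0.5
    seed: int = 0
    bg_min_foreground_frac: float = 0.5
    iou_against_all: bool = True  # constrain random patches against fixed/grid too
    max_rejections: int = 100
    extra_columns: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.patch_size_px <= 0:
            raise ValueError("patch_size_px must be positive")
        if not 0 < self.iou_max <= 1:
            raise ValueError("iou_max must be in (0, 1]")


def iou(box_a: Box, box_b: Box) -> float:
    """Intersection over union of two half-open pixel boxes."""
    for box in (box_a, box_b):
        r0, c0, r1, c1 = box
        if r1 <= r0 or c1 <= c0:
            raise ValueError(f"degenerate box {box}")
    ra = max(box_a[0], box_b[0]), max(box_a[1], box_b[1])
    rb = min(box_a[2], box_b[2]), min(box_a[3], box_b[3])
    ih = max(rb[0] - ra[0], 0)
    iw = max(rb[1] - ra[1], 0)
    inter = ih * iw
    area = lambda b: (b[2] - b[0]) * (b[3] - b[1])  # noqa: E731
    union = area(box_a) + area(box_b) - inter
    return inter / union


def _clamp_box(center_r: int, center_c: int, size: int, image_shape) -> Box:
    """Size×size box centred at (r, c), shifted inward at image borders."""
    h, w = image_shape
    if size > h or size > w:
        raise PatchPlacementError(f"patch size {size} exceeds image {h}x{w}")
    r0 = int(np.clip(center_r - size // 2, 0, h - size))
    c0 = int(np.clip(center_c - size // 2, 0, w - size))
    return (r0, c0, r0 + size, c0 + size)


def grid_decompose(lesion_bbox: Box, patch_size: int, image_shape=None) -> list[Box]:
    """Tile a lesion bbox larger than the patch with ceil(h/p) × ceil(w/p)
    full-size boxes, anchored at the bbox top-left; the last row/column is
    shifted inward to stay on the image when `image_shape` is given."""
    r0, c0, r1, c1 = lesion_bbox
    bh, bw = r1 - r0, c1 - c0
    if bh <= patch_size and bw <= patch_size:
        raise ValueError("lesion bbox does not exceed the patch size; use a fixed patch")
    n = int(np.ceil(bh / patch_size))
    m = int(np.ceil(bw / patch_size))
    if image_shape is not None and (patch_size > image_shape[0] or patch_size > image_shape[1]):
        raise PatchPlacementError("patch larger than image")
    boxes = []
    for i in range(n):
        for j in range(m):
            rr = r0 + i * patch_size
            cc = c0 + j * patch_size
            if image_shape is not None:
                rr = min(rr, image_shape[0] - patch_size)
                cc = min(cc, image_shape[1] - patch_size)
                rr, cc = max(rr, 0), max(cc, 0)
            boxes.append((rr, cc, rr + patch_size, cc + patch_size))
    return boxes


def _overlap_area(box: Box, lesion: LesionAnnotation) -> int:
    """Pixels of the lesion's mask inside the box."""
    r0 = max(box[0], lesion.bbox[0])
    c0 = max(box[1], lesion.bbox[1])
    r1 = min(box[2], lesion.bbox[2])
    c1 = min(box[3], lesion.bbox[3])
    if r1 <= r0 or c1 <= c0:
        return 0
    lr0, lc0 = lesion.bbox[0], lesion.bbox[1]
    return int(lesion.mask[r0 - lr0 : r1 - lr0, c0 - lc0 : c1 - lc0].sum())


def assign_label_index(box: Box, lesions: list[LesionAnnotation]) -> int | None:
    """Index of the lesion with the largest mask overlap (first on ties);
    None when the box intersects no lesion mask."""
    overlaps = [_overlap_area(box, les) for les in lesions]
    if not overlaps or max(overlaps) == 0:
        return None
    return int(np.argmax(overlaps))


def assign_label(box: Box, lesions: list[LesionAnnotation]) -> str:
    """Class of the overlap-dominant lesion; background if none overlaps."""
    idx = assign_label_index(box, lesions)
    return BACKGROUND if idx is None else lesions[idx].class_label


def _lesion_record(image: AnnotatedImage, image_id: str, box: Box, provenance: str
                   ) -> PatchRecord:
    idx = assign_label_index(box, image.lesions)
    if idx is None:
        return PatchRecord(image_id, box, BACKGROUND, provenance)
    les = image.lesions[idx]
    return PatchRecord(
        image_id,
        box,
        les.class_label,
        provenance,
        lesion_type=les.lesion_type,
        size_group=les.size_group(image.pixel_spacing_um),
    )


def _base_boxes(image: AnnotatedImage, lesion: LesionAnnotation, config: ExtractionConfig):
    """Mandatory patches of a lesion: one centred fixed patch when it fits,
    otherwise a grid tiling its bbox."""
    size = config.patch_size_px
    r0, c0, r1, c1 = lesion.bbox
    if r1 - r0 > size or c1 - c0 > size:
        return grid_decompose(lesion.bbox, size, image.shape), GRID
    return [_clamp_box((r0 + r1) // 2, (c0 + c1) // 2, size, image.shape)], FIXED


def _random_boxes(
    image: AnnotatedImage,
    lesion: LesionAnnotation,
    config: ExtractionConfig,
    n_random: int,
    constraint_pool: list[Box],
    rng: np.random.Generator,
) -> list[Box]:
    """Greedy IoU-constrained sampling of lesion-centred patches; gives up
    after `max_rejections` consecutive rejections (the IoU bound caps the
    achievable count for lesions far smaller than the patch)."""
    r0, c0 = lesion.bbox[0], lesion.bbox[1]
    mask_pixels = np.argwhere(lesion.mask)
    accepted: list[Box] = []
    rejections = 0
    while len(accepted) < n_random and rejections < config.max_rejections:
        pr, pc = mask_pixels[rng.integers(len(mask_pixels))]
        box = _clamp_box(r0 + int(pr), c0 + int(pc), config.patch_size_px, image.shape)
        if all(iou(box, other) < config.iou_max for other in constraint_pool + accepted):
            accepted.append(box)
            rejections = 0
        else:
            rejections += 1
    return accepted


def extract_lesion_patches(
    image: AnnotatedImage,
    lesion: LesionAnnotation,
    config: ExtractionConfig,
    existing_boxes: list[Box] | None = None,
    image_id: str = "image",
    rng: np.random.Generator | None = None,
) -> list[PatchRecord]:
    """Fixed/grid plus IoU-constrained random patches for one lesion."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    base_boxes, base_prov = _base_boxes(image, lesion, config)
    records = [_lesion_record(image, image_id, b, base_prov) for b in base_boxes]
    pool = list(existing_boxes or []) + base_boxes if config.iou_against_all \
        else list(existing_boxes or [])
    n_random = max(0, config.min_lesion_patches - len(base_boxes))
    randoms = _random_boxes(image, lesion, config, n_random, pool, rng)
    records += [_lesion_record(image, image_id, b, RANDOM) for b in randoms]
    return records


def foreground_mask(image: AnnotatedImage) -> np.ndarray:
    """Breast foreground by Otsu thresholding of the intensity histogram."""
    pixels = np.asarray(image.pixels, dtype=np.float64)
    thr = threshold_otsu(pixels)
    return pixels > thr


def extract_background_patches(
    image: AnnotatedImage,
    lesions: list[LesionAnnotation],
    config: ExtractionConfig,
    image_id: str = "image",
    rng: np.random.Generator | None = None,
) -> list[PatchRecord]:
    """Exactly ``n_background`` patches with zero lesion-mask intersection,
    centred on breast-foreground pixels and ≥50% inside the foreground."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fg = foreground_mask(image)
    candidates = np.argwhere(fg)
    if len(candidates) == 0:
        raise PatchPlacementError("no breast foreground found")
    size = config.patch_size_px
    records: list[PatchRecord] = []
    budget = 1000 * config.n_background
    tries = 0
    while len(records) < config.n_background and tries < budget:
        tries += 1
        pr, pc = candidates[rng.integers(len(candidates))]
        box = _clamp_box(int(pr), int(pc), size, image.shape)
        if any(_overlap_area(box, les) > 0 for les in lesions):
            continue
        frac = fg[box[0] : box[2], box[1] : box[3]].mean()
        if frac < config.bg_min_foreground_frac:
            continue
        records.append(PatchRecord(image_id, box, BACKGROUND, BACKGROUND))
    if len(records) < config.n_background:
        raise PatchPlacementError(
            f"placed only {len(records)}/{config.n_background} background patches "
            f"after {budget} tries"
        )
    return records


def extract_image_patches(
    image: AnnotatedImage, config: ExtractionConfig, image_id: str = "image"
) -> list[PatchRecord]:
    """All lesion + background patches of one image.

    All mandatory fixed/grid boxes are collected first so that every
    random patch is IoU-checked against every other lesion patch of the
    image, whichever lesion it came from."""
    rng = np.random.default_rng(config.seed)
    records: list[PatchRecord] = []
    per_lesion_bases = []
    pool: list[Box] = []
    for lesion in image.lesions:
        bases, prov = _base_boxes(image, lesion, config)
        per_lesion_bases.append((lesion, bases))
        records += [_lesion_record(image, image_id, b, prov) for b in bases]
        if config.iou_against_all:
            pool += bases
    for lesion, bases in per_lesion_bases:
        n_random = max(0, config.min_lesion_patches - len(bases))
        randoms = _random_boxes(image, lesion, config, n_random, pool, rng)
        records += [_lesion_record(image, image_id, b, RANDOM) for b in randoms]
        pool += randoms
    records += extract_background_patches(
        image, image.lesions, config, image_id=image_id, rng=rng
    )
    return records


def records_to_frame(records: list[PatchRecord], config: ExtractionConfig) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "image_id": [r.source_image_id for r in records],
            "r0": [r.box[0] for r in records],
            "c0": [r.box[1] for r in records],
            "size": config.patch_size_px,
            "label": [r.label for r in records],
            "provenance": [r.provenance for r in records],
            "lesion_type": [r.lesion_type for r in records],
            "size_group": [r.size_group for r in records],
            "seed": config.seed,
        }
    )


def build_patch_dataset(
    manifest: pd.DataFrame, config: ExtractionConfig
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Concatenate per-image patch records; returns (patch manifest,
    5-class histogram for the oversampler). Per-image failures propagate
    with the offending image id."""
    frames = []
    for _, row in manifest.iterrows():
        image_id = str(row["image_path"])
        try:
            image = read_annotated_image(row["image_path"], row["annotation_path"])
            records = extract_image_patches(image, config, image_id=image_id)
        except Exception as e:
            raise RuntimeError(f"patch extraction failed for {image_id}: {e}") from e
        df = records_to_frame(records, config)
        df["split"] = row.get("split", "train")
        frames.append(df)
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(
            columns=[
                "image_id", "r0", "c0", "size", "label", "provenance",
                "lesion_type", "size_group", "seed", "split",
            ]
        )
    histogram = {c: int((out["label"] == c).sum()) for c in CLASSES}
    return out, histogram
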