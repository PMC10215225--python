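"""Core domain types and annotation I/O.

An :class:`AnnotatedImage` is a 2D grayscale mammogram (or phantom) with a
physical pixel spacing in μm/pixel, a list of lesion annotations and an
image-level cancer label. Lesions carry a binary mask (stored run-length
encoded inside their tight bounding box), a type (mass / calcification)
and a pathology (benign / malignant).

Lesions are stratified into three size groups by their maximal dimension:
small (< 25.6 mm), medium (25.6–51.2 mm) and large (≥ 51.2 mm) — i.e.
256 / 512 pixels at the reference spacing of 100 μm/pixel. Boundary values
belong to the larger group. "Maximal dimension" is the larger side of the
mask's tight bounding box.

Coordinates are 0-based (row, col); boxes are half-open
``(r0, c0, r1, c1)`` so that areas are simple differences.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

SCHEMA_VERSION = 1

MASS = "mass"
CALCIFICATION = "calcification"
BENIGN = "benign"
MALIGNANT = "malignant"

SMALL, MEDIUM, LARGE = "small", "medium", "large"
SMALL_MAX_MM = 25.6
MEDIUM_MAX_MM = 51.2

REFERENCE_SPACING_UM = 100.0


class AnnotationSchemaError(ValueError):
    """Raised when an annotation file violates the JSON schema."""


def mm_to_px(length_mm: float, spacing_um: float) -> float:
    """Convert a physical length in mm to pixels at `spacing_um` μm/pixel."""
    if spacing_um <= 0:
        raise ValueError("pixel spacing must be positive")
    return length_mm * 1000.0 / spacing_um


def px_to_mm(length_px: float, spacing_um: float) -> float:
    if spacing_um <= 0:
        raise ValueError("pixel spacing must be positive")
    return length_px * spacing_um / 1000.0


def size_group_from_mm(max_dim_mm: float) -> str:
    if max_dim_mm < SMALL_MAX_MM:
        return SMALL
    if max_dim_mm < MEDIUM_MAX_MM:
        return MEDIUM
    return LARGE


# -- run-length encoding ----------------------------------------------------

def rle_encode(mask: np.ndarray) -> dict:
    """Row-major RLE of a binary 2D array: alternating run lengths starting
    with the number of leading zeros."""
    mask = np.asarray(mask, dtype=bool)
    flat = mask.ravel()
    if flat.size == 0:
        return {"size": list(mask.shape), "counts": []}
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    counts = np.diff(bounds).tolist()
    if flat[0]:
        counts = [0] + counts
    return {"size": [int(s) for s in mask.shape], "counts": [int(c) for c in counts]}


def rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos, val = 0, False
    for c in rle["counts"]:
        if val:
            flat[pos : pos + c] = True
        pos += c
        val = not val
    if pos != h * w:
        raise AnnotationSchemaError("rle_mask: counts do not sum to mask size")
    return flat.reshape(h, w)


@dataclass
class LesionAnnotation:
    """One annotated lesion: bbox-local binary mask + taxonomy."""

    mask: np.ndarray  # bool, shape = bbox (r1-r0, c1-c0)
    bbox: tuple[int, int, int, int]  # (r0, c0, r1, c1), half-open
    lesion_type: str
    pathology: str

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        if self.mask.shape != (r1 - r0, c1 - c0):
            raise ValueError("mask shape does not match bbox")
        if not self.mask.any():
            raise ValueError("lesion mask is empty")
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        if rows[0] != 0 or cols[0] != 0 or rows[-1] != self.mask.shape[0] - 1 \
                or cols[-1] != self.mask.shape[1] - 1:
            raise ValueError("bbox is not tight around the mask")
        if self.lesion_type not in (MASS, CALCIFICATION):
            raise ValueError(f"unknown lesion_type {self.lesion_type!r}")
        if self.pathology not in (BENIGN, MALIGNANT):
            raise ValueError(f"unknown pathology {self.pathology!r}")

    @classmethod
    def from_full_mask(cls, full_mask: np.ndarray, lesion_type: str, pathology: str):
        full_mask = np.asarray(full_mask, dtype=bool)
        rows = np.flatnonzero(full_mask.any(axis=1))
        cols = np.flatnonzero(full_mask.any(axis=0))
        if rows.size == 0:
            raise ValueError("lesion mask is empty")
        bbox = (int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1)
        local = full_mask[bbox[0] : bbox[2], bbox[1] : bbox[3]]
        return cls(local, bbox, lesion_type, pathology)

    @property
    def max_dim_px(self) -> int:
        r0, c0, r1, c1 = self.bbox
        return max(r1 - r0, c1 - c0)

    def max_dim_mm(self, spacing_um: float) -> float:
        return px_to_mm(self.max_dim_px, spacing_um)

    def size_group(self, spacing_um: float) -> str:
        return size_group_from_mm(self.max_dim_mm(spacing_um))

    def full_mask(self, image_shape) -> np.ndarray:
        out = np.zeros(image_shape, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        out[r0:r1, c0:c1] = self.mask
        return out

    @property
    def class_label(self) -> str:
        short = "calc" if self.lesion_type == CALCIFICATION else "mass"
        return f"{self.pathology}_{short}"


def size_group(lesion: LesionAnnotation, spacing_um: float) -> str:
    """Size group of a lesion at a given pixel spacing."""
    return lesion.size_group(spacing_um)


CANCER = "cancer"
NO_CANCER = "no-cancer"


@dataclass
class AnnotatedImage:
    pixels: np.ndarray  # 2D uint16 (or float in [0,1] before quantisation)
    pixel_spacing_um: float
    lesions: list[LesionAnnotation] = field(default_factory=list)

    def __post_init__(self):
        if self.pixel_spacing_um <= 0:
            raise ValueError("pixel_spacing_um must be positive")
        h, w = self.pixels.shape
        for les in self.lesions:
            r0, c0, r1, c1 = les.bbox
            if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
                raise ValueError("lesion bbox outside image bounds")

    @property
    def image_label(self) -> str:
        """Cancer iff any lesion is malignant (binary whole-image task)."""
        return CANCER if any(l.pathology == MALIGNANT for l in self.lesions) else NO_CANCER

    @property
    def shape(self):
        return self.pixels.shape


# -- I/O --------------------------------------------------------------------

def write_annotated_image(img: AnnotatedImage, image_path, annotation_path) -> None:
    """16-bit grayscale PNG + versioned JSON sidecar."""
    pixels = img.pixels
    if pixels.dtype != np.uint16:
        pixels = np.clip(np.round(np.asarray(pixels, dtype=np.float64) * 65535), 0, 65535).astype(
            np.uint16
        )
    iio.imwrite(Path(image_path), pixels)
    doc = {
        "schema": SCHEMA_VERSION,
        "pixel_spacing_um": float(img.pixel_spacing_um),
        "label": img.image_label,
        "lesions": [
            {
                "type": l.lesion_type,
                "pathology": l.pathology,
                "bbox": list(l.bbox),
                "rle_mask": rle_encode(l.mask),
            }
            for l in img.lesions
        ],
    }
    Path(annotation_path).write_text(json.dumps(doc))


def _require(doc: dict, key: str):
    if key not in doc:
        raise AnnotationSchemaError(f"annotation missing required field {key!r}")
    return doc[key]


def read_annotated_image(image_path, annotation_path) -> AnnotatedImage:
    pixels = np.asarray(iio.imread(Path(image_path)))
    if pixels.ndim != 2:
        raise AnnotationSchemaError("image is not single-channel 2D")
    doc = json.loads(Path(annotation_path).read_text())
    if _require(doc, "schema") != SCHEMA_VERSION:
        raise AnnotationSchemaError(f"unsupported schema version {doc['schema']}")
    spacing = _require(doc, "pixel_spacing_um")
    if not isinstance(spacing, (int, float)) or spacing <= 0:
        raise AnnotationSchemaError("pixel_spacing_um must be a positive number")
    lesions = []
    for i, ld in enumerate(_require(doc, "lesions")):
        try:
            mask = rle_decode(_require(ld, "rle_mask"))
            lesions.append(
                LesionAnnotation(
                    mask=mask,
                    bbox=tuple(_require(ld, "bbox")),
                    lesion_type=_require(ld, "type"),
                    pathology=_require(ld, "pathology"),
                )
            )
        except ValueError as e:
            raise AnnotationSchemaError(f"lesion {i}: {e}") from e
    img = AnnotatedImage(pixels=pixels, pixel_spacing_um=float(spacing), lesions=lesions)
    label = _require(doc, "label")
    if label != img.image_label:
        raise AnnotationSchemaError(
            f"label: stored {label!r} inconsistent with lesion pathologies"
        )
    return img


MANIFEST_COLUMNS = ["image_path", "annotation_path", "split", "label"]


def write_manifest(df: pd.DataFrame, path) -> None:
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    df.to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationSchemaError(f"manifest missing columns {sorted(missing)}")
    return df


def read_dicom_image(path) -> AnnotatedImage:
    """Optional DICOM reader: maps PixelSpacing (mm) to μm and applies the
    rescale slope/intercept. Annotations are not read from DICOM."""
    import pydicom

    ds = pydicom.dcmread(path)
    pixels = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    pixels = pixels * slope + intercept
    spacing_attr = getattr(ds, "PixelSpacing", None) or getattr(
        ds, "ImagerPixelSpacing", None
    )
    if spacing_attr is None:
        raise AnnotationSchemaError("DICOM file lacks PixelSpacing/ImagerPixelSpacing")
    spacing_um = float(spacing_attr[0]) * 1000.0
    return AnnotatedImage(pixels=pixels, pixel_spacing_um=spacing_um, lesions=[])
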