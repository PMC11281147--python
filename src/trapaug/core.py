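"""Domain types, YOLO-format annotation I/O and coordinate conversions.

The unit flowing through every augmentation operator is an
:class:`AnnotatedImage`: an 8-bit RGB raster together with its normalized
ground-truth boxes.  Boxes follow the YOLO sidecar convention — one
whitespace-separated line per object, ``class_id cx cy w h``, all four
geometry fields expressed as fractions of the image width/height.
Detection files carry a sixth column, the confidence.

Pixel coordinates are continuous, with the origin at the top-left corner
of the top-left pixel, x rightward and y downward; pixel ``(i, j)`` spans
``[j, j+1) x [i, i+1)``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "TrapAugError",
    "AnnotationFormatError",
    "ValidationError",
    "Box",
    "Detection",
    "AnnotatedImage",
    "PROVENANCE_TAGS",
    "MIN_IMAGE_SIDE",
    "read_yolo_annotation",
    "write_yolo_annotation",
    "box_to_pixel",
    "pixel_to_box",
    "channel_histograms",
    "validate_raster",
    "load_image",
    "save_image",
    "read_dataset",
    "write_dataset",
]

#: Provenance tags an AnnotatedImage may carry.
PROVENANCE_TAGS = frozenset(
    {
        "original",
        "gamma",
        "brightness_contrast",
        "noise",
        "translation",
        "rotation",
        "mosaic",
        "modified_mosaic",
    }
)

#: Augmentation geometry is meaningless below this raster side length.
MIN_IMAGE_SIDE = 8


class TrapAugError(Exception):
    """Base class for all errors raised by trapaug."""


class AnnotationFormatError(TrapAugError, ValueError):
    """A YOLO annotation line is structurally malformed."""


class ValidationError(TrapAugError, ValueError):
    """A value violates a domain invariant (range, count, shape...)."""


@dataclass(frozen=True)
class Box:
    """One normalized axis-aligned ground-truth box, YOLO convention.

    ``cx, cy`` locate the box center and ``w, h`` its extents, all as
    fractions of the image width/height.
    """

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.class_id < 0:
            raise ValidationError(f"class_id must be non-negative, got {self.class_id}")
        if not (self.w > 0 and self.h > 0):
            raise ValidationError(f"box extents must be positive, got w={self.w}, h={self.h}")

    @property
    def corners(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max) in normalized coordinates."""
        return (
            self.cx - self.w / 2,
            self.cy - self.h / 2,
            self.cx + self.w / 2,
            self.cy + self.h / 2,
        )

    @property
    def area(self) -> float:
        return self.w * self.h

    def is_contained(self, tol: float = 1e-9) -> bool:
        """True if the box lies inside the unit square (post-clipping invariant)."""
        x0, y0, x1, y1 = self.corners
        return x0 >= -tol and y0 >= -tol and x1 <= 1 + tol and y1 <= 1 + tol

    def validate(self) -> None:
        """Raise unless all coordinates are in range and the box is contained."""
        for name in ("cx", "cy", "w", "h"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class Detection:
    """A predicted box with a confidence score in [0, 1]."""

    box: Box
    confidence: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            raise ValidationError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class AnnotatedImage:
    """An RGB raster plus its ground-truth boxes and a provenance tag.

    ``meta`` carries the audit trail of the operation that produced the
    image (sampled parameters, source ids); it is free-form and is
    persisted in dataset manifests.
    """

    image: np.ndarray
    boxes: list[Box]
    id: str
    provenance: str = "original"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_raster(self.image)
        if self.provenance not in PROVENANCE_TAGS:
            raise ValidationError(f"unknown provenance tag {self.provenance!r}")

    @property
    def height(self) -> int:
        return int(self.image.shape[0])

    @property
    def width(self) -> int:
        return int(self.image.shape[1])

    def copy_with(self, **kwargs) -> "AnnotatedImage":
        """Functional update; the raster is copied unless replaced."""
        if "image" not in kwargs:
            kwargs["image"] = self.image.copy()
        if "boxes" not in kwargs:
            kwargs["boxes"] = list(self.boxes)
        return replace(self, **kwargs)


def validate_raster(image: np.ndarray) -> None:
    """Check the 8-bit three-channel contract and the minimum side length."""
    if not isinstance(image, np.ndarray):
        raise ValidationError("raster must be a numpy array")
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValidationError(f"raster must be HxWx3, got shape {image.shape}")
    if image.dtype != np.uint8:
        raise ValidationError(f"raster must be uint8, got {image.dtype}")
    h, w = image.shape[:2]
    if h < MIN_IMAGE_SIDE or w < MIN_IMAGE_SIDE:
        raise ValidationError(f"raster {h}x{w} smaller than minimum side {MIN_IMAGE_SIDE}")


# ---------------------------------------------------------------------------
# YOLO sidecar I/O


def read_yolo_annotation(path: str | Path, is_detection: bool = False):
    """Parse a YOLO label file into Box objects (or Detection with 6 columns).

    Each non-empty line must have exactly 5 fields (ground truth) or 6
    (detections, last field the confidence).  Lines are returned in file
    order.  A wrong field count raises :class:`AnnotationFormatError`
    naming the 1-based line number; out-of-range coordinates raise
    :class:`ValidationError`.
    """
    n_fields = 6 if is_detection else 5
    out: list = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != n_fields:
                raise AnnotationFormatError(
                    f"{path}: line {lineno}: expected {n_fields} fields, got {len(parts)}"
                )
            try:
                class_id = int(parts[0])
                values = [float(p) for p in parts[1:]]
            except ValueError as exc:
                raise AnnotationFormatError(f"{path}: line {lineno}: {exc}") from exc
            cx, cy, w, h = values[:4]
            for name, v in zip(("cx", "cy", "w", "h"), (cx, cy, w, h)):
                if not 0.0 <= v <= 1.0:
                    raise ValidationError(f"{path}: line {lineno}: {name}={v} outside [0, 1]")
            box = Box(class_id, cx, cy, w, h)  # raises on w/h <= 0
            if is_detection:
                conf = values[4]
                if not 0.0 <= conf <= 1.0:
                    raise ValidationError(
                        f"{path}: line {lineno}: confidence {conf} outside [0, 1]"
                    )
                out.append(Detection(box, conf))
            else:
                out.append(box)
    return out


def write_yolo_annotation(boxes: Sequence[Box | Detection], path: str | Path) -> None:
    """Write boxes (or detections) as a YOLO label file, 6 decimal places.

    Round-trips with :func:`read_yolo_annotation` to 1e-6.
    """
    lines = []
    for b in boxes:
        if isinstance(b, Detection):
            box, conf = b.box, b.confidence
            lines.append(
                f"{box.class_id} {box.cx:.6f} {box.cy:.6f} {box.w:.6f} {box.h:.6f} {conf:.6f}"
            )
        else:
            lines.append(f"{b.class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}")
    Path(path).write_text("".join(line + "\n" for line in lines), encoding="utf-8")


# ---------------------------------------------------------------------------
# Coordinate conversions


def box_to_pixel(box: Box, width: int, height: int) -> tuple[float, float, float, float]:
    """Normalized box -> continuous pixel rectangle (x_min, y_min, x_max, y_max)."""
    x0, y0, x1, y1 = box.corners
    return (x0 * width, y0 * height, x1 * width, y1 * height)


def pixel_to_box(
    rect: tuple[float, float, float, float], width: int, height: int, class_id: int = 0
) -> Box:
    """Continuous pixel rectangle -> normalized Box. Exact inverse of box_to_pixel."""
    x0, y0, x1, y1 = rect
    return Box(
        class_id,
        (x0 + x1) / (2 * width),
        (y0 + y1) / (2 * height),
        (x1 - x0) / width,
        (y1 - y0) / height,
    )


# ---------------------------------------------------------------------------
# Channel histograms


def channel_histograms(images: Iterable[AnnotatedImage | np.ndarray], bins: int = 32) -> np.ndarray:
    """Pooled per-channel intensity histograms, each normalized to sum 1.

    Trap images shot under comparable conditions show near-identical red,
    green and blue distributions, which is what justifies applying one
    photometric mapping to all three channels; this utility makes that
    inspection reproducible.

    Returns an array of shape (3, bins) ordered (red, green, blue).
    """
    if bins < 2:
        raise ValidationError(f"bins must be >= 2, got {bins}")
    counts = np.zeros((3, bins), dtype=np.float64)
    n = 0
    for img in images:
        arr = img.image if isinstance(img, AnnotatedImage) else img
        validate_raster(arr)
        for c in range(3):
            hist, _ = np.histogram(arr[:, :, c], bins=bins, range=(0, 256))
            counts[c] += hist
        n += 1
    if n == 0:
        raise ValidationError("channel_histograms requires at least one image")
    return counts / counts.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Dataset layout: images/ and labels/ sibling directories, matching basenames


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG file as an HxWx3 uint8 array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"), dtype=np.uint8)


def save_image(image: np.ndarray, path: str | Path) -> None:
    validate_raster(image)
    Image.fromarray(image, mode="RGB").save(path)


def read_dataset(root: str | Path) -> list[AnnotatedImage]:
    """Load an images/ + labels/ directory pair into AnnotatedImages.

    Image files without a label sidecar get an empty box list.
    """
    root = Path(root)
    img_dir, lbl_dir = root / "images", root / "labels"
    if not img_dir.is_dir():
        raise ValidationError(f"missing images directory: {img_dir}")
    out = []
    for p in sorted(img_dir.iterdir()):
        if p.suffix.lower() not in {".png", ".jpg", ".jpeg"}:
            continue
        label = lbl_dir / (p.stem + ".txt")
        boxes = read_yolo_annotation(label) if label.exists() else []
        out.append(AnnotatedImage(load_image(p), boxes, id=p.stem))
    if not out:
        raise ValidationError(f"no images found under {img_dir}")
    return out


def write_dataset(images: Sequence[AnnotatedImage], root: str | Path) -> dict:
    """Write the images/ + labels/ layout plus a JSON manifest; returns the manifest."""
    if not images:
        raise ValidationError("cannot write an empty dataset")
    root = Path(root)
    img_dir, lbl_dir = root / "images", root / "labels"
    img_dir.mkdir(parents=True, exist_ok=True)
    lbl_dir.mkdir(parents=True, exist_ok=True)
    seen: set[str] = set()
    records = []
    for ai in images:
        if ai.id in seen:
            raise ValidationError(f"duplicate image id {ai.id!r}")
        seen.add(ai.id)
        save_image(ai.image, img_dir / f"{ai.id}.png")
        write_yolo_annotation(ai.boxes, lbl_dir / f"{ai.id}.txt")
        records.append({"id": ai.id, "provenance": ai.provenance, **ai.meta})
    manifest = {"n_images": len(images), "images": records}
    with open(root / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
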