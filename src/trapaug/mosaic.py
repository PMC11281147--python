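"""Mosaic composition of four annotated images, plain and modified.

A mosaic stitches crops of four source images around a randomly offset
center point, raising the density of small objects per training image.
Each source is first uniformly rescaled to the square output canvas;
the center splits the canvas into four quadrant rectangles, and quadrant
q shows the same-corner-anchored crop of source q (top-left quadrant =
source 1's top-left region, and so on; a random-window crop is available
behind a switch).  Source boxes are mapped through the rescale and crop,
clipped to their quadrant, and dropped under the standard visibility
rule.

The modified mosaic additionally applies, independently per sub-image
and before composition, a brightness-contrast adjustment with
probability 0.8 and multiplicative Gaussian noise with probability 0.3 —
photometric diversity folded into the geometric recombination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from PIL import Image

from .core import AnnotatedImage, Box, ValidationError, box_to_pixel, pixel_to_box
from .geometric import MIN_BOX_SIDE_PX, MIN_VISIBILITY
from .photometric import (
    NoiseParams,
    add_gaussian_noise,
    brightness_contrast,
    sample_photometric_params,
)

__all__ = ["MosaicSpec", "make_mosaic", "make_modified_mosaic", "sample_mosaic_center"]

_QUADRANTS = ("top_left", "top_right", "bottom_left", "bottom_right")


@dataclass(frozen=True)
class MosaicSpec:
    """Configuration of a 4-image mosaic.

    ``center`` is the normalized split point; when None it is sampled
    uniformly within ``max_center_offset`` of (0.5, 0.5) per axis (the
    crop offset may reach 30% of the merged-image size by default).
    """

    out_size: int = 320
    center: tuple[float, float] | None = None
    max_center_offset: float = 0.3
    p_brightness_contrast: float = 0.8
    p_noise: float = 0.3
    crop_anchor: str = "corner"  # "corner" or "random"

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_center_offset < 0.5:
            raise ValidationError(
                f"max_center_offset must be in [0, 0.5), got {self.max_center_offset}"
            )
        for name in ("p_brightness_contrast", "p_noise"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name}={p} outside [0, 1]")
        if self.crop_anchor not in ("corner", "random"):
            raise ValidationError(f"crop_anchor must be 'corner' or 'random', got {self.crop_anchor}")
        if self.center is not None:
            cx, cy = self.center
            if abs(cx - 0.5) > self.max_center_offset or abs(cy - 0.5) > self.max_center_offset:
                raise ValidationError(
                    f"center {self.center} outside the allowed offset {self.max_center_offset}"
                )
        if self.out_size < 8:
            raise ValidationError(f"out_size must be >= 8, got {self.out_size}")


def sample_mosaic_center(
    max_offset: float, rng: np.random.Generator
) -> tuple[float, float]:
    """Draw the mosaic center (cx, cy) ~ U(0.5 - max_offset, 0.5 + max_offset)^2."""
    if not 0.0 <= max_offset < 0.5:
        raise ValidationError(f"max_offset must be in [0, 0.5), got {max_offset}")
    cx = rng.uniform(0.5 - max_offset, 0.5 + max_offset)
    cy = rng.uniform(0.5 - max_offset, 0.5 + max_offset)
    return (cx, cy)


def _rescale(src: AnnotatedImage, size: int) -> np.ndarray:
    if src.image.shape[0] == size and src.image.shape[1] == size:
        return src.image.copy()
    im = Image.fromarray(src.image, mode="RGB").resize((size, size), Image.BILINEAR)
    return np.asarray(im, dtype=np.uint8)


def _quadrant_rects(xc: int, yc: int, s: int) -> list[tuple[int, int, int, int]]:
    """Canvas rectangles (x0, y0, x1, y1) in TL, TR, BL, BR order."""
    return [(0, 0, xc, yc), (xc, 0, s, yc), (0, yc, xc, s), (xc, yc, s, s)]


def _compose(
    rasters: Sequence[np.ndarray],
    box_lists: Sequence[list[Box]],
    center: tuple[float, float],
    windows: Sequence[tuple[int, int]],
    s: int,
) -> tuple[np.ndarray, list[Box]]:
    xc = int(round(center[0] * s))
    yc = int(round(center[1] * s))
    canvas = np.zeros((s, s, 3), dtype=np.uint8)
    out_boxes: list[Box] = []
    for (qx0, qy0, qx1, qy1), raster, boxes, (ox, oy) in zip(
        _quadrant_rects(xc, yc, s), rasters, box_lists, windows
    ):
        qw, qh = qx1 - qx0, qy1 - qy0
        if qw <= 0 or qh <= 0:
            continue
        canvas[qy0:qy1, qx0:qx1] = raster[oy : oy + qh, ox : ox + qw]
        shift_x, shift_y = qx0 - ox, qy0 - oy
        for b in boxes:
            x0, y0, x1, y1 = box_to_pixel(b, s, s)
            x0, y0, x1, y1 = x0 + shift_x, y0 + shift_y, x1 + shift_x, y1 + shift_y
            pre_area = (x1 - x0) * (y1 - y0)
            cx0, cy0 = max(x0, float(qx0)), max(y0, float(qy0))
            cx1, cy1 = min(x1, float(qx1)), min(y1, float(qy1))
            cw, ch = cx1 - cx0, cy1 - cy0
            if cw < MIN_BOX_SIDE_PX or ch < MIN_BOX_SIDE_PX:
                continue
            if pre_area <= 0 or (cw * ch) / pre_area < MIN_VISIBILITY - 1e-9:
                continue
            out_boxes.append(pixel_to_box((cx0, cy0, cx1, cy1), s, s, class_id=b.class_id))
    return canvas, out_boxes


def _draw_windows(
    spec: MosaicSpec, center: tuple[float, float], rng: np.random.Generator
) -> list[tuple[int, int]]:
    s = spec.out_size
    xc, yc = int(round(center[0] * s)), int(round(center[1] * s))
    windows = []
    for qx0, qy0, qx1, qy1 in _quadrant_rects(xc, yc, s):
        qw, qh = qx1 - qx0, qy1 - qy0
        if spec.crop_anchor == "corner":
            # same-corner-anchored crop lands at the same canvas position
            windows.append((qx0, qy0))
        else:
            ox = int(rng.integers(0, s - qw + 1)) if qw < s else 0
            oy = int(rng.integers(0, s - qh + 1)) if qh < s else 0
            windows.append((ox, oy))
    return windows


def _check_sources(sources: Sequence[AnnotatedImage]) -> None:
    if len(sources) != 4:
        raise ValidationError(f"mosaic needs exactly 4 source images, got {len(sources)}")


def make_mosaic(
    sources: Sequence[AnnotatedImage],
    spec: MosaicSpec,
    rng: np.random.Generator,
    id: str | None = None,
) -> AnnotatedImage:
    """Compose four annotated images into one mosaic around a split center.

    Sources fill the quadrants in (top-left, top-right, bottom-left,
    bottom-right) order.  Fixed generator state gives a bit-identical
    result.
    """
    _check_sources(sources)
    center = spec.center if spec.center is not None else sample_mosaic_center(
        spec.max_center_offset, rng
    )
    windows = _draw_windows(spec, center, rng)
    rasters = [_rescale(s, spec.out_size) for s in sources]
    canvas, boxes = _compose(rasters, [s.boxes for s in sources], center, windows, spec.out_size)
    return AnnotatedImage(
        canvas,
        boxes,
        id=id or "mosaic_" + "+".join(s.id for s in sources),
        provenance="mosaic",
        meta={"source_ids": [s.id for s in sources], "center": list(center)},
    )


def make_modified_mosaic(
    sources: Sequence[AnnotatedImage],
    spec: MosaicSpec,
    rng: np.random.Generator,
    id: str | None = None,
) -> AnnotatedImage:
    """Mosaic with stochastic photometric transforms on the sub-images.

    Independently per sub-image, brightness-contrast adjustment is applied
    with probability ``spec.p_brightness_contrast`` (parameters freshly
    drawn from the standard photometric sampler) and multiplicative
    Gaussian noise with probability ``spec.p_noise``; both may hit the
    same sub-image.  Composition randomness (center, crop windows) is
    consumed before any photometric draw, so with both probabilities at
    zero the output is bit-identical to :func:`make_mosaic` under the
    same seed.
    """
    _check_sources(sources)
    center = spec.center if spec.center is not None else sample_mosaic_center(
        spec.max_center_offset, rng
    )
    windows = _draw_windows(spec, center, rng)
    rasters = []
    sub_log = []
    for src, quad in zip(sources, _QUADRANTS):
        scaled = AnnotatedImage(_rescale(src, spec.out_size), list(src.boxes), id=src.id)
        entry: dict = {"quadrant": quad, "brightness_contrast": False, "noise": False}
        if rng.random() < spec.p_brightness_contrast:
            _, bc = sample_photometric_params(rng)
            scaled = brightness_contrast(scaled, bc)
            entry.update(brightness_contrast=True, alpha=bc.alpha, beta=bc.beta)
        if rng.random() < spec.p_noise:
            scaled = add_gaussian_noise(scaled, NoiseParams(), rng)
            entry["noise"] = True
        rasters.append(scaled.image)
        sub_log.append(entry)
    canvas, boxes = _compose(rasters, [s.boxes for s in sources], center, windows, spec.out_size)
    return AnnotatedImage(
        canvas,
        boxes,
        id=id or "modified_mosaic_" + "+".join(s.id for s in sources),
        provenance="modified_mosaic",
        meta={
            "source_ids": [s.id for s in sources],
            "center": list(center),
            "sub_transforms": sub_log,
        },
    )
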