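"""Spatial augmentations: translation and rotation with exact box handling.

Both operators keep the canvas size fixed and fill vacated or
out-of-source regions with mid-gray (114, 114, 114), the convention of
the detector family these datasets feed.  Boxes are transformed
analytically: translation shifts them by the exact fractional offset;
rotation maps the four corners about the canvas center and takes the
axis-aligned bounding box of the result (annotations stay axis-aligned).
Transformed boxes are clipped to the canvas; a box is dropped when its
clipped area falls below 25% of its pre-clip area or either clipped side
is under 2 pixels — slivers of insects exiting the frame are unlearnable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import AnnotatedImage, Box, ValidationError, box_to_pixel, pixel_to_box

__all__ = [
    "TranslationParams",
    "RotationParams",
    "translate",
    "rotate",
    "sample_geometric_params",
    "clip_pixel_rect",
    "FILL_COLOR",
    "SHIFT_RANGE",
    "ANGLE_RANGE",
    "MIN_BOX_SIDE_PX",
    "MIN_VISIBILITY",
]

FILL_COLOR = (114, 114, 114)
SHIFT_RANGE = (-0.2, 0.2)
ANGLE_RANGE = (-90.0, 90.0)
MIN_BOX_SIDE_PX = 2.0
MIN_VISIBILITY = 0.25


@dataclass(frozen=True)
class TranslationParams:
    """Signed shifts as fractions of image width/height."""

    dx: float
    dy: float


@dataclass(frozen=True)
class RotationParams:
    """Rotation angle in degrees about the canvas center, counter-clockwise positive."""

    theta: float


def clip_pixel_rect(
    rect: tuple[float, float, float, float],
    width: int,
    height: int,
    min_side_px: float = MIN_BOX_SIDE_PX,
    min_visibility: float = MIN_VISIBILITY,
) -> tuple[float, float, float, float] | None:
    """Clip a continuous pixel rectangle to the canvas; None if it should be dropped.

    Drop rule: clipped area < ``min_visibility`` of the pre-clip area, or a
    clipped side shorter than ``min_side_px``.
    """
    x0, y0, x1, y1 = rect
    pre_area = max(x1 - x0, 0.0) * max(y1 - y0, 0.0)
    cx0, cy0 = max(x0, 0.0), max(y0, 0.0)
    cx1, cy1 = min(x1, float(width)), min(y1, float(height))
    cw, ch = cx1 - cx0, cy1 - cy0
    if cw < min_side_px or ch < min_side_px:
        return None
    # epsilon guards boxes split exactly at the visibility threshold
    if pre_area <= 0 or (cw * ch) / pre_area < min_visibility - 1e-9:
        return None
    return (cx0, cy0, cx1, cy1)


def _clip_boxes_px(
    rects: list[tuple[Box, tuple[float, float, float, float]]], width: int, height: int
) -> list[Box]:
    out = []
    for box, rect in rects:
        clipped = clip_pixel_rect(rect, width, height)
        if clipped is not None:
            out.append(pixel_to_box(clipped, width, height, class_id=box.class_id))
    return out


def translate(img: AnnotatedImage, params: TranslationParams) -> AnnotatedImage:
    """Shift image content by (dx*width, dy*height); clip and drop boxes.

    The raster moves by the rounded integer pixel offset; boxes move by the
    exact fractional shift, so translate(dx, dy) followed by
    translate(-dx, -dy) restores every box that was never clipped.
    dx = dy = 0 is a bit-exact identity.
    """
    h, w = img.image.shape[:2]
    if params.dx == 0.0 and params.dy == 0.0:
        return img.copy_with(provenance="translation", meta={**img.meta, "dx": 0.0, "dy": 0.0})
    sx = int(math.floor(abs(params.dx) * w + 0.5)) * (1 if params.dx >= 0 else -1)
    sy = int(math.floor(abs(params.dy) * h + 0.5)) * (1 if params.dy >= 0 else -1)

    canvas = np.empty_like(img.image)
    canvas[:, :] = np.array(FILL_COLOR, dtype=np.uint8)
    src_x0, src_x1 = max(0, -sx), min(w, w - sx)
    src_y0, src_y1 = max(0, -sy), min(h, h - sy)
    if src_x1 > src_x0 and src_y1 > src_y0:
        canvas[src_y0 + sy : src_y1 + sy, src_x0 + sx : src_x1 + sx] = img.image[
            src_y0:src_y1, src_x0:src_x1
        ]

    rects = []
    for b in img.boxes:
        x0, y0, x1, y1 = box_to_pixel(b, w, h)
        shift_px, shift_py = params.dx * w, params.dy * h
        rects.append((b, (x0 + shift_px, y0 + shift_py, x1 + shift_px, y1 + shift_py)))
    return img.copy_with(
        image=canvas,
        boxes=_clip_boxes_px(rects, w, h),
        provenance="translation",
        meta={**img.meta, "dx": params.dx, "dy": params.dy},
    )


def _rotation_matrix(theta_deg: float) -> np.ndarray:
    """Forward point transform for a visually counter-clockwise rotation.

    In image coordinates (y down), rotating a point CCW on screen by theta
    maps offset (x, y) from the center to (x cos + y sin, -x sin + y cos).
    """
    t = math.radians(theta_deg)
    return np.array([[math.cos(t), math.sin(t)], [-math.sin(t), math.cos(t)]])


def rotate(img: AnnotatedImage, params: RotationParams, order: int = 1) -> AnnotatedImage:
    """Rotate about the canvas center, canvas size unchanged.

    The raster is resampled bilinearly (``order=1``; ``order=0`` gives
    nearest-neighbor, exact at multiples of 90 degrees).  Each box's four
    corners are rotated about the center and replaced by their axis-aligned
    bounding box — a conservative cover of the rotated insect — then
    clipped with the standard drop rule.  theta = 0 is an identity on
    boxes and leaves the raster equal to the input.
    """
    h, w = img.image.shape[:2]
    theta = params.theta
    if theta == 0.0:
        return img.copy_with(provenance="rotation", meta={**img.meta, "theta": 0.0})
    fwd = _rotation_matrix(theta)
    # ndimage.affine_transform maps output index coords to input coords:
    # in = M @ out + offset, indices ordered (row, col) = (y, x).
    inv_xy = _rotation_matrix(-theta)
    m_rc = inv_xy[::-1, ::-1].copy()  # reorder (x,y) matrix to (row,col)
    # pixel centers sit at index i == continuous i + 0.5; canvas center
    # (w/2, h/2) continuous is index ((h-1)/2, (w-1)/2)
    c_rc = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = c_rc - m_rc @ c_rc
    canvas = np.empty_like(img.image)
    for c in range(3):
        chan = ndimage.affine_transform(
            img.image[:, :, c].astype(np.float64),
            m_rc,
            offset=offset,
            order=order,
            mode="constant",
            cval=float(FILL_COLOR[c]),
        )
        canvas[:, :, c] = np.floor(np.clip(chan, 0.0, 255.0) + 0.5).astype(np.uint8)

    center = np.array([w / 2.0, h / 2.0])
    rects = []
    for b in img.boxes:
        x0, y0, x1, y1 = box_to_pixel(b, w, h)
        corners = np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])
        rotated = (fwd @ (corners - center).T).T + center
        rects.append(
            (b, (rotated[:, 0].min(), rotated[:, 1].min(), rotated[:, 0].max(), rotated[:, 1].max()))
        )
    return img.copy_with(
        image=canvas,
        boxes=_clip_boxes_px(rects, w, h),
        provenance="rotation",
        meta={**img.meta, "theta": theta},
    )


def sample_geometric_params(
    rng: np.random.Generator,
) -> tuple[TranslationParams, RotationParams]:
    """Draw dx, dy ~ U(-0.2, 0.2) and theta ~ U(-90, 90) degrees.

    Draw order (dx, dy, theta) is part of the determinism contract.
    """
    dx = rng.uniform(*SHIFT_RANGE)
    dy = rng.uniform(*SHIFT_RANGE)
    theta = rng.uniform(*ANGLE_RANGE)
    return TranslationParams(dx=dx, dy=dy), RotationParams(theta=theta)
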