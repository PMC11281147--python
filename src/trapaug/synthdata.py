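"""Synthetic sticky-trap image generator and controlled detection sets.

Real trap photographs are a bright, quasi-uniform adhesive paper under
an illumination gradient, dotted with small dark insects in arbitrary
poses.  This module emulates exactly that geometry — a textured bright
background with a linear ramp, plus dark filled ellipses of random size
and orientation at non-overlapping positions — with exact ground-truth
boxes, so every augmentation operator and the evaluator can be exercised
without any photograph.  It makes no attempt at photorealism: insects
are single-class ellipses, and pose variety comes only from orientation
and axis ratio.

``generate_detections`` perturbs ground truth into a controlled fake
detector output (misses, box jitter, spurious boxes) for evaluator
tests; jitter consumes the same random draws regardless of magnitude, so
sweeping the jitter scale at a fixed seed moves every detection along a
fixed ray away from its ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .core import (
    AnnotatedImage,
    Box,
    Detection,
    TrapAugError,
    ValidationError,
    write_dataset,
)

__all__ = [
    "SynthConfig",
    "DetectionNoise",
    "PlacementError",
    "generate_trap_image",
    "generate_detections",
    "generate_dataset",
]


class PlacementError(TrapAugError):
    """Could not place the requested insects without overlap."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic trap scene.

    ``insect_axes`` bounds the ellipse semi-axes in pixels; the full
    major axis is kept at or below one sixth of the image side, the
    small-object regime trap images live in.  Intensities are on the
    0-255 scale.
    """

    image_size: int = 320
    n_insects: tuple[int, int] = (3, 12)
    insect_axes: tuple[float, float] = (4.0, 14.0)
    background_level: tuple[float, float] = (190.0, 230.0)
    gradient_strength: float = 25.0
    texture_std: float = 5.0
    insect_level: tuple[float, float] = (20.0, 70.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 8:
            raise ValidationError(f"image_size must be >= 8, got {self.image_size}")
        lo, hi = self.n_insects
        if lo < 0 or hi < lo:
            raise ValidationError(f"bad n_insects range {self.n_insects}")
        alo, ahi = self.insect_axes
        if alo < 1.0 or ahi < alo:
            raise ValidationError(f"bad insect_axes range {self.insect_axes}")
        if 2 * ahi > self.image_size / 6:
            raise ValidationError(
                f"largest insect axis {2 * ahi} px exceeds image_size/6 "
                f"({self.image_size / 6:.1f} px); shrink insect_axes or enlarge the image"
            )
        for name in ("background_level", "insect_level"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi <= 255):
                raise ValidationError(f"{name} must be within [0, 255], got {(lo, hi)}")
        if self.texture_std < 0 or self.gradient_strength < 0:
            raise ValidationError("texture_std and gradient_strength must be non-negative")


@dataclass(frozen=True)
class DetectionNoise:
    """Noise model turning ground truth into fake detector output.

    Each ground truth is missed with ``p_miss``, otherwise emitted with
    center/size jitter of scale ``jitter_sd`` (as a fraction of the box
    size) and a confidence ~ U(0.6, 1.0); spurious boxes arrive as a
    Poisson(``p_spurious_per_image``) count with confidences U(0.1, 0.6).
    """

    p_miss: float = 0.0
    p_spurious_per_image: float = 0.0
    jitter_sd: float = 0.0
    tp_confidence: tuple[float, float] = (0.6, 1.0)
    fp_confidence: tuple[float, float] = (0.1, 0.6)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_miss <= 1.0:
            raise ValidationError(f"p_miss={self.p_miss} outside [0, 1]")
        if self.p_spurious_per_image < 0:
            raise ValidationError("p_spurious_per_image must be non-negative")
        if self.jitter_sd < 0:
            raise ValidationError("jitter_sd must be non-negative")


def _background(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    s = cfg.image_size
    base = rng.uniform(*cfg.background_level)
    phi = rng.uniform(0.0, 2.0 * np.pi)
    yy, xx = np.mgrid[0:s, 0:s]
    proj = (xx * np.cos(phi) + yy * np.sin(phi)) / s
    ramp = cfg.gradient_strength * (proj - proj.mean())
    tint = rng.uniform(-6.0, 6.0, size=3)
    texture = rng.normal(0.0, cfg.texture_std, size=(s, s))
    field = base + ramp + texture
    bg = np.stack([field + t for t in tint], axis=2)
    return np.clip(bg, 0, 255)


def generate_trap_image(
    cfg: SynthConfig, rng: np.random.Generator, id: str = "synthetic_trap"
) -> AnnotatedImage:
    """One synthetic trap photo with exact per-insect ground-truth boxes.

    Insects are dark filled ellipses at uniformly random non-overlapping
    positions and orientations; each box is the tight axis-aligned bound
    of its ellipse's rasterized pixels.  Deterministic under the
    generator state; raises :class:`PlacementError` when ``n`` insects
    cannot be placed without overlap in 1,000 attempts.
    """
    s = cfg.image_size
    canvas = _background(cfg, rng)
    n = int(rng.integers(cfg.n_insects[0], cfg.n_insects[1] + 1))
    boxes: list[Box] = []
    placed: list[tuple[int, int, int, int]] = []
    attempts = 0
    while len(boxes) < n:
        attempts += 1
        if attempts > 1000:
            raise PlacementError(
                f"placed only {len(boxes)}/{n} insects in 1000 attempts; "
                "use fewer or smaller insects"
            )
        a = rng.uniform(*cfg.insect_axes)
        b = rng.uniform(cfg.insect_axes[0], a)
        theta = rng.uniform(-np.pi, np.pi)
        margin = a + 2.0
        cy = rng.uniform(margin, s - margin)
        cx = rng.uniform(margin, s - margin)
        rr, cc = draw_ellipse(cy, cx, b, a, shape=(s, s), rotation=theta)
        if rr.size == 0:
            continue
        x0, x1 = int(cc.min()), int(cc.max()) + 1
        y0, y1 = int(rr.min()), int(rr.max()) + 1
        if any(x0 < px1 + 1 and px0 < x1 + 1 and y0 < py1 + 1 and py0 < y1 + 1
               for px0, py0, px1, py1 in placed):
            continue
        body = rng.uniform(*cfg.insect_level)
        speckle = rng.normal(0.0, 6.0, size=rr.size)
        for ch in range(3):
            canvas[rr, cc, ch] = np.clip(body + speckle, 0, 255)
        placed.append((x0, y0, x1, y1))
        boxes.append(
            Box(0, (x0 + x1) / (2 * s), (y0 + y1) / (2 * s), (x1 - x0) / s, (y1 - y0) / s)
        )
    return AnnotatedImage(
        np.floor(canvas + 0.5).astype(np.uint8),
        boxes,
        id=id,
        provenance="original",
        meta={"synthetic": True, "n_insects": n},
    )


def generate_detections(
    gts: Sequence[Box], noise: DetectionNoise, rng: np.random.Generator
) -> list[Detection]:
    """Perturb ground truth into a fake detector output.

    With ``p_miss=0``, ``jitter_sd=0`` and no spurious rate the output
    reproduces the ground truth exactly (a perfect detector).  The unit
    jitter draws are consumed whether or not a box is missed and are
    scaled by ``jitter_sd`` afterwards, keeping runs at different jitter
    magnitudes on the same random stream.
    """
    dets: list[Detection] = []
    for gt in gts:
        miss = rng.random() < noise.p_miss
        z = rng.standard_normal(4)
        conf = float(rng.uniform(*noise.tp_confidence))
        if miss:
            continue
        sd = noise.jitter_sd
        cx = gt.cx + sd * gt.w * z[0]
        cy = gt.cy + sd * gt.h * z[1]
        w = gt.w * max(0.05, 1.0 + sd * z[2])
        h = gt.h * max(0.05, 1.0 + sd * z[3])
        cx, cy = float(np.clip(cx, 0.0, 1.0)), float(np.clip(cy, 0.0, 1.0))
        w, h = float(min(w, 1.0)), float(min(h, 1.0))
        dets.append(Detection(Box(gt.class_id, cx, cy, w, h), conf))
    n_fp = int(rng.poisson(noise.p_spurious_per_image))
    for _ in range(n_fp):
        cx, cy = rng.uniform(0.05, 0.95, size=2)
        w, h = rng.uniform(0.02, 0.10, size=2)
        conf = float(rng.uniform(*noise.fp_confidence))
        dets.append(Detection(Box(0, float(cx), float(cy), float(w), float(h)), conf))
    return dets


def generate_dataset(
    n_images: int, cfg: SynthConfig, out_dir: str | Path | None = None
) -> tuple[list[AnnotatedImage], dict]:
    """Generate ``n_images`` synthetic trap images; optionally write to disk.

    Per-image seeds descend from ``cfg.seed`` as [seed, image-index], so
    the i-th image is reproducible in isolation.  Returns the images and
    a manifest (also written as JSON when ``out_dir`` is given).
    """
    if n_images < 1:
        raise ValidationError("n_images must be >= 1")
    images = []
    for i in range(n_images):
        rng = np.random.default_rng([cfg.seed, i])
        img = generate_trap_image(cfg, rng, id=f"trap_{i:04d}")
        img.meta["image_seed"] = [cfg.seed, i]
        images.append(img)
    manifest = {
        "n_images": n_images,
        "config": {
            "image_size": cfg.image_size,
            "n_insects": list(cfg.n_insects),
            "insect_axes": list(cfg.insect_axes),
            "background_level": list(cfg.background_level),
            "gradient_strength": cfg.gradient_strength,
            "texture_std": cfg.texture_std,
            "insect_level": list(cfg.insect_level),
            "seed": cfg.seed,
        },
    }
    if out_dir is not None:
        written = write_dataset(images, out_dir)
        manifest["images"] = written["images"]
        import json

        with open(Path(out_dir) / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return images, manifest
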