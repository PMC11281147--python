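"""Deterministic dataset-expansion orchestrator.

Training sets of a few hundred trap images are enriched by materializing
augmented derivatives: each chosen method contributes ``multiple`` full
copies of the original set (one derivative per original image per pass;
for mosaic variants, one freshly composed mosaic per original image),
and the originals themselves are normally kept — the expanded set counts
``n * (1 + multiple * n_methods)`` images.  Pairing two methods at
multiple 1 therefore turns 330 originals into 990 images, and a triple
into 1320.

Every random draw descends from the plan's master seed through a
fixed sub-seeding scheme keyed by (method, pass, image index), so a
run is bit-reproducible and adding a method to a plan does not perturb
another method's outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .core import AnnotatedImage, ValidationError, write_dataset
from .geometric import rotate, translate, sample_geometric_params
from .mosaic import MosaicSpec, make_modified_mosaic, make_mosaic
from .photometric import (
    NoiseParams,
    add_gaussian_noise,
    brightness_contrast,
    gamma_correct,
    sample_photometric_params,
)

__all__ = ["EnrichmentPlan", "plan_enrichment", "enrich_dataset", "write_enriched_dataset", "METHODS"]

# Fixed method-id table: part of the sub-seeding contract. Never renumber.
_METHOD_IDS = {
    "gamma": 1,
    "brightness_contrast": 2,
    "noise": 3,
    "translation": 4,
    "rotation": 5,
    "mosaic": 6,
    "modified_mosaic": 7,
}
METHODS = tuple(_METHOD_IDS)
_MOSAIC_METHODS = ("mosaic", "modified_mosaic")


def _aug_gamma(img: AnnotatedImage, rng: np.random.Generator) -> AnnotatedImage:
    gp, _ = sample_photometric_params(rng)
    return gamma_correct(img, gp)


def _aug_bc(img: AnnotatedImage, rng: np.random.Generator) -> AnnotatedImage:
    _, bc = sample_photometric_params(rng)
    return brightness_contrast(img, bc)


def _aug_noise(img: AnnotatedImage, rng: np.random.Generator) -> AnnotatedImage:
    return add_gaussian_noise(img, NoiseParams(), rng)


def _aug_translate(img: AnnotatedImage, rng: np.random.Generator) -> AnnotatedImage:
    tp, _ = sample_geometric_params(rng)
    return translate(img, tp)


def _aug_rotate(img: AnnotatedImage, rng: np.random.Generator) -> AnnotatedImage:
    _, rp = sample_geometric_params(rng)
    return rotate(img, rp)


_SINGLE_IMAGE_OPS: dict[str, Callable[[AnnotatedImage, np.random.Generator], AnnotatedImage]] = {
    "gamma": _aug_gamma,
    "brightness_contrast": _aug_bc,
    "noise": _aug_noise,
    "translation": _aug_translate,
    "rotation": _aug_rotate,
}


@dataclass(frozen=True)
class EnrichmentPlan:
    """Strategy, method list, multiple and seed of a deterministic expansion."""

    methods: tuple[str, ...]
    multiple: int = 1
    seed: int = 0
    include_originals: bool = True
    mosaic_spec: MosaicSpec = field(default_factory=MosaicSpec)

    def __post_init__(self) -> None:
        if not self.methods:
            raise ValidationError("plan needs at least one augmentation method")
        unknown = [m for m in self.methods if m not in _METHOD_IDS]
        if unknown:
            raise ValidationError(f"unknown methods {unknown}; choose from {METHODS}")
        if len(set(self.methods)) != len(self.methods):
            raise ValidationError("methods must be distinct")
        if self.multiple < 1:
            raise ValidationError(f"multiple must be >= 1, got {self.multiple}")

    def to_dict(self) -> dict:
        return {
            "methods": list(self.methods),
            "multiple": self.multiple,
            "seed": self.seed,
            "include_originals": self.include_originals,
            "mosaic": {
                "out_size": self.mosaic_spec.out_size,
                "max_center_offset": self.mosaic_spec.max_center_offset,
                "p_brightness_contrast": self.mosaic_spec.p_brightness_contrast,
                "p_noise": self.mosaic_spec.p_noise,
                "crop_anchor": self.mosaic_spec.crop_anchor,
            },
        }


def plan_enrichment(n_original: int, plan: EnrichmentPlan) -> dict:
    """Pure count arithmetic: total output size and per-method breakdown."""
    if n_original < 1:
        raise ValidationError("n_original must be >= 1")
    per_method = {m: plan.multiple * n_original for m in plan.methods}
    total = sum(per_method.values()) + (n_original if plan.include_originals else 0)
    return {
        "n_original": n_original,
        "per_method": per_method,
        "n_augmented": sum(per_method.values()),
        "total": total,
    }


def _rng(*entropy: int) -> np.random.Generator:
    return np.random.default_rng(list(entropy))


def _mosaic_pass(
    dataset: Sequence[AnnotatedImage],
    method: str,
    plan: EnrichmentPlan,
    pass_idx: int,
) -> list[AnnotatedImage]:
    """One pass of a mosaic method: n compositions from a seeded shuffle.

    Sources come from a shuffled deck consumed 4 at a time; when fewer
    than 4 remain the deck is re-shuffled in full, so the 4 sources of
    any single mosaic are always distinct.
    """
    n = len(dataset)
    mid = _METHOD_IDS[method]
    deck_rng = _rng(plan.seed, mid, pass_idx)
    compose = make_mosaic if method == "mosaic" else make_modified_mosaic
    deck: list[int] = []
    out = []
    for i in range(n):
        if len(deck) < 4:
            deck = list(deck_rng.permutation(n))
        picks, deck = deck[:4], deck[4:]
        sources = [dataset[j] for j in picks]
        rng = _rng(plan.seed, mid, pass_idx, i)
        img = compose(sources, plan.mosaic_spec, rng, id=f"{method}_p{pass_idx + 1}_i{i:04d}")
        img.meta["pass"] = pass_idx + 1
        out.append(img)
    return out


def enrich_dataset(
    dataset: Sequence[AnnotatedImage], plan: EnrichmentPlan
) -> list[AnnotatedImage]:
    """Materialize the enriched dataset: originals first, then per-method passes.

    Output order is originals (if kept), then methods in plan order, each
    method contributing ``multiple`` passes over the originals.  The count
    always equals :func:`plan_enrichment`'s prediction, and a fixed
    (dataset, plan) pair reproduces the output bit-identically.  Original
    images are never mutated.
    """
    if not dataset:
        raise ValidationError("dataset is empty")
    n = len(dataset)
    if any(m in _MOSAIC_METHODS for m in plan.methods) and n < 4:
        raise ValidationError(f"mosaic methods need at least 4 images, got {n}")

    out: list[AnnotatedImage] = []
    if plan.include_originals:
        out.extend(img.copy_with() for img in dataset)
    for method in plan.methods:
        mid = _METHOD_IDS[method]
        for p in range(plan.multiple):
            if method in _MOSAIC_METHODS:
                out.extend(_mosaic_pass(dataset, method, plan, p))
            else:
                op = _SINGLE_IMAGE_OPS[method]
                for i, orig in enumerate(dataset):
                    rng = _rng(plan.seed, mid, p, i)
                    derived = op(orig, rng)
                    derived = replace(
                        derived,
                        id=f"{orig.id}_{method}_p{p + 1}",
                        meta={**derived.meta, "source_ids": [orig.id], "pass": p + 1},
                    )
                    out.append(derived)
    expected = plan_enrichment(n, plan)["total"]
    assert len(out) == expected, f"internal count mismatch: {len(out)} != {expected}"
    return out


def write_enriched_dataset(
    images: Sequence[AnnotatedImage], out_dir: str | Path, plan: EnrichmentPlan | None = None
) -> dict:
    """Write the images/labels layout plus a manifest with the full audit trail.

    The manifest records id, provenance, source ids and every sampled
    parameter per image; re-running :func:`enrich_dataset` with the
    manifest's plan reproduces each file byte-identically.
    """
    manifest = write_dataset(images, out_dir)
    if plan is not None:
        manifest["plan"] = plan.to_dict()
        import json

        with open(Path(out_dir) / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
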