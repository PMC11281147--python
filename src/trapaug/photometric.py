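"""Pixel-intensity augmentations: gamma correction, brightness-contrast, noise.

All three operators act identically on the red, green and blue channels
(trap images show near-identical per-channel distributions, see
:func:`trapaug.core.channel_histograms`), leave the box list untouched,
and produce bit-reproducible uint8 output via a fixed
round-half-away-from-zero rule.

Gamma correction maps each scaled intensity f = v/255 in [0, 1] to
``c * f**gamma``; brightness-contrast is the affine map
``alpha * v + beta`` on the 0-255 scale.  Noise is multiplicative
speckle: each pixel is scaled by an i.i.d. draw from N(1, 0.2^2) —
a mean-1 / sd-0.2 Gaussian only makes sense as a factor, and on field
trap images it models sensor and illumination graininess.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AnnotatedImage, ValidationError

__all__ = [
    "GammaParams",
    "BrightnessContrastParams",
    "NoiseParams",
    "gamma_correct",
    "brightness_contrast",
    "add_gaussian_noise",
    "sample_photometric_params",
    "GAMMA_RANGE",
    "ALPHA_RANGE",
    "BETA_RANGE",
]

#: Default sampling ranges for the photometric parameter sampler.
GAMMA_RANGE = (0.2, 3.0)
ALPHA_RANGE = (0.5, 2.0)
BETA_RANGE = (-50.0, 50.0)


@dataclass(frozen=True)
class GammaParams:
    """Power-law mapping f* = gain * f**gamma on intensities scaled to [0, 1]."""

    gamma: float
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValidationError(f"gamma must be positive, got {self.gamma}")


@dataclass(frozen=True)
class BrightnessContrastParams:
    """Affine intensity mapping alpha*v + beta; alpha is contrast, beta brightness."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValidationError(f"alpha must be positive, got {self.alpha}")


@dataclass(frozen=True)
class NoiseParams:
    """Multiplicative Gaussian noise, one factor per pixel.

    ``per_channel=False`` (default) shares the draw across the three
    channels, modelling luminance graininess rather than chroma noise.
    """

    mean: float = 1.0
    std: float = 0.2
    per_channel: bool = False

    def __post_init__(self) -> None:
        if self.std <= 0:
            raise ValidationError(f"std must be positive, got {self.std}")


def _quantize(values: np.ndarray) -> np.ndarray:
    """Clip to [0, 255] and round half away from zero to uint8.

    np.round rounds half-to-even, which is platform-stable but surprises
    anyone checking hand-computed examples; floor(x + 0.5) on the already
    non-negative clipped values gives the conventional rule.
    """
    return np.floor(np.clip(values, 0.0, 255.0) + 0.5).astype(np.uint8)


def gamma_correct(img: AnnotatedImage, params: GammaParams) -> AnnotatedImage:
    """Apply power-law gamma correction; boxes pass through unchanged.

    Per pixel and channel: ``out = round(255 * clip(gain * (v/255)**gamma, 0, 1))``.
    gamma=1, gain=1 is a bit-exact identity.
    """
    scaled = img.image.astype(np.float64) / 255.0
    mapped = 255.0 * np.clip(params.gain * np.power(scaled, params.gamma), 0.0, 1.0)
    return img.copy_with(
        image=_quantize(mapped),
        provenance="gamma",
        meta={**img.meta, "gamma": params.gamma, "gain": params.gain},
    )


def brightness_contrast(img: AnnotatedImage, params: BrightnessContrastParams) -> AnnotatedImage:
    """Affine brightness-contrast adjustment; boxes pass through unchanged.

    Per pixel and channel: ``out = round(clip(alpha*v + beta, 0, 255))``.
    alpha=1, beta=0 is a bit-exact identity.
    """
    mapped = params.alpha * img.image.astype(np.float64) + params.beta
    return img.copy_with(
        image=_quantize(mapped),
        provenance="brightness_contrast",
        meta={**img.meta, "alpha": params.alpha, "beta": params.beta},
    )


def add_gaussian_noise(
    img: AnnotatedImage, params: NoiseParams, rng: np.random.Generator
) -> AnnotatedImage:
    """Multiplicative Gaussian noise ``out = round(clip(v * n, 0, 255))``.

    One draw n ~ N(mean, std^2) per pixel location, shared across the three
    channels unless ``params.per_channel``.  Identical generator state gives
    bit-identical output.
    """
    h, w = img.image.shape[:2]
    if params.per_channel:
        factors = rng.normal(params.mean, params.std, size=(h, w, 3))
    else:
        factors = rng.normal(params.mean, params.std, size=(h, w, 1))
    noisy = img.image.astype(np.float64) * factors
    return img.copy_with(
        image=_quantize(noisy),
        provenance="noise",
        meta={**img.meta, "noise_mean": params.mean, "noise_std": params.std},
    )


def sample_photometric_params(
    rng: np.random.Generator,
) -> tuple[GammaParams, BrightnessContrastParams]:
    """Draw gamma ~ U(0.2, 3.0), alpha ~ U(0.5, 2.0), beta ~ U(-50, 50); gain fixed at 1.

    Draw order (gamma, alpha, beta) is part of the determinism contract.
    """
    gamma = rng.uniform(*GAMMA_RANGE)
    alpha = rng.uniform(*ALPHA_RANGE)
    beta = rng.uniform(*BETA_RANGE)
    return GammaParams(gamma=gamma, gain=1.0), BrightnessContrastParams(alpha=alpha, beta=beta)
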