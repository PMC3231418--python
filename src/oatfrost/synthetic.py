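"""Synthetic four-texture field scenes with known ground truth.

Real frost-damage photographs mix four textures: green (healthy) oat,
dried oat, half-dried oat, and shady ground.  The generator emulates
their class-mixture statistics — blob-structured regions with per-class
colour means, an illumination ramp, and additive sensor noise — so the
full pipeline and the validation machinery can be exercised end to end
with exact ground truth.  It does not attempt photometric realism or
plant morphology; only the mixture statistics matter for testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, PlacementError
from .validation import PolygonSample

__all__ = ["SceneSpec", "DEFAULT_PALETTE", "generate_scene", "generate_polygons"]

#: Default class palette mirroring the four survey roles: green oat,
#: dried (yellow) oat, half-dried (dull straw-brown) oat, shady ground.
#: The half-dried colour is browner than the dried one so the four roles
#: separate along distinct Lab axes (L* isolates shadow, a* the green
#: class, b* the dried from the half-dried vegetation), as they do in
#: real canopy photographs where the intermediate state has lost its
#: yellow cast.
DEFAULT_PALETTE = (
    ("GO", (50, 110, 40), 0.35),
    ("DO", (180, 170, 80), 0.16),
    ("HD", (130, 110, 85), 0.16),
    ("SG", (25, 30, 25), 0.33),
)


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic field scene.

    ``classes`` lists (role, mean RGB, target area fraction); fractions
    must sum to 1.  ``noise_sd`` is the per-channel additive Gaussian
    noise in 8-bit counts — the default of 1.5 reflects a scene-scale
    raster in which each pixel averages many native sensor pixels (a
    multi-megapixel frame reduced to a few hundred pixels a side), which
    suppresses the sensor's per-pixel noise several-fold.
    ``gradient_amplitude`` is the peak-to-peak relative span of a
    horizontal multiplicative illumination ramp; ``patch_scale`` is the
    characteristic blob size in pixels.
    """

    width: int = 512
    height: int = 512
    classes: tuple = DEFAULT_PALETTE
    noise_sd: float = 1.5
    gradient_amplitude: float = 0.2
    patch_scale: float = 24.0
    seed: int = 0

    def __post_init__(self):
        if self.width < 1 or self.height < 1:
            raise ConfigurationError("scene dimensions must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.patch_scale < 1:
            raise ConfigurationError("patch_scale must be >= 1")
        fractions = np.array([c[2] for c in self.classes], dtype=float)
        if (fractions < 0).any() or abs(fractions.sum() - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class fractions must be non-negative and sum to 1, got {fractions}"
            )

    @property
    def roles(self) -> tuple[str, ...]:
        return tuple(c[0] for c in self.classes)


def generate_scene(spec: SceneSpec) -> tuple[np.ndarray, np.ndarray]:
    """Generate an RGB scene and its ground-truth role map.

    The role map comes from quantile-slicing a smoothed Gaussian random
    field, which yields contiguous blobs whose empirical area fractions
    track the targets closely (the quantile split is exact up to ties on
    the continuous field).  Pixel colours are the role's mean RGB scaled
    by the illumination ramp plus noise, clipped to 8 bits.

    Returns ``(rgb, truth)`` with ``rgb`` a (H, W, 3) uint8 array and
    ``truth`` a (H, W) int array of class indices into ``spec.classes``.
    """
    rng = np.random.default_rng(spec.seed)
    fieldv = gaussian_filter(
        rng.standard_normal((spec.height, spec.width)), sigma=spec.patch_scale
    )
    fractions = np.array([c[2] for c in spec.classes], dtype=float)
    cuts = np.quantile(fieldv, np.cumsum(fractions)[:-1]) if len(fractions) > 1 else []
    truth = np.searchsorted(np.asarray(cuts), fieldv, side="right").astype(np.int64)

    means = np.array([c[1] for c in spec.classes], dtype=float)
    ramp = 1.0 + spec.gradient_amplitude * (
        np.linspace(0.0, 1.0, spec.width) - 0.5
    )
    rgb = means[truth] * ramp[None, :, None]
    if spec.noise_sd > 0:
        rgb = rgb + rng.normal(0.0, spec.noise_sd, size=rgb.shape)
    return np.clip(np.rint(rgb), 0, 255).astype(np.uint8), truth


def generate_polygons(
    truth: np.ndarray,
    classes,
    per_class: int = 5,
    size_range: tuple[int, int] = (8, 20),
    seed: int = 0,
    max_tries: int = 5000,
) -> list[PolygonSample]:
    """Place homogeneous rectangular sample polygons on a ground-truth map.

    For each class, axis-aligned rectangles with side lengths drawn from
    ``size_range`` are placed by rejection sampling so every polygon lies
    fully inside a single-role region (each sample unit must contain
    pixels of one class only).  Raises :class:`PlacementError` carrying
    the partial result if a class lacks enough contiguous area.
    """
    truth = np.asarray(truth)
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    if lo < 1 or hi < lo:
        raise ConfigurationError(f"invalid size range {size_range}")
    polygons: list[PolygonSample] = []
    for idx, cls in enumerate(classes):
        placed = 0
        tries = 0
        while placed < per_class and tries < max_tries:
            tries += 1
            w = int(rng.integers(lo, hi + 1))
            h = int(rng.integers(lo, hi + 1))
            if truth.shape[0] < h or truth.shape[1] < w:
                continue
            r0 = int(rng.integers(0, truth.shape[0] - h + 1))
            c0 = int(rng.integers(0, truth.shape[1] - w + 1))
            block = truth[r0 : r0 + h, c0 : c0 + w]
            if not (block == idx).all():
                continue
            placed += 1
            # corner vertices at pixel centres; rasterization is inclusive
            poly = PolygonSample(
                polygon_id=f"{cls}-{placed}",
                label=cls,
                vertices=[
                    (c0, r0),
                    (c0 + w - 1, r0),
                    (c0 + w - 1, r0 + h - 1),
                    (c0, r0 + h - 1),
                ],
            )
            poly.pixels(truth.shape)
            polygons.append(poly)
        if placed < per_class:
            raise PlacementError(
                f"placed only {placed}/{per_class} polygons for class {cls!r}",
                partial=polygons,
            )
    return polygons
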