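"""Deterministic synthetic grayscale textures for tests and demonstrations.

Multi-class sets are rendered as oriented sinusoidal gratings plus seeded
noise — a desk-scale stand-in for photographed natural textures (e.g. tree
bark), giving each class its own spatial frequency and orientation and
hence a distinct, non-parallel texture vector. Pixels are clamped to
[1, 255]: keeping gray levels off zero makes accidental vanishing of the
window minor p11*p22 - p12*p21 rare, while constant patches remain
available for exercising the degenerate path on purpose.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np

from .core import TransformConfig, _window_products, image_to_vector
from .classify import cosine_similarity
from .errors import FixtureError

__all__ = [
    "TextureClassSpec",
    "random_image",
    "render_class",
    "texture_classes",
    "count_degenerate_windows",
]

logger = logging.getLogger(__name__)

_PARALLEL_COS = 1.0 - 1e-9  # two prototypes this aligned are unusable
_MAX_RETRIES = 5


@dataclass(frozen=True)
class TextureClassSpec:
    """Rendering recipe for one texture class.

    frequency is in cycles per image width, orientation in degrees,
    noise_amplitude and base_offset in gray levels.
    """

    label: str
    frequency: float
    orientation_deg: float
    noise_amplitude: float = 8.0
    base_offset: float = 128.0


def random_image(m: int, n: int, seed: int, low: int = 1, high: int = 255) -> np.ndarray:
    """Integer-valued uniform random image on [low, high], seed-reproducible."""
    if m < 3 or n < 3:
        raise ValueError(f"image must be at least 3x3, got {m}x{n}")
    if not (0 <= low <= high <= 255):
        raise ValueError(f"need 0 <= low <= high <= 255, got [{low}, {high}]")
    rng = np.random.default_rng(seed)
    return rng.integers(low, high, size=(m, n), endpoint=True).astype(float)


def _spec_stream_seed(spec: TextureClassSpec, seed: int) -> int:
    # Content hash: identical recipes share a noise stream, so forced
    # duplicates render identical images and are rejected as parallel.
    content = f"{spec.frequency!r}|{spec.orientation_deg!r}|" \
              f"{spec.noise_amplitude!r}|{spec.base_offset!r}"
    return (zlib.crc32(content.encode()) + seed) % (2 ** 31)


def render_class(spec: TextureClassSpec, m: int, n: int, seed: int) -> np.ndarray:
    """Render one class image: oriented grating plus noise, clamped to [1, 255]."""
    y, x = np.mgrid[0:m, 0:n].astype(float)
    theta = np.deg2rad(spec.orientation_deg)
    phase = 2.0 * np.pi * spec.frequency * (x * np.cos(theta) + y * np.sin(theta)) / n
    img = spec.base_offset + 60.0 * np.sin(phase)
    rng = np.random.default_rng(_spec_stream_seed(spec, seed))
    img = img + rng.normal(0.0, 1.0, size=(m, n)) * spec.noise_amplitude
    return np.clip(np.rint(img), 1, 255).astype(float)


def default_specs(n_classes: int) -> list[TextureClassSpec]:
    """Class recipes spreading frequency and orientation across classes."""
    specs = []
    for k in range(n_classes):
        specs.append(TextureClassSpec(
            label=f"class{k + 1:02d}",
            frequency=3.0 + 2.0 * k,
            orientation_deg=180.0 * k / n_classes,
        ))
    return specs


def texture_classes(n_classes: int = 10, m: int = 64, n: int = 64,
                    seed: int = 0,
                    specs: list[TextureClassSpec] | None = None,
                    ) -> dict[str, np.ndarray]:
    """One labeled image per class, with pairwise non-parallel texture vectors.

    If a rendered set contains (near-)parallel prototype vectors it is
    regenerated with an incremented seed, up to a bounded number of
    retries; persistent failure raises :class:`FixtureError`. Explicit
    ``specs`` override the default frequency/orientation ladder.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    if specs is None:
        specs = default_specs(n_classes)
    elif len(specs) != n_classes:
        raise ValueError("specs length must equal n_classes")

    cfg = TransformConfig()
    for attempt in range(_MAX_RETRIES):
        images = {s.label: render_class(s, m, n, seed + attempt) for s in specs}
        vectors = {lab: image_to_vector(img, cfg).as_array()
                   for lab, img in images.items()}
        labels = list(vectors)
        parallel = [
            (labels[i], labels[j])
            for i in range(len(labels)) for j in range(i + 1, len(labels))
            if cosine_similarity(vectors[labels[i]], vectors[labels[j]]) > _PARALLEL_COS
        ]
        if not parallel:
            return images
        logger.warning("parallel texture vectors %s at seed %d; retrying",
                       parallel, seed + attempt)
    raise FixtureError(
        f"could not generate pairwise non-parallel class vectors after "
        f"{_MAX_RETRIES} attempts (last offenders: {parallel})")


def count_degenerate_windows(image, tol: float = 1e-12) -> int:
    """Number of 3x3 windows whose leading minor p11*p22 - p12*p21 vanishes.

    Matches the transform's ``n_degenerate`` under any policy.
    """
    from .core import as_gray_image
    a = as_gray_image(image)
    p11, p12, _, p21, p22, _ = _window_products(a)
    prod1 = p11 * p22
    prod2 = p12 * p21
    degenerate = np.abs(prod1 - prod2) <= tol * np.maximum(
        1.0, np.abs(prod1) + np.abs(prod2))
    return int(np.count_nonzero(degenerate))
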