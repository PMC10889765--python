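"""Texture-space transform: 3x3 patterns, texture units and image vectors.

A grayscale image ``S`` (an M x N real matrix) is scanned with a 3x3
observation window at stride 1. Each window position detects a pattern
``P = (p_ij)`` whose entries are taken as the coefficients of a
parametrized homogeneous linear system. The system's parametric solution
assigns the window a three-component *texture unit*

    t1 = (p13*p22 - p23*p12) / (p11*p22 - p12*p21) * lam
    t2 = (p11*p23 - p21*p13) / (p11*p22 - p12*p21) * lam
    t3 = lam

for a free scalar ``lam != 0``. Summing the units of every window yields
the image's *texture vector* C = (a1, a2, a3), a point in a 3-D texture
space whose direction and magnitude characterize the image's texture.
Note the solution uses only the first two pattern rows; the third row
enters only the diagnostic K value (:func:`compute_K`).

Windows whose 2x2 leading minor D = p11*p22 - p12*p21 vanishes (flat
patches, for instance) have no defined unit; a configurable policy
decides whether they contribute (0, 0, lam), are skipped, or raise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Literal

import numpy as np

from .errors import DegeneratePatternError, DimensionError, UndefinedDirectionError

__all__ = [
    "Pattern",
    "TextureUnit",
    "TextureVector",
    "VectorGeometry",
    "TransformConfig",
    "as_gray_image",
    "extract_patterns",
    "compute_K",
    "texture_unit",
    "image_to_vector",
    "vector_geometry",
]

DegeneratePolicy = Literal["zero-ratio", "skip", "error"]


@dataclass(frozen=True)
class Pattern:
    """A 3x3 window of gray levels detected at one image position.

    ``p`` uses the 1-based (i, j) convention of the linear system, i.e.
    ``p[i-1, j-1]`` is p_ij. ``origin`` is the 0-based (row, col) of the
    window's top-left pixel in the source image.
    """

    p: np.ndarray
    origin: tuple[int, int] = (0, 0)

    def __post_init__(self):
        p = np.asarray(self.p, dtype=float)
        if p.shape != (3, 3):
            raise DimensionError(f"pattern must be 3x3, got {p.shape}")
        if not np.all(np.isfinite(p)):
            raise ValueError("pattern values must be finite")
        object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class TextureUnit:
    """Radius vector T = (t1, t2, t3) of one window in texture space.

    ``t3`` always equals the lambda of the transform that produced it.
    ``degenerate`` marks units where the denominator test failed and the
    policy value was substituted.
    """

    t1: float
    t2: float
    t3: float
    degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.t1, self.t2, self.t3], dtype=float)


@dataclass(frozen=True)
class TextureVector:
    """Image-level vector C = (a1, a2, a3): the sum of all texture units."""

    a1: float
    a2: float
    a3: float
    n_patterns: int
    n_degenerate: int
    lam: float

    def as_array(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3], dtype=float)


@dataclass(frozen=True)
class VectorGeometry:
    """Magnitude and direction cosines of a texture-space vector."""

    magnitude: float
    cos_alpha: float
    cos_beta: float
    cos_gamma: float


@dataclass(frozen=True)
class TransformConfig:
    """Parameters of the image -> texture-vector transform.

    lam
        The free parameter selecting one solution from the parametric
        family; a pure scale factor on the result. Default 2. Zero is
        permitted only explicitly (``allow_zero_lambda``) and yields the
        all-zero vector.
    degenerate_policy
        ``zero-ratio`` (default) substitutes (0, 0, lam) for windows with
        a vanishing leading minor; ``skip`` omits them from the sum;
        ``error`` raises :class:`DegeneratePatternError`.
    degeneracy_tol
        Relative tolerance eps of the denominator test
        |D| <= eps * max(1, |p11*p22| + |p12*p21|).
    """

    lam: float = 2.0
    degenerate_policy: DegeneratePolicy = "zero-ratio"
    degeneracy_tol: float = 1e-12
    allow_zero_lambda: bool = False

    def __post_init__(self):
        if self.degeneracy_tol < 0:
            raise ValueError("degeneracy_tol must be >= 0")
        if self.degenerate_policy not in ("zero-ratio", "skip", "error"):
            raise ValueError(f"unknown degenerate policy {self.degenerate_policy!r}")
        if self.lam == 0 and not self.allow_zero_lambda:
            raise ValueError("lambda = 0 yields only the trivial solution; "
                             "set allow_zero_lambda=True to permit it")


def as_gray_image(pixels) -> np.ndarray:
    """Validate and return an M x N float image matrix (M, N >= 3)."""
    a = np.asarray(pixels, dtype=float)
    if a.ndim != 2:
        raise DimensionError(f"image must be 2-D, got shape {a.shape}")
    if a.shape[0] < 3 or a.shape[1] < 3:
        raise DimensionError(f"image must be at least 3x3, got {a.shape[0]}x{a.shape[1]}")
    if not np.all(np.isfinite(a)):
        raise ValueError("image values must be finite")
    return a


def extract_patterns(image) -> Iterator[Pattern]:
    """Yield the (M-2)*(N-2) 3x3 patterns of ``image`` in row-major order.

    Stride 1, no padding: every window lies fully inside the image. The
    top-left window comes first.
    """
    a = as_gray_image(image)
    m, n = a.shape
    for r in range(m - 2):
        for c in range(n - 2):
            yield Pattern(p=a[r:r + 3, c:c + 3].copy(), origin=(r, c))


def _window_products(a: np.ndarray):
    """Slice the nine per-window coefficient planes of an image."""
    p11, p12, p13 = a[:-2, :-2], a[:-2, 1:-1], a[:-2, 2:]
    p21, p22, p23 = a[1:-1, :-2], a[1:-1, 1:-1], a[1:-1, 2:]
    return p11, p12, p13, p21, p22, p23


def _is_degenerate(p11p22: float, p12p21: float, tol: float) -> bool:
    return abs(p11p22 - p12p21) <= tol * max(1.0, abs(p11p22) + abs(p12p21))


def compute_K(pattern: Pattern, tol: float = 1e-12) -> float:
    """The scalar K that, multiplying p33, makes the pattern matrix singular.

    Forcing det = 0 guarantees the homogeneous system has infinitely many
    solutions. K is a diagnostic: the parametric solution itself
    (:func:`texture_unit`) never uses it.

    Raises :class:`DegeneratePatternError` when p33 = 0 or the minor
    p21*p12 - p11*p22 vanishes (relative tolerance ``tol``).
    """
    p = pattern.p
    p11, p12, p13 = p[0]
    p21, p22, p23 = p[1]
    p31, p32, p33 = p[2]
    minor = p21 * p12 - p11 * p22
    if _is_degenerate(p21 * p12, p11 * p22, tol):
        raise DegeneratePatternError(
            "K undefined: minor p21*p12 - p11*p22 vanishes", origin=pattern.origin)
    if abs(p33) <= tol * max(1.0, abs(p33)):
        raise DegeneratePatternError("K undefined: p33 = 0", origin=pattern.origin)
    num = p31 * (p12 * p23 - p22 * p13) + p32 * (p13 * p21 - p23 * p11)
    return num / (p33 * minor)


def texture_unit(pattern: Pattern, config: TransformConfig | None = None) -> TextureUnit | None:
    """Solve the window's parametrized system for its texture unit.

    With D = p11*p22 - p12*p21 nonzero the unit is
    ((p13*p22 - p23*p12)/D * lam, (p11*p23 - p21*p13)/D * lam, lam),
    which satisfies p11*t1 + p12*t2 = p13*t3 and p21*t1 + p22*t2 = p23*t3.
    Only rows 1-2 of the pattern enter the formula.

    Degenerate windows follow ``config.degenerate_policy``: ``zero-ratio``
    returns ``TextureUnit(0, 0, lam, degenerate=True)``, ``skip`` returns
    ``None`` (the aggregator omits it), ``error`` raises.
    """
    cfg = config or TransformConfig()
    p = pattern.p
    p11, p12, p13 = p[0]
    p21, p22, p23 = p[1]
    d = p11 * p22 - p12 * p21
    if _is_degenerate(p11 * p22, p12 * p21, cfg.degeneracy_tol):
        if cfg.degenerate_policy == "error":
            raise DegeneratePatternError(
                f"degenerate window at origin {pattern.origin}: leading minor vanishes",
                origin=pattern.origin)
        if cfg.degenerate_policy == "skip":
            return None
        return TextureUnit(0.0, 0.0, cfg.lam, degenerate=True)
    t1 = (p13 * p22 - p23 * p12) / d * cfg.lam
    t2 = (p11 * p23 - p21 * p13) / d * cfg.lam
    return TextureUnit(float(t1), float(t2), float(cfg.lam))


def image_to_vector(image, config: TransformConfig | None = None) -> TextureVector:
    """Transform an image into its texture vector C = (a1, a2, a3).

    Each component a_k is the sum of t_k over all (M-2)*(N-2) windows,
    accumulated in double precision. Under the default zero-ratio policy
    a3 = lam * n_patterns exactly; under ``skip``, degenerate windows drop
    out of all three sums.
    """
    cfg = config or TransformConfig()
    a = as_gray_image(image)
    m, n = a.shape
    n_patterns = (m - 2) * (n - 2)

    p11, p12, p13, p21, p22, p23 = _window_products(a)
    prod1 = p11 * p22
    prod2 = p12 * p21
    d = prod1 - prod2
    degenerate = np.abs(d) <= cfg.degeneracy_tol * np.maximum(
        1.0, np.abs(prod1) + np.abs(prod2))
    n_degenerate = int(np.count_nonzero(degenerate))

    if n_degenerate and cfg.degenerate_policy == "error":
        r, c = np.argwhere(degenerate)[0]
        raise DegeneratePatternError(
            f"degenerate window at origin ({r}, {c}): leading minor vanishes",
            origin=(int(r), int(c)))

    safe_d = np.where(degenerate, 1.0, d)
    t1 = np.where(degenerate, 0.0, (p13 * p22 - p23 * p12) / safe_d) * cfg.lam
    t2 = np.where(degenerate, 0.0, (p11 * p23 - p21 * p13) / safe_d) * cfg.lam

    a1 = float(np.sum(t1, dtype=np.float64))
    a2 = float(np.sum(t2, dtype=np.float64))
    if cfg.degenerate_policy == "skip":
        a3 = cfg.lam * (n_patterns - n_degenerate)
    else:
        a3 = cfg.lam * n_patterns
    return TextureVector(a1, a2, float(a3), n_patterns, n_degenerate, cfg.lam)


def vector_geometry(v) -> VectorGeometry:
    """Magnitude and direction cosines of a 3-component vector.

    The squares of the cosines sum to 1. Raises
    :class:`UndefinedDirectionError` for the zero vector, whose direction
    is undefined (its magnitude, 0, is reported in the message).
    """
    a = np.asarray(v, dtype=float).reshape(3)
    mag = math.sqrt(float(a @ a))
    if mag == 0.0:
        raise UndefinedDirectionError(
            "zero vector (magnitude 0) has no direction cosines")
    return VectorGeometry(mag, float(a[0] / mag), float(a[1] / mag), float(a[2] / mag))
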