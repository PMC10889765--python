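"""Raster loading, grayscale conversion and texture-vector CSV serialization."""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .core import TextureVector
from .errors import VectorParseError

__all__ = [
    "VectorRecord",
    "load_grayscale",
    "save_vectors",
    "load_vectors",
    "save_matrix",
    "load_matrix",
]

# ITU-R BT.601 luma weights, the classic MATLAB rgb2gray convention.
_LUMA = np.array([0.2989, 0.5870, 0.1140])

_VECTOR_HEADER = ["image_id", "lambda", "a1", "a2", "a3",
                  "n_patterns", "n_degenerate"]


@dataclass(frozen=True)
class VectorRecord:
    """One serialized texture vector with its provenance."""

    image_id: str
    vector: TextureVector


def load_grayscale(path) -> np.ndarray:
    """Load a raster image (PNG/TIFF/JPEG/BMP) as a real-valued gray matrix.

    Single-channel images pass through unchanged; RGB(A) is reduced with
    BT.601 luma weights 0.2989 R + 0.5870 G + 0.1140 B and kept as real
    values without requantization. 16-bit images keep their native scale.
    """
    try:
        a = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio wraps decoder failures variously
        raise OSError(f"cannot read image {path}: {exc}") from exc
    a = np.asarray(a)
    if a.size == 0:
        raise ValueError(f"zero-size image: {path}")
    if a.ndim == 2:
        return a.astype(float)
    if a.ndim == 3 and a.shape[2] in (3, 4):
        return a[:, :, :3].astype(float) @ _LUMA
    raise ValueError(f"unsupported image layout {a.shape} in {path}")


def save_vectors(records, path) -> None:
    """Write texture-vector records as CSV with a fixed header.

    Floats are rendered with `repr`, so a round trip through
    :func:`load_vectors` is bit-exact.
    """
    records = list(records)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_VECTOR_HEADER)
        for rec in records:
            v = rec.vector
            w.writerow([rec.image_id, repr(float(v.lam)), repr(float(v.a1)),
                        repr(float(v.a2)), repr(float(v.a3)),
                        int(v.n_patterns), int(v.n_degenerate)])


def load_vectors(path) -> list[VectorRecord]:
    """Read a texture-vector CSV written by :func:`save_vectors`."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise VectorParseError(f"{path}: empty file, expected header", line=1)
        if header != _VECTOR_HEADER:
            raise VectorParseError(
                f"{path}: bad header {header!r}, expected {_VECTOR_HEADER!r}", line=1)
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(_VECTOR_HEADER):
                raise VectorParseError(
                    f"{path}: line {lineno}: expected {len(_VECTOR_HEADER)} "
                    f"fields, got {len(row)}", line=lineno)
            try:
                vec = TextureVector(
                    a1=float(row[2]), a2=float(row[3]), a3=float(row[4]),
                    n_patterns=int(row[5]), n_degenerate=int(row[6]),
                    lam=float(row[1]))
            except ValueError as exc:
                raise VectorParseError(
                    f"{path}: line {lineno}: {exc}", line=lineno) from exc
            records.append(VectorRecord(image_id=row[0], vector=vec))
    return records


def save_matrix(df: pd.DataFrame, path) -> None:
    """Write a labeled similarity/confusion matrix as CSV with headers."""
    df.to_csv(path, index_label="label")


def load_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def iter_image_files(directory) -> list[Path]:
    """Sorted raster files (png/tif/tiff/jpg/jpeg/bmp) in a directory."""
    exts = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}
    d = Path(directory)
    return sorted(p for p in d.iterdir() if p.suffix.lower() in exts)
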