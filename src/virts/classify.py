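"""Cosine-similarity measurement and prototype classification in texture space.

Two images are compared through the angle between their texture vectors:
sim(u, v) = cos(phi) = (u . v) / (|u| |v|). Identical images give 1; the
measure is invariant to the scale factor lambda of the transform, which is
why classification results do not depend on lambda. A test image is
assigned to the prototype class of maximal cosine similarity, and results
over a test set are summarized in a confusion matrix H with efficiency
Ef% = 100 * trace(H) / sum(H).

Although the derivation considers similarities in [0, 1], texture vectors
can have negative components, so cos(phi) in [-1, 1] is admitted; the
argmax rule is unchanged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedSimilarityError, UnknownLabelError

__all__ = [
    "PrototypeSet",
    "difference_vector",
    "cosine_similarity",
    "similarity_matrix",
    "classify",
    "confusion_and_efficiency",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PrototypeSet:
    """Ordered (class label, prototype vector) pairs with unique labels."""

    entries: tuple[tuple[str, np.ndarray], ...]

    def __post_init__(self):
        if not self.entries:
            raise ValueError("prototype set must contain at least one entry")
        entries = []
        seen = set()
        for label, vec in self.entries:
            if label in seen:
                raise ValueError(f"duplicate prototype label {label!r}")
            seen.add(label)
            v = np.asarray(vec, dtype=float).reshape(3)
            if not np.any(v):
                raise UndefinedSimilarityError(
                    f"prototype {label!r} has zero magnitude")
            entries.append((label, v))
        object.__setattr__(self, "entries", tuple(entries))

    @property
    def labels(self) -> list[str]:
        return [label for label, _ in self.entries]

    @classmethod
    def from_items(cls, items) -> "PrototypeSet":
        """Build from any iterable of (label, vector) pairs or a dict."""
        pairs = items.items() if hasattr(items, "items") else items
        return cls(entries=tuple((str(k), v) for k, v in pairs))


def difference_vector(c_test, c_proto) -> np.ndarray:
    """Componentwise difference of two texture vectors, test minus prototype."""
    return np.asarray(c_test, dtype=float).reshape(3) - \
        np.asarray(c_proto, dtype=float).reshape(3)


def cosine_similarity(c_test, c_proto) -> float:
    """cos(phi) between two texture vectors, clamped to [-1, 1].

    Raises :class:`UndefinedSimilarityError` when either vector has zero
    magnitude.
    """
    u = np.asarray(c_test, dtype=float).reshape(3)
    v = np.asarray(c_proto, dtype=float).reshape(3)
    nu = math.sqrt(float(u @ u))
    nv = math.sqrt(float(v @ v))
    if nu == 0.0 or nv == 0.0:
        raise UndefinedSimilarityError(
            "cosine similarity undefined for a zero-magnitude vector")
    if np.array_equal(u, v):
        return 1.0  # identical vectors: keep the diagonal exactly 1
    return max(-1.0, min(1.0, float(u @ v) / (nu * nv)))


def similarity_matrix(tests, prototypes: PrototypeSet) -> pd.DataFrame:
    """Full cross matrix of cosine similarities.

    ``tests`` is a dict or iterable of (label, vector) pairs. Rows are test
    labels, columns prototype labels; the matrix is symmetric (and its
    diagonal is 1) when the test set equals the prototype set.
    """
    pairs = list(tests.items() if hasattr(tests, "items") else tests)
    data = [[cosine_similarity(vec, pvec) for _, pvec in prototypes.entries]
            for _, vec in pairs]
    return pd.DataFrame(data,
                        index=[str(label) for label, _ in pairs],
                        columns=prototypes.labels,
                        dtype=float)


def classify(c_test, prototypes: PrototypeSet) -> str:
    """Assign a test vector to the prototype class of maximal similarity.

    Ties are broken by earliest prototype in insertion order and logged.
    """
    sims = [cosine_similarity(c_test, vec) for _, vec in prototypes.entries]
    best = max(sims)
    winners = [i for i, s in enumerate(sims) if s == best]
    if len(winners) > 1:
        tied = [prototypes.labels[i] for i in winners]
        logger.warning("similarity tie among prototypes %s; keeping %r",
                       tied, tied[0])
    return prototypes.labels[winners[0]]


def confusion_and_efficiency(true_labels, predicted_labels,
                             labels: list[str]) -> tuple[pd.DataFrame, float]:
    """Confusion matrix H and classification efficiency Ef%.

    Rows are prototype (assigned) classes, columns test (true) classes.
    Ef% = 100 * (sum of the diagonal) / (sum of all entries). Any label
    outside ``labels`` raises :class:`UnknownLabelError`.
    """
    true_labels = [str(t) for t in true_labels]
    predicted_labels = [str(p) for p in predicted_labels]
    if len(true_labels) != len(predicted_labels):
        raise ValueError("true and predicted label sequences differ in length")
    index = {label: i for i, label in enumerate(labels)}
    h = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(true_labels, predicted_labels):
        if t not in index:
            raise UnknownLabelError(f"true label {t!r} not in prototype set")
        if p not in index:
            raise UnknownLabelError(f"predicted label {p!r} not in prototype set")
        h[index[p], index[t]] += 1
    total = int(h.sum())
    if total == 0:
        raise ValueError("no classified test images")
    efficiency = 100.0 * float(np.trace(h)) / total
    cm = pd.DataFrame(h, index=list(labels), columns=list(labels))
    return cm, efficiency
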