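"""Pairwise genetic distances between individuals from band scores.

Two metrics are offered for 0/1 band vectors:

* ``"mismatch-count"`` — number of loci with differing scores.  On binary
  vectors this *is* the squared Euclidean distance, the quantity AMOVA's
  sums of squares are built from.
* ``"p-distance"`` — mismatch count / n_loci, the per-site difference
  used for dendrogram branch lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .exceptions import ValidationError
from .matrix import BandMatrix

__all__ = ["DistanceMatrix", "pairwise_distance"]

METRICS = ("mismatch-count", "p-distance")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric distance matrix with labels and a metric tag."""

    labels: tuple[str, ...]
    values: np.ndarray
    metric: str

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("distance matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValidationError("label count does not match matrix size")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        if (v < -1e-12).any():
            raise ValidationError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def squared(self) -> np.ndarray:
        """Matrix of squared distances.

        Mismatch counts on 0/1 data already are squared Euclidean
        distances; any other metric is squared entrywise.
        """
        if self.metric == "mismatch-count":
            return self.values
        return self.values ** 2

    def select(self, labels: Sequence[str]) -> "DistanceMatrix":
        pos = {l: i for i, l in enumerate(self.labels)}
        idx = np.array([pos[l] for l in labels], dtype=int)
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)],
                              self.metric)


def pairwise_distance(matrix: BandMatrix,
                      metric: str = "mismatch-count") -> DistanceMatrix:
    """All-pairs distance between accessions of *matrix* under *metric*."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    x = matrix.values.astype(float)
    d = squareform(pdist(x, metric="cityblock"))  # = mismatch count on 0/1
    if metric == "p-distance":
        d = d / matrix.n_loci
    return DistanceMatrix(tuple(matrix.accession_ids), d, metric)
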