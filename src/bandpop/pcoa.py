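"""Principal coordinates analysis (metric multidimensional scaling).

Given a distance matrix D, PCoA double-centers -1/2 * D2 (Gower), where
D2 holds squared distances, and eigendecomposes the result.  Coordinates
are eigenvectors scaled by sqrt(lambda) for positive eigenvalues; axis
percentages divide each positive eigenvalue by the positive-eigenvalue
total.  Negative eigenvalues (non-Euclidean input) are retained in the
result but excluded from that denominator.

For the mismatch-count metric on band data the matrix entries already
*are* squared Euclidean distances and are centered as-is; any other
metric is squared first.  The per-axis sign is fixed by forcing the first
accession's coordinate (falling back to the largest-|loading| element
when that is ~0) non-negative, making output reproducible across linear
algebra backends.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import linalg

from .distance import DistanceMatrix
from .matrix import PopulationLayout

__all__ = ["PcoaResult", "pcoa", "population_centroids"]

_NULL_EIG_REL = 1e-10


@dataclass
class PcoaResult:
    """Eigenvalues, axis percentages and individual coordinates."""

    eigenvalues: np.ndarray          # all retained, descending
    axis_pct: np.ndarray             # per positive axis, sums to 100
    coordinates: pd.DataFrame        # individuals x positive axes
    n_positive_axes: int

    def summary(self, n_axes: int = 3) -> str:
        n = min(n_axes, self.n_positive_axes)
        lines = ["Principal coordinates analysis",
                 f"positive axes: {self.n_positive_axes}"]
        for i in range(n):
            lines.append(f"axis {i + 1}: eigenvalue {self.eigenvalues[i]:.4f}"
                         f"  ({self.axis_pct[i]:.2f}%)")
        lines.append(f"first {n} axes together: "
                     f"{self.axis_pct[:n].sum():.2f}%")
        return "\n".join(lines)


def pcoa(dist: DistanceMatrix,
         treat_as_squared: bool | None = None) -> PcoaResult:
    """Principal coordinates of *dist*.

    ``treat_as_squared`` overrides the metric-based default (mismatch
    counts are squared Euclidean distances; other metrics are squared
    entrywise before centering).
    """
    n = dist.n
    if n < 3:
        raise ValueError(f"PCoA needs at least 3 individuals, got {n}")
    if treat_as_squared is None:
        dsq = dist.squared()
    elif treat_as_squared:
        dsq = dist.values
    else:
        dsq = dist.values ** 2
    j = np.eye(n) - np.ones((n, n)) / n
    g = -0.5 * j @ dsq @ j
    g = (g + g.T) / 2.0
    eigval, eigvec = linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = np.abs(eigval) >= _NULL_EIG_REL * max(np.abs(eigval).max(), 1e-300)
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    pos = eigval > 0
    n_pos = int(pos.sum())
    coords = eigvec[:, pos] * np.sqrt(eigval[pos])
    # deterministic sign: first accession's coordinate non-negative per axis
    for jax in range(n_pos):
        pivot = coords[0, jax]
        if abs(pivot) < 1e-12:
            pivot = coords[np.argmax(np.abs(coords[:, jax])), jax]
        if pivot < 0:
            coords[:, jax] = -coords[:, jax]
    axis_pct = 100.0 * eigval[pos] / eigval[pos].sum() if n_pos else \
        np.empty(0)
    frame = pd.DataFrame(
        coords, index=list(dist.labels),
        columns=[f"axis{i + 1}" for i in range(n_pos)])
    return PcoaResult(eigenvalues=eigval, axis_pct=axis_pct,
                      coordinates=frame, n_positive_axes=n_pos)


def population_centroids(result: PcoaResult,
                         layout: PopulationLayout | Mapping[str, str]
                         ) -> pd.DataFrame:
    """Per-population mean coordinates on each positive axis.

    *layout* is either a :class:`PopulationLayout` (individuals assumed
    grouped in its population order) or a mapping accession -> population.
    """
    coords = result.coordinates
    if isinstance(layout, PopulationLayout):
        pop_of = {}
        pos = 0
        for p, s in zip(layout.populations, layout.sizes):
            for i in range(pos, pos + s):
                pop_of[coords.index[i]] = p
            pos += s
    else:
        pop_of = dict(layout)
    missing = [a for a in coords.index if a not in pop_of]
    if missing:
        raise ValueError(f"accessions without a population: {missing[:5]}")
    groups = coords.groupby([pop_of[a] for a in coords.index], sort=False)
    out = groups.mean()
    if (groups.size() == 0).any():
        raise ValueError("empty population in centroid computation")
    return out
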