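"""Binary agglomerative hierarchical clustering of expression profiles.

Four linkage rules are exposed — single, complete, average and centroid —
applied to a correlation distance (1 - Pearson r, the standard metric for
expression heat maps) or, by option, Euclidean distance.  A separation score
quantifies how cleanly a two-cluster cut of the sample dendrogram divides
tumor from adjacent-normal tissue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "LINKAGES",
    "Dendrogram",
    "correlation_distance",
    "euclidean_distance",
    "hierarchical_cluster",
    "separation_score",
]

LINKAGES = ("single", "complete", "average", "centroid")


@dataclass
class Dendrogram:
    """Agglomerative merge sequence over named leaves.

    ``merges`` is the standard linkage matrix: row i merges clusters
    ``merges[i, 0]`` and ``merges[i, 1]`` (indices < n are leaves, >= n are
    prior merges) at height ``merges[i, 2]`` into a cluster of size
    ``merges[i, 3]``.
    """

    labels: list[str]
    merges: np.ndarray
    linkage: str

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.merges.shape != (n - 1, 4):
            raise ValueError(f"expected {n - 1} merges for {n} leaves, got {self.merges.shape}")
        if np.any(self.merges[:, 2] < -1e-12):
            raise ValueError("merge heights must be non-negative")

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]

    def leaf_order(self) -> list[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.merges)]

    def cut(self, k: int) -> dict[str, int]:
        """Assign each leaf to one of ``k`` flat clusters."""
        assign = hierarchy.fcluster(self.merges, t=k, criterion="maxclust")
        return dict(zip(self.labels, (int(c) for c in assign)))

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(self.merges, columns=["left", "right", "height", "size"])


def correlation_distance(values: pd.DataFrame) -> pd.DataFrame:
    """Pairwise 1 - Pearson r between rows; range [0, 2], zero diagonal.

    Raises on zero-variance rows (correlation undefined there).
    """
    X = values.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need >=2 columns to correlate")
    sd = X.std(axis=1)
    dead = values.index[sd == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance rows: {dead[:5]}")
    r = np.corrcoef(X)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)  # symmetrize away rounding
    return pd.DataFrame(d, index=values.index, columns=values.index)


def euclidean_distance(values: pd.DataFrame) -> pd.DataFrame:
    X = values.to_numpy(dtype=float)
    diff = X[:, None, :] - X[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    return pd.DataFrame(d, index=values.index, columns=values.index)


def hierarchical_cluster(distances: pd.DataFrame, linkage: str = "average") -> Dendrogram:
    """Cluster from a symmetric distance matrix under the chosen linkage rule."""
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    d = distances.to_numpy(dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"distance matrix must be square, got {d.shape}")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if d.shape[0] < 2:
        raise ValueError("need >=2 items to cluster")
    condensed = squareform(d, checks=False)
    merges = hierarchy.linkage(condensed, method=linkage)
    return Dendrogram(labels=list(distances.index), merges=merges, linkage=linkage)


def separation_score(dendrogram: Dendrogram, group_of: dict[str, str]) -> float:
    """Purity of the two-cluster cut against the tumor/normal labels.

    Cuts the tree into two flat clusters and returns the maximal fraction of
    leaves correctly grouped over the two ways of matching clusters to
    labels; 1.0 means the cut perfectly separates the groups, 0.5 is chance
    for balanced groups.
    """
    if len(dendrogram.labels) < 2:
        raise ValueError("need >=2 leaves to score separation")
    missing = [l for l in dendrogram.labels if l not in group_of]
    if missing:
        raise ValueError(f"leaves without a group label: {missing[:5]}")
    assign = dendrogram.cut(2)
    labels = sorted({group_of[l] for l in dendrogram.labels})
    if len(labels) == 1:
        return 1.0
    n = len(dendrogram.labels)
    # contingency of cluster (1/2) vs true label
    counts = {(c, g): 0 for c in (1, 2) for g in labels}
    for leaf in dendrogram.labels:
        counts[(assign[leaf], group_of[leaf])] += 1
    straight = counts[(1, labels[0])] + counts[(2, labels[1])]
    crossed = counts[(1, labels[1])] + counts[(2, labels[0])]
    return max(straight, crossed) / n
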