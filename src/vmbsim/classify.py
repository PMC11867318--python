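"""Nearest-centroid community state classification.

A light-weight stand-in for the VALENCIA classifier: a composition is
assigned the label of the centroid (in relative-abundance space) closest in
Euclidean distance.  The default centroids are the one-hot unit vectors for
the four species groups, which reduces the rule to "label = most abundant
group"; VALENCIA-derived centroids can be loaded from CSV instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SPECIES, N_SPECIES, CommunityState

__all__ = ["CentroidSet", "default_centroids", "classify_cst", "classify_compositions"]

#: Tie-break priority (ambiguous compositions count as treatment failure).
LABELS: tuple[str, ...] = ("nAB", "Li", "oLB", "P")


@dataclass
class CentroidSet:
    """Ordered mapping label -> 4-vector of relative abundances.

    Order encodes the tie-break priority: the first centroid at minimal
    distance wins.
    """

    labels: tuple[str, ...]
    centroids: np.ndarray  # (n_labels, 4), rows sum to 1

    def __post_init__(self) -> None:
        c = np.asarray(self.centroids, dtype=float)
        if c.ndim != 2 or c.shape[1] != N_SPECIES:
            raise ValueError(f"centroids must be (n, {N_SPECIES})")
        if len(self.labels) != c.shape[0]:
            raise ValueError("one label per centroid required")
        if np.any(c < 0) or np.any(c > 1):
            raise ValueError("centroid entries must lie in [0, 1]")
        if not np.allclose(c.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("each centroid must sum to 1")
        self.centroids = c
        self.labels = tuple(self.labels)

    @classmethod
    def from_csv(cls, path) -> "CentroidSet":
        df = pd.read_csv(path)
        labels = tuple(df.iloc[:, 0].astype(str))
        return cls(labels, df.iloc[:, 1 : 1 + N_SPECIES].to_numpy(float))

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.centroids, columns=list(SPECIES))
        df.insert(0, "label", list(self.labels))
        df.to_csv(path, index=False)


def default_centroids() -> CentroidSet:
    """One-hot centroids: pure dominance semantics, priority nAB > Li > oLB > P."""
    return CentroidSet(LABELS, np.eye(N_SPECIES))


def classify_compositions(rel: np.ndarray, centroids: CentroidSet | None = None) -> np.ndarray:
    """Vectorized nearest-centroid labels for an (n, 4) matrix of relative abundances."""
    if centroids is None:
        centroids = default_centroids()
    rel = np.asarray(rel, dtype=float)
    d2 = ((rel[:, None, :] - centroids.centroids[None, :, :]) ** 2).sum(axis=2)
    # first centroid within float noise of the minimum: stable priority tie-break
    near = d2 <= d2.min(axis=1, keepdims=True) + 1e-12
    idx = near.argmax(axis=1)
    labels = np.asarray(centroids.labels, dtype=object)
    return labels[idx]


def classify_cst(state: CommunityState | np.ndarray, centroids: CentroidSet | None = None) -> str:
    """Label one community by its nearest centroid in relative-abundance space.

    Raises ``ValueError`` for an empty community (composition undefined).
    """
    if isinstance(state, CommunityState):
        x = state.abundances
    else:
        x = np.asarray(state, dtype=float)
    total = x.sum()
    if total <= 0:
        raise ValueError("total abundance is zero: composition undefined")
    return str(classify_compositions((x / total)[None, :], centroids)[0])
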