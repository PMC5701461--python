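"""Glycan-microarray clustering: RMS normalization and complete linkage.

Binding matrices are pandas DataFrames (rows = Siglec-Fc samples, columns =
glycans, values = background-subtracted relative fluorescence units).  Each
sample's profile is normalized by its root mean square so profile shape,
not magnitude, drives the unsupervised hierarchical clustering
(complete linkage on Euclidean distances, both axes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist


def rms_normalize(M: pd.DataFrame, axis: str = "rows") -> pd.DataFrame:
    """Divide each row (or column) by the root mean square of its entries."""
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    X = M.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in matrix")
    ax = 1 if axis == "rows" else 0
    rms = np.sqrt((X ** 2).mean(axis=ax))
    zero = np.flatnonzero(rms == 0)
    if zero.size:
        names = (M.index if axis == "rows" else M.columns)[zero].tolist()
        raise ValueError(f"all-zero vector(s) cannot be RMS-normalized: {names}")
    out = X / (rms[:, None] if axis == "rows" else rms[None, :])
    return pd.DataFrame(out, index=M.index, columns=M.columns)


@dataclass
class Dendrogram:
    """Agglomerative merge sequence over named leaves.

    Z is a scipy linkage matrix; merges lists (members_a, members_b, height)
    with members as sorted leaf-name tuples.
    """

    labels: list[str]
    Z: np.ndarray

    @property
    def merges(self) -> list[tuple[tuple[str, ...], tuple[str, ...], float]]:
        n = len(self.labels)
        clusters: dict[int, tuple[str, ...]] = {
            i: (self.labels[i],) for i in range(n)
        }
        out = []
        for k, (a, b, h, _cnt) in enumerate(self.Z):
            ca, cb = clusters[int(a)], clusters[int(b)]
            merged = tuple(sorted(ca + cb))
            clusters[n + k] = merged
            out.append((ca, cb, float(h)))
        return out

    @property
    def heights(self) -> np.ndarray:
        return self.Z[:, 2]

    def cluster_sets(self) -> list[frozenset]:
        """All non-singleton clusters formed during the merge sequence."""
        return [frozenset(a) | frozenset(b) for a, b, _ in self.merges]

    def to_newick(self) -> str:
        n = len(self.labels)
        reps: dict[int, str] = {i: self.labels[i] for i in range(n)}
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        for k, (a, b, h, _cnt) in enumerate(self.Z):
            a, b = int(a), int(b)
            la = h - height[a]
            lb = h - height[b]
            reps[n + k] = f"({reps[a]}:{la:g},{reps[b]}:{lb:g})"
            height[n + k] = h
        return reps[n + len(self.Z) - 1] + ";"


def hcluster_complete(M: pd.DataFrame, axis: str = "rows") -> Dendrogram:
    """Complete-linkage (max inter-cluster Euclidean distance) clustering."""
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    X = M.to_numpy(dtype=float) if axis == "rows" else M.to_numpy(dtype=float).T
    labels = list(M.index if axis == "rows" else M.columns)
    if X.shape[0] < 2:
        raise ValueError("need >= 2 items to cluster")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in matrix")
    Z = linkage(pdist(X, metric="euclidean"), method="complete")
    dendro = Dendrogram([str(lbl) for lbl in labels], Z)
    h = dendro.heights
    assert np.all(np.diff(h) >= -1e-12), "complete-linkage heights must be monotone"
    return dendro


def comembership_check(D: Dendrogram, group, exact: bool = True) -> tuple[bool, int]:
    """Does `group` appear as one cluster of the merge sequence?

    Returns (found, size of the smallest cluster containing the group).
    With exact=False, `found` is True whenever the smallest containing
    cluster equals the group (always true for singletons and the full set).
    """
    group = frozenset(str(g) for g in group)
    leaves = set(D.labels)
    unknown = group - leaves
    if unknown:
        raise KeyError(f"unknown leaves {sorted(unknown)}")
    if len(group) <= 1 or group == leaves:
        return True, len(group) if group else 0
    candidates = [c for c in D.cluster_sets() if group <= c]
    smallest = min(candidates, key=len) if candidates else frozenset(leaves)
    found = any(c == group for c in candidates) if exact else smallest == group
    return found, len(smallest)


def read_glycan_tsv(path) -> pd.DataFrame:
    """Rows = Siglec samples (first column), header = glycan IDs."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_glycan_tsv(M: pd.DataFrame, path) -> None:
    M.to_csv(path, sep="\t")
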