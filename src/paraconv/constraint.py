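"""Relaxed-constraint analysis on a fixed reference topology.

For each site-class partition (nonsynonymous, synonymous, intronic) a
Jukes–Cantor distance matrix is computed and per-branch substitution
numbers are obtained by ordinary least squares on the fixed topology: with
X the 0/1 path-incidence matrix (rows = taxon pairs, columns = edges) and d
the vector of pairwise distances, branch lengths solve min ||Xb - d||^2.
The neutral expectation per branch is the mean of the synonymous and
intronic branch lengths, and a per-branch Z-test of
b_nonsyn - b_neutral (SE from a column bootstrap within each partition)
flags branches where protein-level constraint is relaxed (ratio near 1)
or where purifying selection holds (ratio well below 1).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .seq_io import Alignment, SitePartition
from .trees import DistanceMatrix, PhyloTree, alignment_pair_stats, canonical_side


def edge_incidence(topology: PhyloTree, taxa: list[str]):
    """Path-incidence matrix of a fixed topology.

    Returns (edge_ids, X) with X of shape (n_pairs, n_edges); pairs are
    ordered (i<j) over `taxa`, edges identified by the sorted leaf names of
    their canonical (unrooted) bipartition side, joined with '+'.
    """
    if set(taxa) != set(topology.leaves):
        raise ValueError("topology leaf set does not match distance taxa")
    all_leaves = frozenset(taxa)
    edges = [nd for nd in topology.nodes() if nd.parent is not None]
    if len(topology.root.children) == 2:
        # a rooted binary topology: the two root edges are one unrooted edge
        edges = [nd for nd in edges if nd is not topology.root.children[1]]
    ids = []
    below: list[frozenset] = []
    for nd in edges:
        side = frozenset(nd.leaf_names())
        below.append(side)
        ids.append("+".join(canonical_side(side, all_leaves)))
    pairs = [(i, j) for i in range(len(taxa)) for j in range(i + 1, len(taxa))]
    X = np.zeros((len(pairs), len(edges)))
    for k, (i, j) in enumerate(pairs):
        for e, side in enumerate(below):
            # edge lies on the i-j path iff it separates the two leaves
            if (taxa[i] in side) != (taxa[j] in side):
                X[k, e] = 1.0
    return ids, X


def ols_branch_lengths(D: DistanceMatrix, topology: PhyloTree,
                       weighted: bool = False):
    """OLS branch lengths on the fixed topology.

    Returns (lengths: pd.Series indexed by edge id, rss).  Negative
    estimates are retained.  With weighted=True, pairs are weighted by
    1/var (pairs with zero variance get the largest finite weight present).
    """
    if len(D.taxa) < 3:
        raise ValueError("need >= 3 taxa for branch-length estimation")
    ids, X = edge_incidence(topology, D.taxa)
    iu = np.triu_indices(len(D.taxa), k=1)
    d = D.d[iu]
    if weighted:
        v = D.var[iu].copy()
        pos = v > 0
        if not pos.any():
            w = np.ones_like(v)
        else:
            v[~pos] = v[pos].min()
            w = 1.0 / v
        sw = np.sqrt(w)
        Xw, dw = X * sw[:, None], d * sw
    else:
        Xw, dw = X, d
    if np.linalg.matrix_rank(Xw) < X.shape[1]:
        raise ValueError("rank-deficient incidence matrix")
    b, *_ = np.linalg.lstsq(Xw, dw, rcond=None)
    rss = float(((X @ b - d) ** 2).sum())
    return pd.Series(b, index=ids, name="branch_length"), rss


def _normalize_partition(partition) -> dict[str, list[int]]:
    if isinstance(partition, SitePartition):
        cols = {
            "nonsynonymous": partition.columns_of("nonsynonymous"),
            "synonymous": partition.columns_of("synonymous"),
            "intronic": partition.columns_of("noncoding"),
        }
    else:
        cols = dict(partition)
        if "intronic" not in cols and "noncoding" in cols:
            cols["intronic"] = cols.pop("noncoding")
    for name in ("nonsynonymous", "synonymous", "intronic"):
        if not cols.get(name):
            raise ValueError(f"partition {name!r} has zero usable columns")
    return cols


def _jc_from_weighted(diff, valid, w):
    """JC distances for bootstrap column-weight matrix w (L x n_boot)."""
    Lp = valid @ w
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(Lp > 0, (diff @ w) / np.maximum(Lp, 1), np.nan)
        d = np.where(p < 0.75, -0.75 * np.log1p(-4.0 * np.minimum(p, 0.7499) / 3.0),
                     np.nan)
    return d


def branch_constraint_test(aln: Alignment, partition, topology: PhyloTree,
                           n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-branch relaxed-constraint Z-tests.

    Returns a DataFrame indexed by edge id with per-partition branch
    lengths, the neutral mean, the nonsyn/neutral ratio, the bootstrap SE
    of b_nonsyn - b_neutral, Z and the two-sided normal p-value.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    cols = _normalize_partition(partition)
    pairs, valid_all, diff_all, _ = alignment_pair_stats(aln)
    n = aln.n_sequences
    iu_pairs = pairs
    ids, X = edge_incidence(topology, list(aln.names))
    pinv = np.linalg.pinv(X)

    rng = np.random.default_rng(seed)
    point: dict[str, np.ndarray] = {}
    boots: dict[str, np.ndarray] = {}
    for name in ("nonsynonymous", "synonymous", "intronic"):
        idx = np.asarray(cols[name])
        valid = valid_all[:, idx]
        diff = diff_all[:, idx]
        L = idx.size
        Lp = valid.sum(axis=1).astype(float)
        if np.any(Lp == 0):
            raise ValueError(f"partition {name!r}: zero comparable sites for a pair")
        p = diff.sum(axis=1) / Lp
        if np.any(p >= 0.75):
            raise ValueError(f"partition {name!r}: saturated JC distance")
        d = -0.75 * np.log1p(-4.0 * p / 3.0)
        point[name] = pinv @ d
        w = rng.multinomial(L, np.full(L, 1.0 / L), size=n_boot).T.astype(float)
        d_boot = _jc_from_weighted(diff, valid, w)  # (n_pairs, n_boot)
        boots[name] = pinv @ np.nan_to_num(d_boot)
        bad = np.isnan(d_boot).any(axis=0)
        if bad.any():
            boots[name][:, bad] = np.nan
            if bad.sum() > 0.1 * n_boot:
                warnings.warn(
                    f"partition {name!r}: {int(bad.sum())}/{n_boot} bootstrap "
                    "replicates dropped (saturation)"
                )

    b_non, b_syn, b_int = (point[k] for k in ("nonsynonymous", "synonymous", "intronic"))
    b_neutral = 0.5 * (b_syn + b_int)
    diff_stat = b_non - b_neutral
    diff_boot = boots["nonsynonymous"] - 0.5 * (boots["synonymous"] + boots["intronic"])
    se = np.nanstd(diff_boot, axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, diff_stat / se, np.nan)
        ratio = np.where(b_neutral > 0, b_non / b_neutral, np.nan)
    pvals = np.where(np.isfinite(z), 2.0 * stats.norm.sf(np.abs(z)), np.nan)
    assert len(iu_pairs) == n * (n - 1) // 2
    return pd.DataFrame(
        {
            "b_nonsyn": b_non,
            "b_syn": b_syn,
            "b_intron": b_int,
            "b_neutral": b_neutral,
            "ratio": ratio,
            "diff": diff_stat,
            "se_diff": se,
            "Z": z,
            "p": pvals,
        },
        index=pd.Index(ids, name="branch"),
    )


def annotate_ratios_newick(topology: PhyloTree, table: pd.DataFrame) -> str:
    """Newick with the nonsyn/neutral ratio as per-branch annotations."""
    all_leaves = frozenset(topology.leaves)

    def fmt(nd) -> str:
        if nd.is_leaf():
            body = nd.name
        else:
            body = "(" + ",".join(fmt(c) for c in nd.children) + ")"
        if nd.parent is not None:
            eid = "+".join(canonical_side(nd.leaf_names(), all_leaves))
            ratio = table.loc[eid, "ratio"] if eid in table.index else float("nan")
            body += f"[ratio={ratio:.3f}]" if np.isfinite(ratio) else "[ratio=NA]"
            body += f":{nd.length:g}"
        return body

    return fmt(topology.root) + ";"
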