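"""Independent brute-force oracles used by the test suite.

Each oracle recomputes a quantity by the most direct route available
(explicit enumeration, naive loops, or a third-party implementation) so
the package's optimized code paths are checked against something that
shares none of their logic.
"""

from __future__ import annotations

import io
import itertools
import math

import dendropy
import numpy as np
from Bio.Seq import Seq

CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
AA = {c: str(Seq(c).translate()) for c in CODONS}


# --- Nei-Gojobori ----------------------------------------------------------

def ng_syn_sites(codon: str) -> float:
    """Synonymous site count by enumerating all 9 single-base neighbors."""
    syn = 0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if AA[alt] == AA[codon] and AA[alt] != "*":
                syn += 1
    return syn / 3.0


# --- sliding identity ------------------------------------------------------

def brute_sliding_identity(s1: str, s2: str, window: int, step: int):
    """Window identities via explicit per-window loops, gap columns stripped."""
    a, b = [], []
    for x, y in zip(s1, s2):
        if x in "-N" or y in "-N":
            continue
        a.append(x)
        b.append(y)
    values = []
    for start in range(0, len(a) - window + 1, step):
        matches = sum(1 for k in range(start, start + window) if a[k] == b[k])
        values.append(matches / window)
    return values


# --- hierarchical clustering ----------------------------------------------

def naive_complete_linkage(X: np.ndarray, labels: list[str]):
    """Agglomeration by explicit search; lexicographic tie-breaking.

    Returns the sorted list of merge heights.
    """
    clusters: dict[tuple[str, ...], list[int]] = {
        (labels[i],): [i] for i in range(len(labels))
    }
    heights = []
    while len(clusters) > 1:
        best = None
        for ka, kb in itertools.combinations(sorted(clusters), 2):
            dmax = max(
                math.dist(X[i], X[j])
                for i in clusters[ka] for j in clusters[kb]
            )
            key = (dmax, tuple(sorted((ka, kb))))
            if best is None or key < best[0]:
                best = (key, ka, kb)
        (_h, _), ka, kb = best
        heights.append(_h)
        merged = tuple(sorted(ka + kb))
        members = clusters.pop(ka) + clusters.pop(kb)
        clusters[merged] = members
    return sorted(heights)


# --- trees -----------------------------------------------------------------

def canonical_bipartitions(sides, all_leaves):
    ref = min(all_leaves)
    out = set()
    for side in sides:
        side = frozenset(side)
        if ref in side:
            side = frozenset(all_leaves) - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out.add(side)
    return out


def dendropy_nj_bipartitions(taxa: list[str], d: np.ndarray):
    """Unrooted NJ bipartitions from dendropy, as canonical frozensets."""
    buf = io.StringIO()
    buf.write("." + "".join(f",{t}" for t in taxa) + "\n")
    for i, t in enumerate(taxa):
        buf.write(t + "".join(f",{d[i, j]:.12f}" for j in range(len(taxa))) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src=buf, delimiter=",")
    tree = pdm.nj_tree()
    sides = []
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        if head is None or edge.tail_node is None or head.is_leaf():
            continue
        sides.append([lf.taxon.label for lf in head.leaf_iter()])
    return canonical_bipartitions(sides, set(taxa))


def networkx_incidence(tree_root, taxa: list[str]):
    """Path-incidence matrix via shortest paths in an explicit graph."""
    import networkx as nx

    g = nx.Graph()
    ids = {}
    counter = [0]

    def node_id(nd):
        if id(nd) not in ids:
            counter[0] += 1
            ids[id(nd)] = nd.name if (nd.is_leaf() and nd.name) else f"__i{counter[0]}"
        return ids[id(nd)]

    edges = []
    stack = [tree_root]
    while stack:
        nd = stack.pop()
        for ch in nd.children:
            g.add_edge(node_id(nd), node_id(ch))
            edges.append((node_id(nd), node_id(ch)))
            stack.append(ch)
    pairs = [(i, j) for i in range(len(taxa)) for j in range(i + 1, len(taxa))]
    X = np.zeros((len(pairs), len(edges)))
    for k, (i, j) in enumerate(pairs):
        path = nx.shortest_path(g, taxa[i], taxa[j])
        on_path = set(zip(path, path[1:])) | set(zip(path[1:], path))
        for e, (u, v) in enumerate(edges):
            if (u, v) in on_path:
                X[k, e] = 1.0
    return edges, X


def chi2_1_sf(x: float) -> float:
    """Upper tail of chi-square with 1 df via the error function."""
    return math.erfc(math.sqrt(x / 2.0))


def naive_nj_bipartitions(taxa: list[str], d: np.ndarray):
    """Plain dictionary-based Saitou-Nei NJ (lexicographic tie-break on the
    smallest member name of each cluster); returns canonical bipartitions."""
    dist = {}
    for i, a in enumerate(taxa):
        for j, b in enumerate(taxa):
            if i < j:
                dist[frozenset((a, b))] = float(d[i, j])
    clusters = {t: frozenset([t]) for t in taxa}
    sides = []
    while len(clusters) > 3:
        names = sorted(clusters)
        m = len(names)
        r = {a: sum(dist[frozenset((a, b))] for b in names if b != a)
             for a in names}
        best = None
        for ii, a in enumerate(names):
            for b in names[ii + 1:]:
                q = (m - 2) * dist[frozenset((a, b))] - r[a] - r[b]
                key = (round(q, 12), a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        new = min(a, b)
        merged = clusters[a] | clusters[b]
        dab = dist[frozenset((a, b))]
        newd = {}
        for c in names:
            if c in (a, b):
                continue
            newd[c] = 0.5 * (dist[frozenset((a, c))] + dist[frozenset((b, c))] - dab)
        for c in names:
            if c in (a, b):
                continue
            dist[frozenset((new, c))] = newd[c]
        clusters.pop(a), clusters.pop(b)
        clusters[new] = merged
        sides.append(merged)
    return canonical_bipartitions(sides, set(taxa))
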