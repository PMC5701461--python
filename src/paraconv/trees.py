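"""Corrected pairwise distances, neighbor-joining, bootstrap, and the
conversion-signature topology test.

Gene conversion between paralogs leaves a diagnostic phylogenetic
incongruence: inside a converted region the two paralogs of a species are
each other's closest relatives (within-species clustering), while outside
it the tree follows the locus-wise (paralogous) pattern expected from a
single ancient duplication.  This module builds the trees (Saitou–Nei NJ on
Jukes–Cantor- or Kimura-corrected distances, with column bootstrap) and
classifies species as converted/unconverted from the two topologies.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .seq_io import Alignment, GAPLIKE

PURINES = frozenset("AG")

# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray               # corrected distances, symmetric
    var: np.ndarray             # sampling variances
    model: str                  # 'p' | 'JC69' | 'K2P'
    sites_compared: np.ndarray  # per-pair ungapped columns

    def pair(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])

    def pair_var(self, a: str, b: str) -> float:
        return float(self.var[self.taxa.index(a), self.taxa.index(b)])


class SaturatedDistanceError(ValueError):
    pass


def alignment_pair_stats(aln: Alignment):
    """Per-pair, per-column comparability/mismatch/transition masks.

    Returns (pairs, valid, diff, ts) where valid/diff/ts are
    (n_pairs, length) boolean arrays; shared by the distance and bootstrap
    code so column resampling reduces to integer-weighted sums.
    """
    mat = aln.as_matrix()
    n, L = mat.shape
    gap = np.isin(mat, list(GAPLIKE))
    purine = np.isin(mat, list(PURINES))
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    valid = np.empty((len(pairs), L), dtype=bool)
    diff = np.empty_like(valid)
    ts = np.empty_like(valid)
    for k, (i, j) in enumerate(pairs):
        valid[k] = ~gap[i] & ~gap[j]
        diff[k] = (mat[i] != mat[j]) & valid[k]
        ts[k] = diff[k] & (purine[i] == purine[j])  # transition: within pu/py
    return pairs, valid, diff, ts


def _correct(p: np.ndarray, q: np.ndarray, L: np.ndarray, model: str):
    """Distance + variance from mismatch (p) and transversion (q) proportions."""
    if model == "p":
        return p, p * (1 - p) / np.maximum(L, 1)
    if model == "JC69":
        if np.any(p >= 0.75):
            raise SaturatedDistanceError(
                "saturated distance: mismatch proportion >= 0.75 under JC69"
            )
        d = -0.75 * np.log1p(-4.0 * p / 3.0)
        var = p * (1 - p) / (np.maximum(L, 1) * (1 - 4.0 * p / 3.0) ** 2)
        return d, var
    if model == "K2P":
        P = p - q  # transitions
        Q = q
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        if np.any(w1 <= 0) or np.any(w2 <= 0):
            raise SaturatedDistanceError("saturated distance under K2P")
        d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
        c1 = 1.0 / w1
        c2 = 1.0 / w2
        c3 = 0.5 * (c1 + c2)
        var = (c1 ** 2 * P + c3 ** 2 * Q - (c1 * P + c3 * Q) ** 2) / np.maximum(L, 1)
        return d, var
    raise ValueError(f"unknown model {model!r}")


def pairwise_distance(aln: Alignment, model: str = "JC69") -> DistanceMatrix:
    """Pairwise-deletion distances under p, JC69 or K2P."""
    if aln.n_sequences < 2:
        raise ValueError("need >= 2 sequences")
    pairs, valid, diff, ts = alignment_pair_stats(aln)
    L = valid.sum(axis=1).astype(float)
    if np.any(L == 0):
        raise ValueError("zero comparable sites for some pair")
    p = diff.sum(axis=1) / L
    q = (diff.sum(axis=1) - ts.sum(axis=1)) / L  # transversions
    d_flat, var_flat = _correct(p, q, L, model)
    n = aln.n_sequences
    d = np.zeros((n, n))
    var = np.zeros((n, n))
    sites = np.zeros((n, n))
    for k, (i, j) in enumerate(pairs):
        d[i, j] = d[j, i] = d_flat[k]
        var[i, j] = var[j, i] = var_flat[k]
        sites[i, j] = sites[j, i] = L[k]
    return DistanceMatrix(list(aln.names), d, var, model, sites)


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)
    parent: "TreeNode | None" = None

    def is_leaf(self) -> bool:
        return not self.children

    def leaf_names(self) -> list[str]:
        if self.is_leaf():
            return [self.name]
        out = []
        for ch in self.children:
            out.extend(ch.leaf_names())
        return out


def canonical_side(side, all_leaves) -> tuple[str, ...]:
    """Canonical representation of an unrooted bipartition: the smaller
    side, ties broken by the lexicographically smaller sorted tuple."""
    side = frozenset(side)
    comp = frozenset(all_leaves) - side
    a, b = tuple(sorted(side)), tuple(sorted(comp))
    if (len(a), a) <= (len(b), b):
        return a
    return b


@dataclass
class PhyloTree:
    """Rooted representation of an (often unrooted) tree.

    NJ output is unrooted with a trifurcation at the stored root; all
    bipartition operations treat it as unrooted.
    """

    root: TreeNode

    @property
    def leaves(self) -> list[str]:
        return self.root.leaf_names()

    def nodes(self):
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(nd.children)

    # --- Newick -----------------------------------------------------------
    def newick(self, digits: int = 10) -> str:
        def fmt(nd: TreeNode) -> str:
            if nd.is_leaf():
                body = nd.name
            else:
                body = "(" + ",".join(fmt(c) for c in nd.children) + ")"
                if nd.support is not None:
                    body += f"{nd.support:g}"
            if nd.parent is not None:
                body += f":{nd.length:.{digits}g}"
            return body

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        dt = dendropy.Tree.get(data=text, schema="newick",
                               suppress_internal_node_taxa=True)

        def convert(nd) -> TreeNode:
            node = TreeNode()
            if nd.is_leaf():
                node.name = nd.taxon.label.replace(" ", "_")
            else:
                if nd.label is not None:
                    try:
                        node.support = float(nd.label)
                    except ValueError:
                        node.name = nd.label
            node.length = nd.edge.length if nd.edge.length is not None else 0.0
            for ch in nd.child_nodes():
                child = convert(ch)
                child.parent = node
                node.children.append(child)
            return node

        return cls(convert(dt.seed_node))

    # --- bipartitions -----------------------------------------------------
    def bipartitions(self, include_trivial: bool = False):
        """Map canonical leaf-side frozenset -> node below the edge.

        Canonical side: the side not containing the lexicographically first
        leaf, so unrooted bipartitions compare across differently rooted
        trees.
        """
        all_leaves = frozenset(self.leaves)
        ref = min(all_leaves)
        out: dict[frozenset, TreeNode] = {}
        for nd in self.nodes():
            if nd.parent is None:
                continue
            side = frozenset(nd.leaf_names())
            if ref in side:
                side = all_leaves - side
            if not include_trivial and (len(side) < 2 or len(side) > len(all_leaves) - 2):
                continue
            out[side] = nd
        return out

    def has_clade(self, group) -> tuple[bool, float | None]:
        """Is `group` one unrooted bipartition side?  Returns (bool, support)."""
        group = frozenset(group)
        all_leaves = frozenset(self.leaves)
        unknown = group - all_leaves
        if unknown:
            raise KeyError(f"unknown leaves {sorted(unknown)}")
        ref = min(all_leaves)
        if ref in group:
            group = all_leaves - group
        bip = self.bipartitions(include_trivial=True)
        if group in bip:
            return True, bip[group].support
        return False, None


def _three_point(dab, dac, dbc):
    la = 0.5 * (dab + dac - dbc)
    lb = 0.5 * (dab + dbc - dac)
    lc = 0.5 * (dac + dbc - dab)
    return la, lb, lc


def nj_tree(D: DistanceMatrix, clamp_negative: bool = True) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    Ties in the Q criterion are broken by the lexicographically smallest
    (min leaf name) pair so the result is deterministic.  Negative branch
    lengths are clamped to zero with the remainder transferred to the
    sister branch (disable with clamp_negative=False).
    """
    n0 = len(D.taxa)
    if n0 < 3:
        raise ValueError("NJ needs >= 3 taxa")
    nodes = [TreeNode(name=t) for t in D.taxa]
    reps = [t for t in D.taxa]  # tie-break representative per cluster
    d = D.d.astype(float).copy()
    active = list(range(n0))

    def join_key(i, j):
        return tuple(sorted((reps[i], reps[j])))

    nxt = n0
    d = np.pad(d, ((0, 2 * n0), (0, 2 * n0)))
    nodes += [None] * (2 * n0)
    reps += [None] * (2 * n0)

    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        sub = d[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        ties = np.argwhere(q <= qmin + 1e-12 * max(1.0, abs(qmin)))
        best = min(
            ((a, b) for a, b in ties if a < b),
            key=lambda ab: join_key(idx[ab[0]], idx[ab[1]]),
        )
        ia, ib = idx[best[0]], idx[best[1]]
        dij = d[ia, ib]
        vi = 0.5 * dij + (r[best[0]] - r[best[1]]) / (2.0 * (m - 2))
        vj = dij - vi
        if clamp_negative:
            if vi < 0:
                vj += vi
                vi = 0.0
            if vj < 0:
                vi += vj
                vj = 0.0
        parent = TreeNode()
        for child, length in ((nodes[ia], vi), (nodes[ib], vj)):
            child.length = float(length)
            child.parent = parent
            parent.children.append(child)
        nodes[nxt] = parent
        reps[nxt] = min(reps[ia], reps[ib])
        for k in active:
            if k in (ia, ib):
                continue
            duk = 0.5 * (d[ia, k] + d[ib, k] - dij)
            d[nxt, k] = d[k, nxt] = duk
        active = [k for k in active if k not in (ia, ib)] + [nxt]
        nxt += 1

    a, b, c = sorted(active, key=lambda k: reps[k])
    la, lb, lc = _three_point(d[a, b], d[a, c], d[b, c])
    if clamp_negative:
        la, lb, lc = (max(x, 0.0) for x in (la, lb, lc))
    root = TreeNode()
    for k, length in ((a, la), (b, lb), (c, lc)):
        nodes[k].length = float(length)
        nodes[k].parent = root
        root.children.append(nodes[k])
    return PhyloTree(root)


def bootstrap_support(aln: Alignment, model: str = "JC69", n_reps: int = 1000,
                      seed: int = 0, clamp_negative: bool = True) -> PhyloTree:
    """NJ tree with internal-edge supports from a column bootstrap.

    Columns are resampled with replacement; each internal bipartition of
    the point-estimate tree is annotated with its frequency (x100) among
    the replicates.  Replicates with saturated distances are dropped (a
    warning fires when more than 10% drop).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    point = nj_tree(pairwise_distance(aln, model), clamp_negative)
    pairs, valid, diff, ts = alignment_pair_stats(aln)
    L_cols = aln.length
    rng = np.random.default_rng(seed)
    counts: Counter = Counter()
    dropped = 0
    n = aln.n_sequences
    for _ in range(n_reps):
        w = rng.multinomial(L_cols, np.full(L_cols, 1.0 / L_cols)).astype(float)
        Lp = valid @ w
        if np.any(Lp == 0):
            dropped += 1
            continue
        p = (diff @ w) / Lp
        q = ((diff @ w) - (ts @ w)) / Lp
        try:
            d_flat, _ = _correct(p, q, Lp, model)
        except SaturatedDistanceError:
            dropped += 1
            continue
        dm = np.zeros((n, n))
        for k, (i, j) in enumerate(pairs):
            dm[i, j] = dm[j, i] = d_flat[k]
        rep_tree = nj_tree(
            DistanceMatrix(list(aln.names), dm, np.zeros_like(dm), model, Lp),
            clamp_negative,
        )
        counts.update(rep_tree.bipartitions().keys())
    ok = n_reps - dropped
    if dropped > 0.1 * n_reps:
        warnings.warn(f"{dropped}/{n_reps} bootstrap replicates dropped (saturation)")
    if ok == 0:
        raise SaturatedDistanceError("all bootstrap replicates saturated")
    for side, node in point.bipartitions().items():
        node.support = 100.0 * counts.get(side, 0) / ok
    return point


# ---------------------------------------------------------------------------
# conversion signature
# ---------------------------------------------------------------------------


@dataclass
class ConversionCall:
    species: str
    converted: bool | None      # None = not applicable (single locus)
    support: float | None       # bootstrap % of the decisive bipartition
    note: str = ""


def parse_leaf_labels(names, sep: str = "_") -> dict[str, tuple[str, str]]:
    """'Hsa_S11' -> ('Hsa', 'S11'); split on the last separator."""
    out = {}
    for nm in names:
        if sep not in nm:
            raise ValueError(f"cannot split {nm!r} into (species, locus)")
        sp, locus = nm.rsplit(sep, 1)
        out[nm] = (sp, locus)
    return out


def conversion_signature(tree_converted: PhyloTree,
                         tree_control: PhyloTree | None,
                         labels: dict[str, tuple[str, str]]) -> list[ConversionCall]:
    """Call per-species gene conversion from tree incongruence.

    A species is called converted when its two paralogs form an unrooted
    clade in the candidate-region tree while NOT doing so in the control
    (paralogous-pattern) tree.  Species with a single locus are
    not-applicable.
    """
    by_species: dict[str, list[str]] = {}
    for leaf, (sp, _locus) in labels.items():
        by_species.setdefault(sp, []).append(leaf)
    calls = []
    for sp in sorted(by_species):
        leaves = by_species[sp]
        if len(leaves) != 2:
            calls.append(ConversionCall(sp, None, None, "single locus"))
            continue
        in_a, supp = tree_converted.has_clade(leaves)
        note = ""
        converted = in_a
        if tree_control is not None:
            in_b, _ = tree_control.has_clade(leaves)
            if in_a and in_b:
                note = "paralogs cluster in control tree too"
            converted = in_a and not in_b
        calls.append(ConversionCall(sp, converted, supp, note))
    return calls


def write_phylip(D: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(D.taxa)}\n")
        for i, t in enumerate(D.taxa):
            row = " ".join(f"{x:.8f}" for x in D.d[i])
            fh.write(f"{t:<12s}{row}\n")
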