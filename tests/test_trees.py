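"""Distances, neighbor joining, bootstrap and conversion-signature calls."""

import numpy as np
import pytest
import sympy

from oracles import dendropy_nj_bipartitions, naive_nj_bipartitions
from paraconv.seq_io import Alignment
from paraconv.trees import (DistanceMatrix, PhyloTree, SaturatedDistanceError,
                            bootstrap_support, conversion_signature, nj_tree,
                            pairwise_distance, parse_leaf_labels)


def dm(taxa, d):
    d = np.asarray(d, dtype=float)
    return DistanceMatrix(list(taxa), d, np.zeros_like(d), "JC69",
                          np.full_like(d, 100.0))


class TestPairwiseDistance:
    def test_identical_pair_is_zero(self):
        aln = Alignment(["a", "b"], ["ACGTACGTAC", "ACGTACGTAC"])
        D = pairwise_distance(aln, "JC69")
        assert D.pair("a", "b") == 0.0
        assert D.pair_var("a", "b") == 0.0

    def test_jc_correction_matches_high_precision_closed_form(self):
        # p = 0.1 over 100 sites
        aln = Alignment(["a", "b"], ["A" * 100, "C" * 10 + "A" * 90])
        D = pairwise_distance(aln, "JC69")
        p = sympy.Rational(1, 10)
        exact = -sympy.Rational(3, 4) * sympy.log(1 - 4 * p / 3)
        assert D.pair("a", "b") == pytest.approx(float(exact.evalf(30)), abs=1e-12)
        assert D.pair("a", "b") == pytest.approx(0.10732, abs=1e-5)
        var_exact = (p * (1 - p)) / (100 * (1 - 4 * p / 3) ** 2)
        assert D.pair_var("a", "b") == pytest.approx(float(var_exact.evalf(30)),
                                                     rel=1e-12)

    def test_saturated_distance_rejected(self):
        aln = Alignment(["a", "b"], ["A" * 100, "C" * 75 + "A" * 25])
        with pytest.raises(SaturatedDistanceError):
            pairwise_distance(aln, "JC69")

    def test_k2p_reduces_to_jc_rate_when_ts_tv_balanced(self):
        # 2 transitions + 4 transversions among 60 sites: K2P and JC differ
        # but both must be >= p-distance
        s1 = "A" * 60
        s2 = "G" * 2 + "C" * 4 + "A" * 54
        aln = Alignment(["a", "b"], [s1, s2])
        p = pairwise_distance(aln, "p").pair("a", "b")
        jc = pairwise_distance(aln, "JC69").pair("a", "b")
        k2p = pairwise_distance(aln, "K2P").pair("a", "b")
        assert p == pytest.approx(0.1)
        assert jc >= p and k2p >= p

    def test_pairwise_deletion(self):
        aln = Alignment(["a", "b"], ["ACGT-CGT", "ACGTAC-T"])
        D = pairwise_distance(aln, "p")
        assert D.sites_compared[0, 1] == 6


class TestNJ:
    def test_three_taxon_pendant_lengths(self):
        D = dm("ABC", [[0, 0.2, 0.3], [0.2, 0, 0.4], [0.3, 0.4, 0]])
        tree = nj_tree(D)
        lengths = {nd.name: nd.length for nd in tree.nodes() if nd.is_leaf()}
        assert lengths == pytest.approx({"A": 0.05, "B": 0.15, "C": 0.25})

    def test_fewer_than_three_taxa_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            nj_tree(dm("AB", [[0, 0.1], [0.1, 0]]))

    def test_additive_six_taxon_exact_recovery(self):
        # caterpillar tree with known branch lengths
        newick = "(((a:0.1,b:0.2):0.05,(c:0.3,d:0.15):0.1):0.2,e:0.4,f:0.5);"
        truth = PhyloTree.from_newick(newick)
        from paraconv.constraint import edge_incidence
        from paraconv.trees import canonical_side
        taxa = sorted(truth.leaves)
        ids, X = edge_incidence(truth, taxa)
        lengths = {}
        for nd in truth.nodes():
            if nd.parent is None:
                continue
            key = "+".join(canonical_side(nd.leaf_names(), taxa))
            lengths[key] = lengths.get(key, 0.0) + nd.length
        b = np.array([lengths[i] for i in ids])
        d_flat = X @ b
        n = len(taxa)
        d = np.zeros((n, n))
        k = 0
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = d_flat[k]
                k += 1
        est = nj_tree(dm(taxa, d))
        assert set(est.bipartitions()) == set(truth.bipartitions())
        # path-length matrix reproduces the input exactly
        est_ids, est_X = edge_incidence(est, taxa)
        est_lengths = {}
        for nd in est.nodes():
            if nd.parent is None:
                continue
            key = "+".join(canonical_side(nd.leaf_names(), taxa))
            est_lengths[key] = est_lengths.get(key, 0.0) + nd.length
        est_b = np.array([est_lengths[i] for i in est_ids])
        assert np.allclose(est_X @ est_b, d_flat, atol=1e-12)

    def test_matches_dendropy_on_random_matrix(self):
        rng = np.random.default_rng(17)
        n = 7
        taxa = [f"t{i}" for i in range(n)]
        pts = rng.uniform(0, 1, (n, 4))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        mine = nj_tree(dm(taxa, d))
        assert set(mine.bipartitions()) == dendropy_nj_bipartitions(taxa, d)

    def test_invariant_under_taxon_reordering(self):
        rng = np.random.default_rng(3)
        n = 6
        taxa = [f"t{i}" for i in range(n)]
        pts = rng.uniform(0, 1, (n, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        t1 = nj_tree(dm(taxa, d))
        perm = rng.permutation(n)
        t2 = nj_tree(dm([taxa[i] for i in perm], d[np.ix_(perm, perm)]))
        assert set(t1.bipartitions()) == set(t2.bipartitions())
        l1 = {nd.name: nd.length for nd in t1.nodes() if nd.is_leaf()}
        l2 = {nd.name: nd.length for nd in t2.nodes() if nd.is_leaf()}
        assert l1 == pytest.approx(l2)


class TestNewick:
    def test_roundtrip_preserves_topology_lengths_supports(self):
        rng = np.random.default_rng(21)
        n = 6
        taxa = [f"t{i}" for i in range(n)]
        pts = rng.uniform(0, 1, (n, 3))
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        tree = nj_tree(dm(taxa, d))
        for side, nd in tree.bipartitions().items():
            nd.support = float(len(side) * 10)
        back = PhyloTree.from_newick(tree.newick())
        assert set(back.bipartitions()) == set(tree.bipartitions())
        for side, nd in tree.bipartitions().items():
            assert back.bipartitions()[side].support == nd.support
            assert back.bipartitions()[side].length == pytest.approx(nd.length,
                                                                     abs=1e-9)


class TestBootstrap:
    def test_uniform_signal_gives_full_support(self):
        # every column supports ((a,b),(c,d)) against the rest
        col_ab = "AACC"
        aln = Alignment(list("abcd"), ["".join(col_ab[i] for _ in range(40))
                                       for i in range(4)])
        # add a few neutral identical columns to avoid zero distances
        rng = np.random.default_rng(0)
        extra = rng.choice(list("ACGT"), 20)
        rows = [aln.rows[i] + "".join(extra) for i in range(4)]
        aln = Alignment(list("abcd"), rows)
        tree = bootstrap_support(aln, "p", n_reps=100, seed=1)
        (side,) = tree.bipartitions().keys()
        assert tree.bipartitions()[side].support == 100.0

    def test_supports_match_independent_reimplementation(self):
        """Same seed + resampling scheme, but naive distances and dendropy NJ."""
        rng = np.random.default_rng(42)
        n, L = 5, 50
        taxa = [f"t{i}" for i in range(n)]
        base = rng.choice(list("ACGT"), L)
        rows = []
        for i in range(n):
            row = base.copy()
            mut = rng.random(L) < 0.12 * (i + 1) / n
            row[mut] = [rng.choice(list("ACGT")) for _ in range(mut.sum())]
            rows.append("".join(row))
        aln = Alignment(taxa, rows)
        n_reps, seed = 60, 9
        mine = bootstrap_support(aln, "JC69", n_reps=n_reps, seed=seed)

        # oracle: replicate the resampling stream, naive everything else
        mat = np.array([list(r) for r in rows])
        rng2 = np.random.default_rng(seed)
        from collections import Counter
        counts = Counter()
        ok = 0
        for _ in range(n_reps):
            w = rng2.multinomial(L, np.full(L, 1.0 / L)).astype(float)
            d = np.zeros((n, n))
            sat = False
            for i in range(n):
                for j in range(i + 1, n):
                    diff = float(((mat[i] != mat[j]) * w).sum())
                    p = diff / L
                    if p >= 0.75:
                        sat = True
                        break
                    d[i, j] = d[j, i] = -0.75 * np.log(1 - 4 * p / 3)
                if sat:
                    break
            if sat:
                continue
            ok += 1
            counts.update(naive_nj_bipartitions(taxa, d))
        for side, nd in mine.bipartitions().items():
            assert nd.support == pytest.approx(100.0 * counts[side] / ok)

    def test_default_replications_is_1000(self):
        import inspect
        sig = inspect.signature(bootstrap_support)
        assert sig.parameters["n_reps"].default == 1000


class TestConversionSignature:
    def test_within_species_clusters_call_converted(self):
        tree_a = PhyloTree.from_newick(
            "((H_11:1,H_16:1):1,(C_11:1,C_16:1):1,(G_11:1,G_16:2):1);")
        tree_b = PhyloTree.from_newick(
            "((H_11:1,C_11:1):1,G_11:4,((H_16:1,C_16:1):1,G_16:1):1);")
        labels = parse_leaf_labels(
            ["H_11", "H_16", "C_11", "C_16", "G_11", "G_16"])
        calls = conversion_signature(tree_a, tree_b, labels)
        assert all(c.converted for c in calls)

    def test_paralogous_pattern_calls_unconverted(self):
        tree = PhyloTree.from_newick(
            "((H_11:1,C_11:1):1,G_11:4,((H_16:1,C_16:1):1,G_16:1):1);")
        labels = parse_leaf_labels(
            ["H_11", "H_16", "C_11", "C_16", "G_11", "G_16"])
        calls = conversion_signature(tree, None, labels)
        assert not any(c.converted for c in calls)

    def test_single_locus_species_not_applicable(self):
        tree = PhyloTree.from_newick("((H_11:1,H_16:1):1,C_11:1,M_11:1);")
        labels = parse_leaf_labels(["H_11", "H_16", "C_11", "M_11"])
        calls = conversion_signature(tree, None, labels)
        by_sp = {c.species: c for c in calls}
        assert by_sp["M"].converted is None
        assert by_sp["H"].converted is True

    def test_recovers_simulated_conversion(self, simulated_six_taxon):
        cfg, aln, truth = simulated_six_taxon
        (tract,) = [tuple(e["tract"]) for e in truth.events]
        tree_a = nj_tree(pairwise_distance(aln.take_columns(range(*tract))))
        outside = [c for c in range(aln.length) if not tract[0] <= c < tract[1]]
        tree_b = nj_tree(pairwise_distance(aln.take_columns(outside)))
        calls = conversion_signature(tree_a, tree_b, parse_leaf_labels(aln.names))
        by_sp = {c.species: c.converted for c in calls}
        assert by_sp == {"A": False, "B": True, "C": False}
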