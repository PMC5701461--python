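"""OLS branch lengths on a fixed topology and per-branch constraint Z-tests."""

import numpy as np
import pytest

from oracles import networkx_incidence
from paraconv.constraint import (branch_constraint_test, edge_incidence,
                                 ols_branch_lengths)
from paraconv.experiments import enumerate_unrooted_topologies, random_topology
from paraconv.simulate import SimConfig, simulate_history
from paraconv.trees import DistanceMatrix, PhyloTree


def dm(taxa, d, var=None):
    d = np.asarray(d, dtype=float)
    if var is None:
        var = np.zeros_like(d)
    return DistanceMatrix(list(taxa), d, var, "JC69", np.full_like(d, 100.0))


def square_from_flat(taxa, flat):
    n = len(taxa)
    d = np.zeros((n, n))
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = flat[k]
            k += 1
    return d


class TestOLS:
    def test_additive_four_taxon_exact(self):
        topo = PhyloTree.from_newick("((a:0.1,b:0.2):0.05,c:0.3,d:0.4);")
        taxa = sorted(topo.leaves)
        ids, X = edge_incidence(topo, taxa)
        b_true = np.array([0.1, 0.2, 0.05, 0.3, 0.4])
        # map by edge id for robustness
        truth = {"a": 0.1, "b": 0.2, "a+b": 0.05, "c": 0.3, "d": 0.4}
        b_true = np.array([truth[i] for i in ids])
        d = square_from_flat(taxa, X @ b_true)
        b_hat, rss = ols_branch_lengths(dm(taxa, d), topo)
        assert rss == pytest.approx(0.0, abs=1e-20)
        for eid, val in truth.items():
            assert b_hat[eid] == pytest.approx(val, abs=1e-12)

    def test_star_symmetric_distances(self):
        topo = PhyloTree.from_newick("((a:1,b:1):1,c:1,d:1);")
        taxa = sorted(topo.leaves)
        d = np.full((4, 4), 0.5)
        np.fill_diagonal(d, 0.0)
        b_hat, _ = ols_branch_lengths(dm(taxa, d), topo)
        pendants = [b_hat[t] for t in taxa]
        assert np.allclose(pendants, pendants[0])
        assert b_hat["a+b"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_pseudoinverse_oracle_on_perturbed_instances(self):
        rng = np.random.default_rng(14)
        for _ in range(30):
            n = int(rng.integers(4, 9))
            topo = random_topology(n, rng)
            taxa = sorted(topo.leaves)
            ids, X = edge_incidence(topo, taxa)
            b_true = rng.uniform(0.05, 0.5, len(ids))
            noisy = X @ b_true + rng.normal(0, 0.01, X.shape[0])
            b_hat, _ = ols_branch_lengths(dm(taxa, square_from_flat(taxa, noisy)),
                                          topo)
            # oracle: incidence built via shortest paths in a graph
            _, Xo = networkx_incidence(topo.root, taxa)
            b_oracle = np.linalg.pinv(Xo) @ noisy
            assert np.allclose(sorted(b_hat.to_numpy()), sorted(b_oracle),
                               atol=1e-10)

    def test_additive_exact_for_all_five_taxon_topologies(self):
        rng = np.random.default_rng(8)
        for topo in enumerate_unrooted_topologies(["a", "b", "c", "d", "e"]):
            taxa = sorted(topo.leaves)
            ids, X = edge_incidence(topo, taxa)
            b_true = rng.uniform(0.05, 1.0, len(ids))
            d = square_from_flat(taxa, X @ b_true)
            b_hat, rss = ols_branch_lengths(dm(taxa, d), topo)
            assert rss == pytest.approx(0.0, abs=1e-18)
            assert np.allclose(b_hat.to_numpy(), b_true, atol=1e-10)

    def test_leaf_set_mismatch_rejected(self):
        topo = PhyloTree.from_newick("((a:1,b:1):1,c:1,d:1);")
        with pytest.raises(ValueError, match="leaf set"):
            ols_branch_lengths(dm(["a", "b", "c", "x"], np.zeros((4, 4))), topo)

    def test_too_few_taxa_rejected(self):
        topo = PhyloTree.from_newick("(a:1,b:1);")
        with pytest.raises(ValueError, match=">= 3"):
            ols_branch_lengths(dm(["a", "b"], np.zeros((2, 2))), topo)


@pytest.fixture(scope="module")
def sim_setup():
    cfg = SimConfig(
        species_tree="((A:7000000,B:7000000):8000000,C:15000000);",
        site_layout=[("coding", 999), ("noncoding", 600)],
        seed=5,
    )
    aln, _ = simulate_history(cfg)
    classes = cfg.site_classes()
    part = {
        "nonsynonymous": np.flatnonzero(classes == 2).tolist(),
        "synonymous": np.flatnonzero(classes == 1).tolist(),
        "intronic": np.flatnonzero(classes == 0).tolist(),
    }
    from paraconv.experiments import paralog_topology
    topo = paralog_topology(cfg.species_tree)
    return aln, part, topo


class TestBranchConstraintTest:
    def test_table_shape_and_columns(self, sim_setup):
        aln, part, topo = sim_setup
        table = branch_constraint_test(aln, part, topo, n_boot=100, seed=0)
        # unrooted binary tree over n leaves has 2n - 3 edges
        assert len(table) == 2 * aln.n_sequences - 3
        assert {"b_nonsyn", "b_syn", "b_intron", "b_neutral", "ratio",
                "se_diff", "Z", "p"} <= set(table.columns)
        ok = table["p"].dropna()
        assert ((ok > 0) & (ok <= 1)).all()

    def test_neutral_mean_invariant_under_partition_swap(self, sim_setup):
        aln, part, topo = sim_setup
        swapped = dict(part)
        swapped["synonymous"], swapped["intronic"] = \
            part["intronic"], part["synonymous"]
        t1 = branch_constraint_test(aln, part, topo, n_boot=100, seed=0)
        t2 = branch_constraint_test(aln, swapped, topo, n_boot=100, seed=0)
        assert np.allclose(t1["b_neutral"], t2["b_neutral"])

    def test_diff_statistic_antisymmetric_under_role_exchange(self, sim_setup):
        aln, part, topo = sim_setup
        exchanged = {
            "nonsynonymous": part["synonymous"],
            "synonymous": part["nonsynonymous"],
            "intronic": part["nonsynonymous"],
        }
        t1 = branch_constraint_test(aln, part, topo, n_boot=100, seed=0)
        # b_neutral of the exchanged table equals b_nonsyn of the original
        t2 = branch_constraint_test(aln, exchanged, topo, n_boot=100, seed=0)
        # when syn == intron == original nonsyn, diff = b_syn_orig - b_nonsyn_orig
        one_sided = t2["b_nonsyn"] - t2["b_neutral"]
        expected = t1["b_syn"] - t1["b_nonsyn"]
        assert np.allclose(one_sided, expected, atol=1e-12)

    def test_empty_partition_named_in_error(self, sim_setup):
        aln, part, topo = sim_setup
        bad = dict(part)
        bad["synonymous"] = []
        with pytest.raises(ValueError, match="synonymous"):
            branch_constraint_test(aln, bad, topo, n_boot=100, seed=0)

    def test_low_bootstrap_count_rejected(self, sim_setup):
        aln, part, topo = sim_setup
        with pytest.raises(ValueError, match="n_boot"):
            branch_constraint_test(aln, part, topo, n_boot=10, seed=0)
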