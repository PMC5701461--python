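"""Seeded simulation studies exercising the full inference chain.

Each function runs one self-contained study on the bundled paralog
simulator — dating round-trips, conversion-call recovery, test
calibrations — and returns a small dict of summary numbers.  They are
shared by the test suite, the acceptance script and the analysis drivers,
so every reported number is recomputed from scratch at run time.

Study sizes (replicate counts, sequence lengths) follow the stated
defaults of the corresponding analyses: 2-kb conversion tracts, ~800-bp
noncoding timing regions, 2-kb coding + 1-kb intron constraint regions,
a neutral rate of 1.4e-9/site/year on a five-species catarrhine tree.
"""

from __future__ import annotations

import numpy as np

import dendropy

from . import constraint as cst
from . import identity as ident
from . import timing as tim
from .seq_io import RegionMap, extract_region
from .simulate import MYR, DEFAULT_SPECIES_TREE, ConversionEvent, SimConfig, simulate_history
from .trees import (DistanceMatrix, PhyloTree, TreeNode, canonical_side,
                    conversion_signature, nj_tree, pairwise_distance,
                    parse_leaf_labels)


def _spawn(seed: int, n: int) -> list[int]:
    """n child seeds below 2**31, deterministic in `seed`."""
    return [int(s) for s in
            np.random.default_rng(seed).integers(0, 2 ** 31 - 1, size=n)]


def paralog_topology(species_newick: str = DEFAULT_SPECIES_TREE,
                     loci: tuple[str, str] = ("S11", "S16")) -> PhyloTree:
    """Expected no-conversion topology: two relabeled copies of the species
    tree joined at the duplication."""
    subtrees = []
    for locus in loci:
        t = dendropy.Tree.get(data=species_newick, schema="newick")
        for leaf in t.leaf_node_iter():
            leaf.taxon.label = f"{leaf.taxon.label}_{locus}"
        subtrees.append(t.as_string(schema="newick").strip().rstrip(";").lstrip("[&U] "))
    return PhyloTree.from_newick(f"({subtrees[0]},{subtrees[1]});")


# ---------------------------------------------------------------------------
# timing round trip
# ---------------------------------------------------------------------------

def timing_roundtrip(n_reps: int = 200, seed: int = 1, t_c: float = 4.4 * MYR,
                     tract: tuple[int, int] = (500, 2500),
                     length: int = 3000) -> dict:
    """Simulate a dated conversion and re-estimate its time as T = d/(2 lambda).

    One conversion at t_c on a terminal lineage, 2-kb tract; the estimator
    uses the JC distance between the two paralogs inside the tract.
    """
    tree = "(Hsa:6500000,Ptr:6500000);"
    estimates = []
    for s in _spawn(seed, n_reps):
        cfg = SimConfig(
            species_tree=tree, duplication_time=40 * MYR,
            site_layout=[("noncoding", length)],
            conversion_events=[ConversionEvent("Ptr", t_c, "S16", "S11", tract)],
            seed=s,
        )
        aln, _ = simulate_history(cfg)
        pair = aln.subset(["Ptr_S11", "Ptr_S16"]).take_columns(range(*tract))
        D = pairwise_distance(pair, "JC69")
        est = tim.estimate_timing(D.pair("Ptr_S11", "Ptr_S16"),
                                  D.pair_var("Ptr_S11", "Ptr_S16"),
                                  cfg.lambda_neutral, se_lam=0.0)
        estimates.append(est.T_myr)
    estimates = np.asarray(estimates)
    mc_se = estimates.std(ddof=1) / np.sqrt(n_reps)
    return {
        "mean_T_myr": float(estimates.mean()),
        "mc_se_myr": float(mc_se),
        "true_T_myr": t_c / MYR,
        "abs_bias_in_se": float(abs(estimates.mean() - t_c / MYR) / mc_se),
        "n": n_reps,
    }


# ---------------------------------------------------------------------------
# conversion-signature recovery
# ---------------------------------------------------------------------------

def conversion_recovery(n_reps: int = 100, seed: int = 2) -> dict:
    """Per-lineage conversion calls vs simulator truth.

    Five species, conversions on three terminal lineages (duplication/
    conversion age ratio >= 5); calls come from NJ trees of the converted
    tract vs the unconverted flank.
    """
    tract = (0, 2000)
    events = [
        ConversionEvent("Ptr", 3.0 * MYR, "S16", "S11", tract),
        ConversionEvent("Ggo", 5.0 * MYR, "S11", "S16", tract),
        ConversionEvent("Pan", 8.0 * MYR, "S16", "S11", tract),
    ]
    truth_converted = {"Ptr", "Ggo", "Pan"}
    regions = RegionMap([("Ac", 0, 2000), ("Bc", 2000, 3000)])
    n_calls = n_correct = 0
    for s in _spawn(seed, n_reps):
        cfg = SimConfig(site_layout=[("noncoding", 3000)],
                        conversion_events=events, seed=s)
        aln, truth = simulate_history(cfg)
        tree_a = nj_tree(pairwise_distance(extract_region(aln, regions, "Ac")))
        tree_b = nj_tree(pairwise_distance(extract_region(aln, regions, "Bc")))
        calls = conversion_signature(tree_a, tree_b, parse_leaf_labels(aln.names))
        for call in calls:
            n_calls += 1
            if call.converted == (call.species in truth_converted):
                n_correct += 1
        assert set(truth.converted_species) == truth_converted
    return {
        "call_accuracy_pct": 100.0 * n_correct / n_calls,
        "n": n_reps,
        "n_calls": n_calls,
    }


# ---------------------------------------------------------------------------
# NJ exactness on additive matrices
# ---------------------------------------------------------------------------

def _attach(parent: TreeNode, child: TreeNode) -> None:
    child.parent = parent
    parent.children.append(child)


def _copy_tree(node: TreeNode) -> TreeNode:
    new = TreeNode(name=node.name, length=node.length)
    for ch in node.children:
        _attach(new, _copy_tree(ch))
    return new


def enumerate_unrooted_topologies(labels: list[str]) -> list[PhyloTree]:
    """All unrooted binary topologies over `labels` by sequential leaf insertion
    (3, 15, 105... trees for 5, 6, 7... taxa)."""
    if len(labels) < 3:
        raise ValueError("need >= 3 labels")
    base = TreeNode()
    for lbl in labels[:3]:
        _attach(base, TreeNode(name=lbl))
    trees = [base]
    for lbl in labels[3:]:
        nxt = []
        for t in trees:
            edges = [nd for nd in PhyloTree(t).nodes() if nd.parent is not None]
            for k in range(len(edges)):
                c = _copy_tree(t)
                c_edges = [nd for nd in PhyloTree(c).nodes() if nd.parent is not None]
                target = c_edges[k]
                parent = target.parent
                mid = TreeNode()
                parent.children[parent.children.index(target)] = mid
                mid.parent = parent
                _attach(mid, target)
                _attach(mid, TreeNode(name=lbl))
                nxt.append(c)
        trees = nxt
    return [PhyloTree(t) for t in trees]


def additive_matrix(tree: PhyloTree, lengths: np.ndarray | None = None,
                    rng: np.random.Generator | None = None) -> DistanceMatrix:
    """Exact path-sum distances for a topology with given/random edge lengths."""
    taxa = sorted(tree.leaves)
    ids, X = cst.edge_incidence(tree, taxa)
    if lengths is None:
        lengths = rng.uniform(0.05, 1.0, size=len(ids))
    d_flat = X @ lengths
    n = len(taxa)
    d = np.zeros((n, n))
    for k, (i, j) in enumerate((i, j) for i in range(n) for j in range(i + 1, n)):
        d[i, j] = d[j, i] = d_flat[k]
    return DistanceMatrix(taxa, d, np.zeros_like(d), "additive", np.full((n, n), 1.0))


def _path_matrix(tree: PhyloTree, taxa: list[str]) -> np.ndarray:
    ids, X = cst.edge_incidence(tree, taxa)
    by_id: dict[str, float] = {}
    for nd in tree.nodes():
        if nd.parent is None:
            continue
        key = "+".join(canonical_side(nd.leaf_names(), taxa))
        by_id[key] = by_id.get(key, 0.0) + nd.length
    lengths = np.array([by_id[i] for i in ids])
    d_flat = X @ lengths
    n = len(taxa)
    d = np.zeros((n, n))
    for k, (i, j) in enumerate((i, j) for i in range(n) for j in range(i + 1, n)):
        d[i, j] = d[j, i] = d_flat[k]
    return d


def nj_additivity_check(seed: int = 3) -> dict:
    """NJ must return the generating tree, exactly, for every 5-taxon topology."""
    labels = ["t1", "t2", "t3", "t4", "t5"]
    rng = np.random.default_rng(seed)
    recovered = 0
    max_dev = 0.0
    topologies = enumerate_unrooted_topologies(labels)
    for topo in topologies:
        D = additive_matrix(topo, rng=rng)
        est = nj_tree(D)
        same = set(est.bipartitions().keys()) == set(
            PhyloTree(topo.root).bipartitions().keys())
        if same:
            recovered += 1
        dev = float(np.abs(_path_matrix(est, D.taxa) - D.d).max())
        max_dev = max(max_dev, dev)
    return {
        "n_topologies": len(topologies),
        "n_recovered": recovered,
        "max_path_length_dev": max_dev,
    }


# ---------------------------------------------------------------------------
# OLS oracle deviation
# ---------------------------------------------------------------------------

def random_topology(n_taxa: int, rng: np.random.Generator) -> PhyloTree:
    labels = [f"t{i + 1}" for i in range(n_taxa)]
    base = TreeNode()
    for lbl in labels[:3]:
        _attach(base, TreeNode(name=lbl))
    for lbl in labels[3:]:
        edges = [nd for nd in PhyloTree(base).nodes() if nd.parent is not None]
        target = edges[rng.integers(0, len(edges))]
        parent = target.parent
        mid = TreeNode()
        parent.children[parent.children.index(target)] = mid
        mid.parent = parent
        _attach(mid, target)
        _attach(mid, TreeNode(name=lbl))
    return PhyloTree(base)


def ols_oracle_check(n_instances: int = 100, seed: int = 4) -> dict:
    """OLS branch lengths vs a pseudoinverse solve; exactness on additive input."""
    rng = np.random.default_rng(seed)
    max_dev = 0.0
    max_resid_additive = 0.0
    for _ in range(n_instances):
        n_taxa = int(rng.integers(4, 9))
        topo = random_topology(n_taxa, rng)
        ids, X = cst.edge_incidence(topo, sorted(topo.leaves))
        b_true = rng.uniform(0.05, 1.0, size=len(ids))
        d_add = X @ b_true
        d_noisy = d_add + rng.normal(0, 0.02, size=d_add.size)
        n = n_taxa
        for d_flat, is_additive in ((d_add, True), (d_noisy, False)):
            dm = np.zeros((n, n))
            for k, (i, j) in enumerate(
                    (i, j) for i in range(n) for j in range(i + 1, n)):
                dm[i, j] = dm[j, i] = d_flat[k]
            D = DistanceMatrix(sorted(topo.leaves), dm, np.zeros_like(dm),
                               "additive", np.full((n, n), 1.0))
            b_hat, rss = cst.ols_branch_lengths(D, topo)
            b_oracle = np.linalg.pinv(X) @ d_flat
            max_dev = max(max_dev, float(np.abs(b_hat.to_numpy() - b_oracle).max()))
            if is_additive:
                max_resid_additive = max(max_resid_additive, rss)
    return {
        "n_instances": n_instances,
        "max_abs_dev_vs_pinv": max_dev,
        "max_rss_on_additive": max_resid_additive,
    }


# ---------------------------------------------------------------------------
# RRT calibration
# ---------------------------------------------------------------------------

def rrt_calibration(n_reps: int = 2000, seed: int = 5, length: int = 800,
                    alpha: float = 0.05) -> dict:
    """Type-I error of the relative-rate test under a strict clock."""
    tree = "((A:10000000,B:10000000):10000000,O:20000000);"
    rejections = informative = 0
    for s in _spawn(seed, n_reps):
        cfg = SimConfig(species_tree=tree, duplication_time=20 * MYR,
                        site_layout=[("noncoding", length)], seed=s)
        aln, _ = simulate_history(cfg)
        triple = aln.subset(["A_S11", "B_S11", "O_S11"])
        res = tim.tajima_rrt(triple, outgroup="O_S11")
        if res.informative:
            informative += 1
            if res.p < alpha:
                rejections += 1
    return {
        "type1_rate": rejections / informative,
        "n": n_reps,
        "n_informative": informative,
        "alpha": alpha,
    }


# ---------------------------------------------------------------------------
# constraint calibration and power
# ---------------------------------------------------------------------------

def _pendant_edge_id(topology: PhyloTree, leaf: str) -> str:
    return "+".join(canonical_side([leaf], topology.leaves))


def constraint_calibration(n_null: int = 500, n_power: int = 100,
                           n_boot: int = 200, seed: int = 6,
                           omega_relaxed: float = 3.0,
                           alpha: float = 0.02) -> dict:
    """Null rejection rate and power of the per-branch constraint Z-test.

    Null: all site classes evolve at the neutral rate (omega = 1). Power:
    omega = 3 on the branch leading to one locus of one species; sequences
    are 2-kb coding + 1-kb intron.
    """
    layout = [("coding", 1998), ("noncoding", 999)]
    topo = paralog_topology()
    relaxed_leaf = "Ggo_S11"
    relaxed_edge = _pendant_edge_id(topo, relaxed_leaf)

    def run(n_reps, omega_map, seed_):
        total_tests = total_rej = 0
        relaxed_hits = 0
        for s in _spawn(seed_, n_reps):
            cfg = SimConfig(site_layout=layout, omega_per_branch=omega_map, seed=s)
            aln, _ = simulate_history(cfg)
            part = {
                "nonsynonymous": np.flatnonzero(cfg.site_classes() == 2).tolist(),
                "synonymous": np.flatnonzero(cfg.site_classes() == 1).tolist(),
                "intronic": np.flatnonzero(cfg.site_classes() == 0).tolist(),
            }
            table = cst.branch_constraint_test(aln, part, topo,
                                               n_boot=max(n_boot, 100), seed=s)
            sig = table["p"] < alpha
            for edge, flag in sig.items():
                if omega_map and edge == relaxed_edge:
                    relaxed_hits += int(bool(flag))
                    continue
                total_tests += 1
                total_rej += int(bool(flag))
        return total_rej, total_tests, relaxed_hits

    null_rej, null_tests, _ = run(n_null, {}, seed)
    omega_map = {("Ggo", "S11"): omega_relaxed}
    other_rej, other_tests, hits = run(n_power, omega_map, seed + 1)
    return {
        "null_rejection_rate": null_rej / null_tests,
        "n_null": n_null,
        "power_pct": 100.0 * hits / n_power,
        "other_branch_rate": other_rej / other_tests,
        "n_power": n_power,
        "alpha": alpha,
    }


# ---------------------------------------------------------------------------
# identity-scan tract recovery
# ---------------------------------------------------------------------------

def identity_tract_recovery(n_reps: int = 50, seed: int = 7,
                            threshold: float = 0.97, min_len: int = 500) -> dict:
    """Planted 2-kb high-identity tract; Jaccard overlap of the recovered
    segmentation with the truth."""
    tract = (1000, 3000)
    jaccards = []
    for s in _spawn(seed, n_reps):
        cfg = SimConfig(
            species_tree="(Hsa:6500000,Ptr:6500000);",
            site_layout=[("noncoding", 4000)],
            conversion_events=[ConversionEvent("Hsa", 1.0 * MYR, "S16", "S11", tract)],
            seed=s,
        )
        aln, _ = simulate_history(cfg)
        pair = aln.subset(["Hsa_S11", "Hsa_S16"])
        track = ident.sliding_identity(pair, window=20, step=1)
        regions = ident.segment_regions(track, threshold=threshold, min_len=min_len)
        detected = np.zeros(cfg.length, dtype=bool)
        for _lbl, s0, e0 in regions.intervals:
            detected[s0:e0] = True
        true = np.zeros(cfg.length, dtype=bool)
        true[tract[0]:tract[1]] = True
        union = (detected | true).sum()
        jaccards.append((detected & true).sum() / union if union else 0.0)
    return {
        "median_jaccard": float(np.median(jaccards)),
        "n": n_reps,
    }


# ---------------------------------------------------------------------------
# flagship end-to-end scenario
# ---------------------------------------------------------------------------

def flagship_config(seed: int = 0) -> tuple[SimConfig, RegionMap]:
    """Five-species scenario with a conversion in every lineage.

    Tract = 2-kb candidate region (800-bp noncoding + first part of the
    coding block); conversion times echo a plausible catarrhine history
    (most recent conversion youngest in the human lineage).
    """
    tract = (0, 2000)
    events = [
        ConversionEvent("Hsa", 1.0 * MYR, "S16", "S11", tract),
        ConversionEvent("Ptr", 4.4 * MYR, "S16", "S11", tract),
        ConversionEvent("Ggo", 6.9 * MYR, "S11", "S16", tract),
        ConversionEvent("Hla", 8.4 * MYR, "S16", "S11", tract),
        ConversionEvent("Pan", 12.0 * MYR, "S11", "S16", tract),
    ]
    cfg = SimConfig(site_layout=[("noncoding", 800), ("coding", 1998),
                                 ("noncoding", 202)],
                    conversion_events=events, seed=seed)
    regions = RegionMap([
        ("Ac", 0, 2000), ("Bc", 2000, 3000),
        ("Ac_noncoding", 0, 800),
        ("exon", 800, 2798),
    ])
    return cfg, regions


def flagship_scenario(seed: int = 8) -> dict:
    """One full simulate -> scan -> trees -> date round trip; summary numbers."""
    cfg, regions = flagship_config(seed)
    aln, truth = simulate_history(cfg)
    labels = parse_leaf_labels(aln.names)

    pair = aln.subset(["Hsa_S11", "Hsa_S16"])
    ac_identity = ident.mean_identity(pair, regions, "Ac")
    bc_identity = ident.mean_identity(pair, regions, "Bc")

    tree_a = nj_tree(pairwise_distance(extract_region(aln, regions, "Ac")))
    tree_b = nj_tree(pairwise_distance(extract_region(aln, regions, "Bc")))
    calls = conversion_signature(tree_a, tree_b, labels)
    n_converted = sum(1 for c in calls if c.converted)

    noncod = extract_region(aln, regions, "Ac_noncoding")
    timings = {}
    for sp, ev_time in sorted(truth.expected_paralog_time.items()):
        D = pairwise_distance(noncod.subset([f"{sp}_S11", f"{sp}_S16"]))
        est = tim.estimate_timing(D.pair(f"{sp}_S11", f"{sp}_S16"),
                                  D.pair_var(f"{sp}_S11", f"{sp}_S16"))
        timings[sp] = (est.T_myr, ev_time / MYR)
    return {
        "hsa_ac_identity_pct": ac_identity,
        "hsa_bc_identity_pct": bc_identity,
        "n_species_called_converted": n_converted,
        "n_species_truth_converted": len(truth.converted_species),
        "timing_mae_myr": float(np.mean([abs(a - b) for a, b in timings.values()])),
    }
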