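"""End-to-end orchestration: simulate (or load) -> scan -> trees -> date -> constraint.

The pipeline config is a YAML mapping with exactly one of ``simulate`` (a
SimConfig description) or ``inputs`` (paths to a pre-aligned FASTA, a
BED-like region TSV, and optionally a reference topology and a glycan RFU
TSV).  Every stochastic stage derives its seed from the top-level seed, and
the machine-readable summary contains no timestamps, so a rerun with the
same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import glycan as gly
from . import identity as ident
from . import timing as tim
from .constraint import branch_constraint_test
from .seq_io import (RegionMap, classify_sites, extract_region,
                     read_alignment, read_regions, write_alignment, write_regions)
from .simulate import ConversionEvent, SimConfig, simulate_history
from .trees import (PhyloTree, bootstrap_support, conversion_signature,
                    nj_tree, pairwise_distance, parse_leaf_labels)

log = logging.getLogger("paraconv")

DEFAULT_PARAMS = {
    "model": "JC69",
    "window": 20,
    "step": 1,
    "threshold": 0.97,
    "min_len": 500,
    "n_boot": 1000,
    "lambda": 1.4e-9,
    "lambda_se": 0.1e-9,
    "converted_label": "Ac",
    "control_label": "Bc",
    "noncoding_label": None,   # timing region; falls back to converted_label
    "coding_label": None,      # enables the constraint stage
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    if ("simulate" in cfg) == ("inputs" in cfg):
        raise ValueError("config must contain exactly one of 'simulate' or 'inputs'")
    cfg.setdefault("seed", 0)
    params = dict(DEFAULT_PARAMS)
    params.update(cfg.get("params", {}))
    cfg["params"] = params


def sim_config_from_dict(d: dict, seed: int) -> SimConfig:
    events = [
        ConversionEvent(e["lineage"], float(e["time"]), e["donor"], e["acceptor"],
                        tuple(e["tract"]))
        for e in d.get("conversion_events", [])
    ]
    omega = {
        (k.split("/")[0], k.split("/")[1]): float(v)
        for k, v in d.get("omega_per_branch", {}).items()
    }
    kwargs = {}
    for key in ("species_tree", "duplication_time", "lambda_neutral", "loci"):
        if key in d:
            kwargs[key] = d[key] if key != "loci" else tuple(d[key])
    if "site_layout" in d:
        kwargs["site_layout"] = [(k, int(n)) for k, n in d["site_layout"]]
    return SimConfig(conversion_events=events, omega_per_branch=omega,
                     seed=seed, **kwargs)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def run_pipeline(cfg: dict, outdir) -> dict:
    """Run all applicable stages; returns (and writes) the summary dict."""
    validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = cfg["params"]
    seed = int(cfg["seed"])
    rng = np.random.default_rng(seed)
    stage_seeds = {name: int(s) for name, s in zip(
        ("simulate", "tree_a", "tree_b", "constraint"),
        rng.integers(0, 2 ** 31 - 1, size=4))}
    summary: dict = {
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(cfg),
        "stages": {},
    }
    t0 = time.perf_counter()

    # --- stage: obtain alignment + regions ---------------------------------
    if "simulate" in cfg:
        sim = sim_config_from_dict(cfg["simulate"], stage_seeds["simulate"])
        aln, truth = simulate_history(sim)
        write_alignment(aln, outdir / "alignment.fasta")
        truth.to_json(outdir / "truth.json")
        tracts = sorted({tuple(e["tract"]) for e in truth.events})
        intervals = [(params["converted_label"], s, e) for s, e in tracts]
        covered = np.zeros(sim.length, dtype=bool)
        for s, e in tracts:
            covered[s:e] = True
        # complement of the converted tract(s) = control region
        free = np.flatnonzero(~covered)
        if free.size:
            runs = np.split(free, np.flatnonzero(np.diff(free) > 1) + 1)
            intervals += [(params["control_label"], int(r[0]), int(r[-1]) + 1)
                          for r in runs]
        regions = RegionMap(intervals)
        write_regions(regions, outdir / "regions.tsv")
        summary["stages"]["simulate"] = {
            "n_sequences": aln.n_sequences, "length": aln.length,
            "n_events": len(truth.events),
            "total_substitutions": truth.total_substitutions(),
        }
    else:
        inputs = cfg["inputs"]
        aln = read_alignment(inputs["alignment"])
        regions = read_regions(inputs["regions"])
        regions.validate_against(aln)
        truth = None
        summary["stages"]["load"] = {
            "n_sequences": aln.n_sequences, "length": aln.length,
        }

    labels = parse_leaf_labels(aln.names)
    by_species: dict[str, list[str]] = {}
    for leaf, (sp, _) in labels.items():
        by_species.setdefault(sp, []).append(leaf)
    paired = {sp: lv for sp, lv in by_species.items() if len(lv) == 2}

    # --- stage: identity scan ---------------------------------------------
    scan_summary = {}
    for sp, (l1, l2) in sorted(paired.items()):
        pair = aln.subset([l1, l2])
        track = ident.sliding_identity(pair, params["window"], params["step"])
        with open(outdir / f"identity_{sp}.tsv", "w") as fh:
            fh.write("start\tend\tidentity\n")
            for s, v in zip(track.window_starts, track.values):
                fh.write(f"{int(s) + 1}\t{int(s) + track.window}\t{v:.4f}\n")
        segs = ident.segment_regions(track, params["threshold"], params["min_len"])
        write_regions(segs, outdir / f"segments_{sp}.tsv")
        scan_summary[sp] = {
            "n_segments": len(segs.intervals),
            "identity_pct": {
                lbl: round(ident.mean_identity(pair, regions, lbl), 1)
                for lbl in (params["converted_label"], params["control_label"])
                if lbl in regions.labels
            },
        }
    summary["stages"]["identity_scan"] = scan_summary

    # --- stage: trees + conversion calls -----------------------------------
    tree_summary = {}
    calls = []
    if aln.n_sequences >= 4 and params["converted_label"] in regions.labels:
        aln_a = extract_region(aln, regions, params["converted_label"])
        tree_a = bootstrap_support(aln_a, params["model"], params["n_boot"],
                                   stage_seeds["tree_a"])
        (outdir / "tree_converted.nwk").write_text(tree_a.newick() + "\n")
        tree_b = None
        if params["control_label"] in regions.labels:
            aln_b = extract_region(aln, regions, params["control_label"])
            tree_b = bootstrap_support(aln_b, params["model"], params["n_boot"],
                                       stage_seeds["tree_b"])
            (outdir / "tree_control.nwk").write_text(tree_b.newick() + "\n")
        calls = conversion_signature(tree_a, tree_b, labels)
        with open(outdir / "conversion_calls.tsv", "w") as fh:
            fh.write("species\tconverted\tsupport\tnote\n")
            for c in calls:
                supp = "NA" if c.support is None else f"{c.support:.1f}"
                conv = "NA" if c.converted is None else str(c.converted).lower()
                fh.write(f"{c.species}\t{conv}\t{supp}\t{c.note}\n")
        tree_summary = {
            "converted_species": sorted(c.species for c in calls if c.converted),
            "calls": {c.species: c.converted for c in calls},
        }
    summary["stages"]["trees"] = tree_summary

    # --- stage: timing ------------------------------------------------------
    timing_label = params["noncoding_label"] or params["converted_label"]
    timing_summary = {}
    if timing_label in regions.labels:
        sub = extract_region(aln, regions, timing_label)
        with open(outdir / "timing.tsv", "w") as fh:
            fh.write("species\td\tvar_d\tT_myr\tT_se_myr\tse_from_d\tse_from_lambda\n")
            for sp, (l1, l2) in sorted(paired.items()):
                D = pairwise_distance(sub.subset([l1, l2]), params["model"])
                est = tim.estimate_timing(D.pair(l1, l2), D.pair_var(l1, l2),
                                          params["lambda"], params["lambda_se"])
                fh.write(f"{sp}\t{est.d:.6f}\t{est.var_d:.3e}\t{est.T_myr:.1f}"
                         f"\t{est.T_se_myr:.1f}\t{est.T_se_from_d / 1e6:.1f}"
                         f"\t{est.T_se_from_lambda / 1e6:.1f}\n")
                timing_summary[sp] = round(est.T_myr, 1)
    summary["stages"]["timing"] = timing_summary

    # --- stage: constraint --------------------------------------------------
    constraint_summary = {}
    if params["coding_label"] and params["coding_label"] in regions.labels \
            and aln.n_sequences >= 4:
        part = classify_sites(aln, regions, coding_label=params["coding_label"])
        topo_path = cfg.get("inputs", {}).get("topology")
        if topo_path:
            topo = PhyloTree.from_newick(Path(topo_path).read_text())
        else:
            # reference topology from the intronic (noncoding) sites
            noncod = aln.take_columns(part.columns_of("noncoding"))
            topo = nj_tree(pairwise_distance(noncod, params["model"]))
        table = branch_constraint_test(aln, part, topo, params["n_boot"],
                                       stage_seeds["constraint"])
        table.to_csv(outdir / "branch_rates.tsv", sep="\t")
        constraint_summary = {
            "n_branches": int(len(table)),
            "significant_branches": sorted(table.index[table["p"] < 0.02]),
        }
    summary["stages"]["constraint"] = constraint_summary

    # --- stage: glycan ------------------------------------------------------
    glycan_summary = {}
    glycan_path = cfg.get("inputs", {}).get("glycan")
    if glycan_path:
        M = gly.read_glycan_tsv(glycan_path)
        norm = gly.rms_normalize(M, axis="rows")
        gly.write_glycan_tsv(norm, outdir / "glycan_normalized.tsv")
        for axis, name in (("rows", "siglecs"), ("columns", "glycans")):
            dendro = gly.hcluster_complete(norm, axis=axis)
            (outdir / f"dendrogram_{name}.nwk").write_text(dendro.to_newick() + "\n")
        glycan_summary = {"n_siglecs": int(M.shape[0]), "n_glycans": int(M.shape[1])}
    summary["stages"]["glycan"] = glycan_summary

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
        fh.write("\n")
    log.info("pipeline finished in %.1fs (seed=%d, config=%s)",
             time.perf_counter() - t0, seed, summary["config_hash"])
    return summary
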