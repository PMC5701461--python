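"""Forward simulation of a duplicated locus pair with gene conversion.

The model: a single ancestral sequence duplicates into two linked loci
(inhibitory/activating paralogs, e.g. SIGLEC11/SIGLEC16) at
``duplication_time`` years before present.  Both copies then evolve
independently down a dated species tree under Jukes–Cantor substitution at
the neutral rate ``lambda_neutral`` per site per year; sites in the
nonsynonymous class (codon positions 1–2 of coding blocks) are scaled by a
branch- and locus-specific multiplier omega, so omega < 1 models purifying
constraint and omega ~ 1 its relaxation.  Discrete gene-conversion events
copy a donor tract onto the acceptor locus instantaneously at a given time
on a given species-tree branch, homogenizing the pair within the tract.

Output is a gap-free alignment (one row per species x locus) plus a
machine-readable :class:`TruthRecord` with the realized substitution counts
and applied events, used by the recovery tests downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np

from .seq_io import Alignment

MYR = 1.0e6
BASES = np.array(list("ACGT"))

DEFAULT_SPECIES_TREE = (
    "((((Hsa:6500000,Ptr:6500000):2500000,Ggo:9000000):9000000,"
    "Hla:18000000):12000000,Pan:30000000);"
)
DEFAULT_LAMBDA = 1.4e-9  # neutral substitutions/site/year
SITE_CLASSES = ("noncoding", "synonymous", "nonsynonymous")


@dataclass(frozen=True)
class ConversionEvent:
    """One instantaneous donor->acceptor tract copy on a species-tree branch."""

    lineage: str          # branch id = name of the node below the branch
    time: float           # years before present; within the branch interval
    donor: str            # locus id
    acceptor: str         # locus id
    tract: tuple[int, int]  # half-open, ungapped coordinates

    def __post_init__(self) -> None:
        if self.donor == self.acceptor:
            raise ValueError("conversion donor and acceptor must differ")
        if not (0 <= self.tract[0] < self.tract[1]):
            if self.tract[0] != self.tract[1]:  # empty tract = explicit no-op
                raise ValueError(f"bad tract {self.tract}")


@dataclass
class SimConfig:
    species_tree: str = DEFAULT_SPECIES_TREE   # Newick, branch lengths in years
    duplication_time: float = 40.0 * MYR       # years before present
    lambda_neutral: float = DEFAULT_LAMBDA
    site_layout: list[tuple[str, int]] = field(
        default_factory=lambda: [("noncoding", 800), ("coding", 1998), ("noncoding", 200)]
    )
    loci: tuple[str, str] = ("S11", "S16")
    omega_per_branch: dict[tuple[str, str], float] = field(default_factory=dict)
    conversion_events: list[ConversionEvent] = field(default_factory=list)
    seed: int = 0

    @property
    def length(self) -> int:
        return sum(n for _, n in self.site_layout)

    def site_classes(self) -> np.ndarray:
        """Per-site class index: 0 noncoding, 1 synonymous, 2 nonsynonymous."""
        classes = []
        for kind, n in self.site_layout:
            if kind == "noncoding":
                classes.extend([0] * n)
            elif kind == "coding":
                if n % 3 != 0:
                    raise ValueError(f"coding block length {n} not divisible by 3")
                # codon positions 1-2 nonsynonymous-class, 3 synonymous-class
                classes.extend(([2, 2, 1] * (n // 3)))
            else:
                raise ValueError(f"unknown block kind {kind!r}")
        return np.asarray(classes, dtype=np.int8)

    def omega(self, branch: str, locus: str) -> float:
        return self.omega_per_branch.get((branch, locus), 1.0)


@dataclass
class TruthRecord:
    """Simulator ground truth: what happened, for recovery tests."""

    seed: int
    duplication_time: float
    lambda_neutral: float
    species: list[str]
    loci: list[str]
    events: list[dict]
    subst_counts: dict[str, int]   # "branch/locus/class" -> realized event count
    converted_species: dict[str, float]  # species -> most recent conversion time
    expected_paralog_time: dict[str, float]  # species -> divergence time of the
    # paralog pair inside the most recent conversion tract (duplication_time
    # when no conversion hit the lineage)

    def total_substitutions(self) -> int:
        return int(sum(self.subst_counts.values()))

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        return cls(**d)


class _SpNode:
    __slots__ = ("name", "age", "children", "parent")

    def __init__(self, name, age):
        self.name, self.age = name, age
        self.children: list[_SpNode] = []
        self.parent: _SpNode | None = None


def _parse_species_tree(newick: str) -> _SpNode:
    """Dated species tree -> node structure with ages (years before present)."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    counter = [0]

    def depth(nd):
        d = 0.0
        while nd.parent_node is not None:
            d += nd.edge.length or 0.0
            nd = nd.parent_node
        return d

    height = max(depth(lf) for lf in tree.leaf_node_iter())

    def convert(nd, cum):
        age = height - cum
        if nd.is_leaf():
            name = nd.taxon.label.replace(" ", "_")
            age = 0.0 if abs(age) < 1e-6 * max(height, 1.0) else age
        else:
            counter[0] += 1
            name = nd.label or f"anc{counter[0]}"
        node = _SpNode(name, age)
        for ch in nd.child_nodes():
            child = convert(ch, cum + (ch.edge.length or 0.0))
            child.parent = node
            node.children.append(child)
        return node

    return convert(tree.seed_node, 0.0)


def _iter_nodes(root: _SpNode):
    yield root
    for ch in root.children:
        yield from _iter_nodes(ch)


def apply_conversion(donor_seq: str, acceptor_seq: str, tract: tuple[int, int]) -> str:
    """Copy donor_seq[tract] onto the acceptor; everything else unchanged."""
    if len(donor_seq) != len(acceptor_seq):
        raise ValueError(
            f"length mismatch: donor {len(donor_seq)} vs acceptor {len(acceptor_seq)}"
        )
    start, end = tract
    if start == end:
        return acceptor_seq
    if not (0 <= start < end <= len(acceptor_seq)):
        raise ValueError(f"tract {tract} out of range for length {len(acceptor_seq)}")
    return acceptor_seq[:start] + donor_seq[start:end] + acceptor_seq[end:]


def _evolve(seq: np.ndarray, dt: float, cfg: SimConfig, classes: np.ndarray,
            class_sites: dict[int, np.ndarray], branch: str, locus: str,
            rng: np.random.Generator, counts: dict[str, int]) -> np.ndarray:
    """Jukes–Cantor evolution of `seq` for dt years; counts realized events."""
    if dt < 0:
        raise ValueError(f"negative branch segment on {branch}: {dt}")
    seq = seq.copy()
    for ci, cname in enumerate(SITE_CLASSES):
        sites = class_sites[ci]
        if sites.size == 0:
            continue
        rate = cfg.lambda_neutral * (cfg.omega(branch, locus) if ci == 2 else 1.0)
        n_events = rng.poisson(rate * dt * sites.size)
        if n_events:
            hit = sites[rng.integers(0, sites.size, n_events)]
            for site in hit:  # sequential multiple hits allowed
                seq[site] = (seq[site] + 1 + rng.integers(0, 3)) % 4
        key = f"{branch}/{locus}/{cname}"
        counts[key] = counts.get(key, 0) + int(n_events)
    return seq


def simulate_history(cfg: SimConfig) -> tuple[Alignment, TruthRecord]:
    """Simulate the duplicated pair down the species tree; deterministic per seed."""
    rng = np.random.default_rng(cfg.seed)
    root = _parse_species_tree(cfg.species_tree)
    classes = cfg.site_classes()
    L = classes.size
    class_sites = {ci: np.flatnonzero(classes == ci) for ci in range(3)}
    node_names = {nd.name for nd in _iter_nodes(root)} | {"stem"}

    events_by_branch: dict[str, list[ConversionEvent]] = {}
    for ev in cfg.conversion_events:
        if ev.lineage not in node_names:
            raise ValueError(
                f"conversion event on unknown branch {ev.lineage!r}; "
                f"known: {sorted(node_names)}"
            )
        if ev.donor not in cfg.loci or ev.acceptor not in cfg.loci:
            raise ValueError(f"unknown locus in event {ev}")
        if ev.tract[1] > L:
            raise ValueError(f"tract {ev.tract} out of range for length {L}")
        events_by_branch.setdefault(ev.lineage, []).append(ev)

    if cfg.duplication_time < root.age:
        raise ValueError("duplication_time must predate the species-tree root")

    counts: dict[str, int] = {}
    anc = rng.integers(0, 4, L)

    def run_branch(seqs: dict[str, np.ndarray], branch: str,
                   t_hi: float, t_lo: float) -> dict[str, np.ndarray]:
        evs = sorted(events_by_branch.get(branch, []), key=lambda e: -e.time)
        t = t_hi
        for ev in evs:
            if not (t_lo <= ev.time <= t_hi):
                raise ValueError(
                    f"event time {ev.time} outside branch {branch} "
                    f"interval [{t_lo}, {t_hi}]"
                )
            for locus in cfg.loci:
                seqs[locus] = _evolve(seqs[locus], t - ev.time, cfg, classes,
                                      class_sites, branch, locus, rng, counts)
            s, e = ev.tract
            seqs[ev.acceptor] = seqs[ev.acceptor].copy()
            seqs[ev.acceptor][s:e] = seqs[ev.donor][s:e]
            t = ev.time
        for locus in cfg.loci:
            seqs[locus] = _evolve(seqs[locus], t - t_lo, cfg, classes,
                                  class_sites, branch, locus, rng, counts)
        return seqs

    # stem: duplication down to species-tree root
    seqs = {cfg.loci[0]: anc.copy(), cfg.loci[1]: anc.copy()}
    seqs = run_branch(seqs, "stem", cfg.duplication_time, root.age)

    names: list[str] = []
    rows: list[str] = []
    species: list[str] = []

    def descend(node: _SpNode, seqs: dict[str, np.ndarray]) -> None:
        if not node.children:
            species.append(node.name)
            for locus in cfg.loci:
                names.append(f"{node.name}_{locus}")
                rows.append("".join(BASES[seqs[locus]]))
            return
        for ch in node.children:
            child_seqs = {k: v.copy() for k, v in seqs.items()}
            child_seqs = run_branch(child_seqs, ch.name, node.age, ch.age)
            descend(ch, child_seqs)

    descend(root, seqs)

    # ground truth per species: most recent conversion on its root-to-tip path
    converted: dict[str, float] = {}
    expected_time: dict[str, float] = {}
    paths: dict[str, list[str]] = {}

    def collect_paths(node: _SpNode, path: list[str]) -> None:
        path = path + [node.name]
        if not node.children:
            paths[node.name] = ["stem"] + path
        for ch in node.children:
            collect_paths(ch, path)

    collect_paths(root, [])
    for sp in species:
        times = [ev.time for b in paths[sp] for ev in events_by_branch.get(b, [])]
        if times:
            converted[sp] = min(times)  # most recent
            expected_time[sp] = min(times)
        else:
            expected_time[sp] = cfg.duplication_time

    truth = TruthRecord(
        seed=cfg.seed,
        duplication_time=cfg.duplication_time,
        lambda_neutral=cfg.lambda_neutral,
        species=species,
        loci=list(cfg.loci),
        events=[{**asdict(ev), "tract": list(ev.tract)} for ev in cfg.conversion_events],
        subst_counts=counts,
        converted_species=converted,
        expected_paralog_time=expected_time,
    )
    return Alignment(names, rows), truth
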