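"""Alignment and region-annotation I/O, plus site classification.

The central containers are :class:`Alignment` (equal-length nucleotide rows
over ``{A,C,G,T,-,N}``) and :class:`RegionMap` (labeled half-open column
intervals on the alignment: exon/intron/upstream blocks, or the high-identity
regions called by the identity scan).  ``classify_sites`` partitions alignment
columns into noncoding / synonymous / nonsynonymous classes and produces
Nei–Gojobori (1986) fractional synonymous/nonsynonymous site counts per
sequence pair, the inputs of the relaxed-constraint analysis.

Coordinates are 0-based half-open internally; report writers convert to
1-based inclusive.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_CHARS = set("ACGT-N")
GAPLIKE = set("-N")

# codon -> amino acid, standard code; '*' marks stops
CODON_TABLE: dict[str, str] = {
    "".join(c): str(Seq("".join(c)).translate())
    for c in itertools.product("ACGT", repeat=3)
}


class AlignmentError(ValueError):
    """Raised for malformed alignments (ragged rows, duplicate names...)."""


@dataclass
class Alignment:
    """Named, equal-length, gap-containing nucleotide sequences."""

    names: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise AlignmentError("empty alignment")
        if len(self.names) != len(self.rows):
            raise AlignmentError("names/rows length mismatch")
        if len(set(self.names)) != len(self.names):
            raise AlignmentError("duplicate sequence names")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise AlignmentError(
                f"not an alignment: unequal row lengths {sorted(lengths)}"
            )
        if self.length < 1:
            raise AlignmentError("alignment has zero columns")
        self.rows = [r.upper() for r in self.rows]
        bad = set("".join(self.rows)) - VALID_CHARS
        if bad:
            raise AlignmentError(f"invalid characters in alignment: {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    def row(self, name: str) -> str:
        return self.rows[self.names.index(name)]

    def subset(self, names: list[str]) -> "Alignment":
        return Alignment(list(names), [self.row(n) for n in names])

    def take_columns(self, cols) -> "Alignment":
        cols = list(cols)
        return Alignment(list(self.names), ["".join(r[c] for c in cols) for r in self.rows])

    def as_matrix(self) -> np.ndarray:
        """(n_sequences, length) array of single characters."""
        return np.array([list(r) for r in self.rows], dtype="U1")


@dataclass
class RegionMap:
    """Labeled half-open intervals on an alignment's columns.

    Same-label intervals must be disjoint; different labels may overlap
    (e.g. ``Ac`` nested inside ``A``).
    """

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for label, start, end in self.intervals:
            if not (0 <= start < end):
                raise ValueError(f"bad interval {label}:[{start},{end})")
        by_label: dict[str, list[tuple[int, int]]] = {}
        for label, start, end in self.intervals:
            by_label.setdefault(label, []).append((start, end))
        for label, ivs in by_label.items():
            ivs = sorted(ivs)
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 < e1:
                    raise ValueError(f"overlapping intervals for label {label!r}")

    @property
    def labels(self) -> list[str]:
        seen: list[str] = []
        for label, _, _ in self.intervals:
            if label not in seen:
                seen.append(label)
        return seen

    def columns(self, label: str) -> list[int]:
        if label not in self.labels:
            raise KeyError(
                f"unknown region label {label!r}; available: {self.labels}"
            )
        cols: list[int] = []
        for lab, start, end in sorted(self.intervals):
            if lab == label:
                cols.extend(range(start, end))
        return cols

    def validate_against(self, aln: Alignment) -> None:
        for label, _, end in self.intervals:
            if end > aln.length:
                raise ValueError(
                    f"interval {label!r} ends at {end} beyond alignment length {aln.length}"
                )


def read_alignment(path) -> Alignment:
    """Read a FASTA alignment; all records must have equal length."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"empty or unparseable FASTA: {path}")
    return Alignment([r.id for r in records], [str(r.seq) for r in records])


def write_alignment(aln: Alignment, path) -> None:
    records = [
        SeqRecord(Seq(row), id=name, description="")
        for name, row in zip(aln.names, aln.rows)
    ]
    SeqIO.write(records, str(path), "fasta")


def read_regions(path) -> RegionMap:
    """BED-like chrom-less TSV: label, start, end[, strand]."""
    intervals = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            intervals.append((parts[0], int(parts[1]), int(parts[2])))
    return RegionMap(intervals)


def write_regions(regions: RegionMap, path) -> None:
    with open(path, "w") as fh:
        for label, start, end in regions.intervals:
            fh.write(f"{label}\t{start}\t{end}\t+\n")


def extract_region(aln: Alignment, regions: RegionMap, label: str) -> Alignment:
    """Concatenate the columns of every interval carrying `label`, in order."""
    regions.validate_against(aln)
    return aln.take_columns(regions.columns(label))


# ---------------------------------------------------------------------------
# Nei–Gojobori site counting
# ---------------------------------------------------------------------------

def _syn_site_fraction(codon: str) -> list[float]:
    """Per-position fraction of the 3 single-base changes that are synonymous.

    Changes creating a stop codon count as nonsynonymous.
    """
    aa = CODON_TABLE[codon]
    fracs = []
    for pos in range(3):
        syn = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if CODON_TABLE[alt] == aa and CODON_TABLE[alt] != "*":
                syn += 1
        fracs.append(syn / 3.0)
    return fracs


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous difference counts between two codons.

    Multi-hit codons are averaged over all minimal substitution pathways;
    pathways passing through a stop codon are excluded (all-stop fallback:
    average over every pathway).
    """
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0

    def walk(cur: str, remaining: list[int], allow_stops: bool):
        if not remaining:
            return [(0.0, 0.0)]
        results = []
        for pos in remaining:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            # prune orderings passing through an intermediate stop codon
            if CODON_TABLE[nxt] == "*" and not allow_stops and len(remaining) > 1:
                continue
            step_syn = 1.0 if (
                CODON_TABLE[nxt] == CODON_TABLE[cur] and CODON_TABLE[nxt] != "*"
            ) else 0.0
            for s, n in walk(nxt, [p for p in remaining if p != pos], allow_stops):
                results.append((step_syn + s, (1.0 - step_syn) + n))
        return results

    paths = walk(c1, positions, allow_stops=False)
    if not paths:
        paths = walk(c1, positions, allow_stops=True)
    s = sum(p[0] for p in paths) / len(paths)
    n = sum(p[1] for p in paths) / len(paths)
    return s, n


def codon_pair_counts(c1: str, c2: str) -> tuple[float, float, float, float]:
    """(S, N, Sd, Nd) for one aligned codon pair, site counts averaged over
    the two sequences."""
    f1, f2 = _syn_site_fraction(c1), _syn_site_fraction(c2)
    s_sites = sum(f1) / 2.0 + sum(f2) / 2.0
    n_sites = 3.0 - s_sites
    sd, nd = _pathway_diffs(c1, c2)
    return s_sites, n_sites, sd, nd


@dataclass
class SitePartition:
    """Per-column site classes plus per-pair Nei–Gojobori site totals.

    class_of_column entries are 'noncoding', 'synonymous', 'nonsynonymous'
    or 'excluded' (gap or N in any considered sequence).  The per-class
    column labels use the codon-position convention (positions 1–2
    nonsynonymous, position 3 synonymous) shared with the sequence
    simulator; pair_counts holds the fractional Nei–Gojobori S/N site and
    difference totals per sequence pair.
    """

    class_of_column: list[str]
    pair_counts: dict[tuple[str, str], dict[str, float]]

    def columns_of(self, klass: str) -> list[int]:
        return [i for i, c in enumerate(self.class_of_column) if c == klass]


def classify_sites(
    aln: Alignment,
    coding: RegionMap,
    coding_label: str = "exon",
    noncoding_label: str | None = None,
) -> SitePartition:
    """Partition columns into site classes and count Nei–Gojobori sites.

    Coding columns are the (concatenated, in-frame) intervals labeled
    `coding_label`; their total gapless length per pair must be divisible
    by 3.  All other columns are noncoding (or restricted to
    `noncoding_label`'s intervals when given).  Codon pairs containing an
    internal stop raise a warning and are excluded from the counts.
    """
    coding.validate_against(aln)
    # a map without the coding label means an all-noncoding alignment
    coding_cols = coding.columns(coding_label) if coding_label in coding.labels else []
    if len(coding_cols) % 3 != 0:
        raise ValueError(
            f"coding region length {len(coding_cols)} is not divisible by 3"
        )
    if noncoding_label is not None:
        noncoding_cols = set(coding.columns(noncoding_label))
    else:
        noncoding_cols = set(range(aln.length)) - set(coding_cols)

    mat = aln.as_matrix()
    gapped_any = np.isin(mat, list(GAPLIKE)).any(axis=0)

    classes = []
    coding_set = set(coding_cols)
    pos_in_codon = {c: i % 3 for i, c in enumerate(coding_cols)}
    for col in range(aln.length):
        if gapped_any[col]:
            classes.append("excluded")
        elif col in coding_set:
            classes.append("synonymous" if pos_in_codon[col] == 2 else "nonsynonymous")
        elif col in noncoding_cols:
            classes.append("noncoding")
        else:
            classes.append("excluded")

    pair_counts: dict[tuple[str, str], dict[str, float]] = {}
    for i, j in itertools.combinations(range(aln.n_sequences), 2):
        s = n = sd = nd = 0.0
        for k in range(0, len(coding_cols), 3):
            cols = coding_cols[k:k + 3]
            c1 = "".join(mat[i, c] for c in cols)
            c2 = "".join(mat[j, c] for c in cols)
            if set(c1) & GAPLIKE or set(c2) & GAPLIKE:
                continue  # pairwise deletion per codon
            if CODON_TABLE[c1] == "*" or CODON_TABLE[c2] == "*":
                warnings.warn(
                    f"internal stop codon in pair ({aln.names[i]}, {aln.names[j]}); "
                    "codon excluded"
                )
                continue
            ds, dn, dsd, dnd = codon_pair_counts(c1, c2)
            s, n, sd, nd = s + ds, n + dn, sd + dsd, nd + dnd
        pair_counts[(aln.names[i], aln.names[j])] = {
            "S": s, "N": n, "Sd": sd, "Nd": nd,
        }
    return SitePartition(classes, pair_counts)
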