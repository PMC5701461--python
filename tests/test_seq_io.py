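"""Alignment I/O, region extraction and Nei–Gojobori site classification."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import CODONS, AA, ng_syn_sites
from paraconv.seq_io import (Alignment, AlignmentError, RegionMap,
                             classify_sites, codon_pair_counts, extract_region,
                             read_alignment, write_alignment)


class TestAlignment:
    def test_identity_roundtrip_minimal(self):
        aln = Alignment(["x", "y"], ["ACGT", "ACGT"])
        assert aln.length == 4 and aln.n_sequences == 2

    def test_unequal_lengths_rejected(self):
        with pytest.raises(AlignmentError, match="not an alignment"):
            Alignment(["x", "y"], ["ACGT", "ACGTA"])

    def test_duplicate_names_rejected(self):
        with pytest.raises(AlignmentError, match="duplicate"):
            Alignment(["x", "x"], ["ACGT", "ACGT"])

    def test_invalid_characters_rejected(self):
        with pytest.raises(AlignmentError, match="invalid"):
            Alignment(["x"], ["ACGU"])

    def test_lowercase_uppercased(self):
        assert Alignment(["x"], ["acgt"]).rows == ["ACGT"]

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(AlignmentError, match="empty"):
            read_alignment(p)

    def test_fasta_roundtrip_of_simulated_alignment(self, tmp_path,
                                                    simulated_six_taxon):
        _, aln, _ = simulated_six_taxon
        path = tmp_path / "sim.fasta"
        write_alignment(aln, path)
        back = read_alignment(path)
        assert back.names == aln.names
        assert back.rows == aln.rows


class TestRegions:
    def test_single_interval_slice(self):
        aln = Alignment(["x", "y"], ["ACGTACGT", "ACGTACGT"])
        sub = extract_region(aln, RegionMap([("r", 0, 4)]), "r")
        assert sub.rows == ["ACGT", "ACGT"]

    def test_disjoint_intervals_concatenate(self):
        aln = Alignment(["x"], ["ACGTACGT"])
        sub = extract_region(aln, RegionMap([("r", 0, 2), ("r", 4, 6)]), "r")
        assert sub.rows == ["ACAC"]

    def test_full_label_is_identity(self, flat_regions):
        aln = Alignment(["x", "y"], ["ACGTACGT", "TGCATGCA"])
        assert extract_region(aln, flat_regions, "all").rows == aln.rows

    def test_unknown_label_lists_available(self, flat_regions):
        aln = Alignment(["x"], ["ACGTACGT"])
        with pytest.raises(KeyError, match="left"):
            extract_region(aln, flat_regions, "nope")

    def test_same_label_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            RegionMap([("r", 0, 5), ("r", 3, 8)])

    def test_extracted_tract_matches_truth_length(self, simulated_six_taxon):
        cfg, aln, truth = simulated_six_taxon
        (tract,) = [tuple(e["tract"]) for e in truth.events]
        sub = extract_region(aln, RegionMap([("Ac", *tract)]), "Ac")
        assert sub.length == tract[1] - tract[0]


class TestNeiGojobori:
    def test_ttt_sites_from_enumeration(self):
        s, n, sd, nd = codon_pair_counts("TTT", "TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)
        assert (sd, nd) == (0.0, 0.0)

    def test_ttt_vs_tta_worked_example(self):
        s, n, sd, nd = codon_pair_counts("TTT", "TTA")
        assert s == pytest.approx(0.5)
        assert n == pytest.approx(2.5)
        assert sd == pytest.approx(0.0)
        assert nd == pytest.approx(1.0)

    @given(st.sampled_from([c for c in CODONS if AA[c] != "*"]))
    @settings(deadline=None, max_examples=60)
    def test_site_counts_match_neighbor_enumeration(self, codon):
        s, n, _, _ = codon_pair_counts(codon, codon)
        assert s == pytest.approx(ng_syn_sites(codon))
        assert s + n == pytest.approx(3.0)

    @given(st.sampled_from([c for c in CODONS if AA[c] != "*"]),
           st.sampled_from([c for c in CODONS if AA[c] != "*"]))
    @settings(deadline=None, max_examples=60)
    def test_pair_counts_symmetric(self, c1, c2):
        s12, n12, sd12, nd12 = codon_pair_counts(c1, c2)
        s21, n21, sd21, nd21 = codon_pair_counts(c2, c1)
        assert s12 == pytest.approx(s21)
        assert n12 == pytest.approx(n21)
        assert sd12 == pytest.approx(sd21)
        assert nd12 == pytest.approx(nd21)
        ndiff = sum(a != b for a, b in zip(c1, c2))
        assert sd12 + nd12 == pytest.approx(ndiff)


class TestClassifySites:
    def test_all_noncoding_input_has_zero_sn_sites(self):
        aln = Alignment(["x", "y"], ["ACGTAC", "ACGTAC"])
        part = classify_sites(aln, RegionMap([("upstream", 0, 6)]), "exon")
        assert part.columns_of("noncoding") == list(range(6))
        counts = part.pair_counts[("x", "y")]
        assert counts["S"] == counts["N"] == 0.0

    def test_codon_position_classes(self):
        aln = Alignment(["x", "y"], ["AAATTTGGGCCC", "AAATTTGGGCCC"])
        part = classify_sites(aln, RegionMap([("exon", 0, 6)]), "exon")
        assert part.class_of_column[:6] == [
            "nonsynonymous", "nonsynonymous", "synonymous",
            "nonsynonymous", "nonsynonymous", "synonymous",
        ]
        assert part.class_of_column[6:] == ["noncoding"] * 6

    def test_gapped_columns_excluded(self):
        aln = Alignment(["x", "y"], ["A-GTTT", "ACGTTT"])
        part = classify_sites(aln, RegionMap([("exon", 3, 6)]), "exon")
        assert part.class_of_column[1] == "excluded"

    def test_frame_violation_rejected(self):
        aln = Alignment(["x"], ["ACGTA"])
        with pytest.raises(ValueError, match="divisible by 3"):
            classify_sites(aln, RegionMap([("exon", 0, 5)]), "exon")

    def test_internal_stop_warns_and_excluded(self):
        aln = Alignment(["x", "y"], ["TAATTT", "TACTTT"])
        with pytest.warns(UserWarning, match="stop"):
            part = classify_sites(aln, RegionMap([("exon", 0, 6)]), "exon")
        # only the TTT codon contributes
        assert part.pair_counts[("x", "y")]["S"] == pytest.approx(1 / 3)

    def test_total_sites_equal_ungapped_coding_length(self, simulated_six_taxon):
        cfg, aln, _ = simulated_six_taxon
        # simulated fixture is noncoding; build a coding toy instead
        rng = np.random.default_rng(0)
        row = "".join(rng.choice(list("ACGT"), 30))
        aln2 = Alignment(["p", "q"], [row, row])
        part = classify_sites(aln2, RegionMap([("exon", 0, 30)]), "exon")
        c = part.pair_counts[("p", "q")]
        has_stop = any(AA[row[i:i + 3]] == "*" for i in range(0, 30, 3))
        if not has_stop:
            assert c["S"] + c["N"] == pytest.approx(30.0)
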