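"""Sequence-level annotation: FASTA IO, ORF calling, ITR detection,
genome metrics and early-promoter scanning."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from conftest import random_dna
from epvkit.annotate import (
    Genome,
    MotifHit,
    OrfRecord,
    call_orfs,
    compute_genome_metrics,
    detect_itrs,
    filter_repetitive,
    read_fasta,
    reverse_complement,
    scan_early_promoters,
    upstream_window,
)

dna = st.text(alphabet="ACGTN", min_size=0, max_size=200)


class TestReadFasta:
    def test_single_record_uppercased(self, tmp_path):
        path = tmp_path / "g.fasta"
        path.write_text(">g\nacgt\n")
        (genome,) = read_fasta(path)
        assert genome.id == "g"
        assert genome.sequence == "ACGT"
        assert genome.length == 4

    def test_two_records_in_file_order(self, tmp_path):
        path = tmp_path / "two.fasta"
        path.write_text(">a\nACGT\n>b\nTTTT\n")
        genomes = read_fasta(path)
        assert [g.id for g in genomes] == ["a", "b"]

    def test_non_dna_character_names_record(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">g\nACXG\n")
        with pytest.raises(ValueError, match="'g'.*X"):
            read_fasta(path)

    def test_rna_u_rejected(self, tmp_path):
        path = tmp_path / "rna.fasta"
        path.write_text(">r\nACGU\n")
        with pytest.raises(ValueError, match="U"):
            read_fasta(path)

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(ValueError, match="no FASTA records"):
            read_fasta(path)


class TestReverseComplement:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGC", "GCAT"), ("AANT", "ANTT"), ("", ""), ("N", "N")],
    )
    def test_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    def test_rejects_non_dna(self):
        with pytest.raises(ValueError):
            reverse_complement("ACGU")

    @settings(derandomize=True, max_examples=50)
    @given(dna)
    def test_involution(self, seq):
        assert reverse_complement(reverse_complement(seq)) == seq


class TestCallOrfs:
    def test_minimal_orf_hand_translated(self):
        (orf,) = call_orfs(Genome("g", "ATGAAATAA"), min_aa=2)
        assert (orf.start, orf.end, orf.strand) == (0, 9, "+")
        assert orf.protein == "MK"
        assert orf.protein_length == 2

    def test_below_length_threshold_empty(self):
        assert call_orfs(Genome("g", "ATGAAATAA"), min_aa=50) == []

    def test_first_atg_per_stop_segment(self):
        # Two ATGs share one stop: the first defines the ORF.
        seq = "ATGATGAAATAA"
        (orf,) = call_orfs(Genome("g", seq), min_aa=2)
        assert (orf.start, orf.end) == (0, 12)
        assert orf.protein == "MMK"

    def test_orf_running_off_end_not_emitted(self):
        # ATG with no downstream stop in frame.
        assert call_orfs(Genome("g", "ATGAAAAAA"), min_aa=1) == []

    def test_n_codon_blocks_spanning_orf(self):
        # ATG, then an ambiguous codon before the stop: no ORF spans it, but
        # a later ATG after the N codon reaches the stop.
        seq = "ATG" + "ANA" + "ATG" + "AAA" + "TAA"
        (orf,) = call_orfs(Genome("g", seq), min_aa=2)
        assert (orf.start, orf.end) == (6, 15)
        assert orf.protein == "MK"

    def test_minus_strand_coordinates_forward(self):
        fwd = "ATGAAATAA"
        seq = reverse_complement(fwd)
        (orf,) = call_orfs(Genome("g", seq), min_aa=2)
        assert (orf.start, orf.end, orf.strand) == (0, 9, "-")
        assert orf.protein == "MK"

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1000, 5001))
        seq = random_dna(rng, n, gc=0.4, n_frac=0.01 if seed % 3 == 0 else 0.0)
        called = call_orfs(Genome("g", seq), min_aa=20)
        got = {(o.start, o.end, o.strand) for o in called}
        assert got == oracles.orf_oracle(seq, 20)

    @pytest.mark.parametrize("seed", range(5))
    def test_strand_symmetry(self, seed):
        rng = np.random.default_rng(100 + seed)
        seq = random_dna(rng, 3000)
        n = len(seq)
        fwd = call_orfs(Genome("g", seq), min_aa=20)
        rev = call_orfs(Genome("g", reverse_complement(seq)), min_aa=20)
        flip = {"+": "-", "-": "+"}
        fwd_set = {(o.start, o.end, o.strand, o.protein) for o in fwd}
        rev_set = {(n - o.end, n - o.start, flip[o.strand], o.protein) for o in rev}
        assert fwd_set == rev_set


class TestFilterRepetitive:
    def _orf(self, protein):
        if not protein.startswith("M"):
            protein = "M" + protein[1:]
        return OrfRecord("x", 0, 3 * (len(protein) + 1), "+", protein)

    def test_homopolymer_discarded(self):
        kept, discarded = filter_repetitive([self._orf("K" * 20)])
        assert kept == [] and len(discarded) == 1

    def test_diverse_protein_kept(self):
        kept, discarded = filter_repetitive([self._orf("MSKEALVRTGQDINFHWYPC")])
        assert discarded == [] and len(kept) == 1

    def test_two_letter_repeat_entropy_one_bit(self):
        # "MS" x20: dipeptide distribution is {MS, SM} each ~1/2 -> 1 bit < 2.
        kept, discarded = filter_repetitive([self._orf("MS" * 20)])
        assert kept == [] and len(discarded) == 1

    def test_three_letter_repeat_fails_entropy_only(self):
        # "MSK"x13: top residue fraction 1/3 < 0.5 but dipeptide entropy is
        # log2(3) ~ 1.585 bits < 2.0, so rule 2 alone discards it.
        kept, discarded = filter_repetitive([self._orf("MSK" * 13)])
        assert kept == [] and len(discarded) == 1

    def test_short_protein_kept_by_definition(self):
        kept, discarded = filter_repetitive([self._orf("M")])
        assert len(kept) == 1 and discarded == []

    def test_partition_is_exact(self):
        orfs = [self._orf("MSKEALVRTGQDINFHWYPC"), self._orf("Q" * 30)]
        kept, discarded = filter_repetitive(orfs)
        assert sorted(kept + discarded, key=id) == sorted(orfs, key=id)


class TestDetectItrs:
    def test_planted_itr_exact_at_zero_mismatch(self, itr_genome):
        genome, length = itr_genome
        res = detect_itrs(genome, max_mismatch_frac=0.0)
        assert res.length == length
        assert res.identity == 1.0
        assert res.left_span == (0, length)
        assert res.right_span == (genome.length - length, genome.length)

    def test_planted_itr_default_tolerance(self, itr_genome):
        # With a mismatch allowance the extension may absorb a few chance
        # matches past the boundary but never strays far.
        genome, length = itr_genome
        res = detect_itrs(genome)
        assert length <= res.length <= length + 50
        assert res.identity >= 0.98

    def test_random_genome_no_itr(self, rng):
        genome = Genome("r", random_dna(rng, 10_000))
        assert detect_itrs(genome) is None

    def test_symmetry_under_reverse_complement(self, itr_genome):
        genome, _ = itr_genome
        flipped = Genome("f", reverse_complement(genome.sequence))
        assert detect_itrs(genome).length == detect_itrs(flipped).length

    def test_small_mismatch_tolerated(self, rng):
        itr = random_dna(rng, 1000)
        # one substitution inside the right copy, outside the seed
        right = list(reverse_complement(itr))
        right[500] = {"A": "C", "C": "A", "G": "T", "T": "G", "N": "A"}[right[500]]
        genome = Genome("m", itr + random_dna(rng, 5000) + "".join(right))
        res = detect_itrs(genome, max_mismatch_frac=0.01)
        assert res.length >= 1000
        assert res.identity >= 0.99

    def test_too_short_genome_rejected(self):
        with pytest.raises(ValueError, match="min_seed"):
            detect_itrs(Genome("s", "ACGT"), min_seed=25)


class TestGenomeMetrics:
    def _orf_at(self, start, end):
        return OrfRecord("o", start, end, "+", "M" * ((end - start) // 3 - 1))

    def test_single_orf_density(self, rng):
        genome = Genome("g", random_dna(rng, 1000))
        m = compute_genome_metrics(genome, [self._orf_at(0, 300)], None)
        assert m.coding_density_percent == pytest.approx(30.0)

    def test_overlapping_orfs_union_not_sum(self, rng):
        genome = Genome("g", random_dna(rng, 1000))
        orfs = [self._orf_at(0, 300), self._orf_at(150, 450)]
        m = compute_genome_metrics(genome, orfs, None)
        assert m.coding_density_percent == pytest.approx(45.0)

    def test_gc_simple(self):
        m = compute_genome_metrics(Genome("g", "ATGC"), [], None)
        assert m.gc_percent == pytest.approx(50.0)

    def test_gc_denominator_excludes_n(self):
        m = compute_genome_metrics(Genome("g", "GCNN"), [], None)
        assert m.gc_percent == pytest.approx(100.0)

    def test_all_n_errors(self):
        with pytest.raises(ValueError, match="GC undefined"):
            compute_genome_metrics(Genome("g", "NNNN"), [], None)

    def test_density_monotone_and_order_invariant(self, rng):
        genome = Genome("g", random_dna(rng, 2000))
        orfs = [self._orf_at(0, 300), self._orf_at(600, 900), self._orf_at(100, 400)]
        densities = []
        for k in range(len(orfs) + 1):
            m = compute_genome_metrics(genome, orfs[:k], None)
            densities.append(m.coding_density_percent)
        assert densities == sorted(densities)
        m_rev = compute_genome_metrics(genome, orfs[::-1], None)
        assert m_rev.coding_density_percent == densities[-1]


class TestPromoterScan:
    def _genome_with_upstream(self, upstream, orf_body="ATG" + "AAA" * 60 + "TAA"):
        seq = upstream + orf_body
        orf = OrfRecord("o1", len(upstream), len(seq), "+", "M" + "K" * 60)
        return Genome("g", seq), orf

    def test_single_hit_matched_seq(self):
        genome, orf = self._genome_with_upstream("C" * 40 + "TGAAACGTAA" + "C" * 30)
        (hit,) = scan_early_promoters(genome, [orf])
        assert hit.matched_seq == "TGAAACGTAA"
        assert hit.offset == 31

    def test_adjacent_motif_offset_one(self):
        genome, orf = self._genome_with_upstream("C" * 30 + "TGAAACGTAA")
        (hit,) = scan_early_promoters(genome, [orf])
        assert hit.offset == 1

    def test_no_hits_in_t_run(self):
        genome, orf = self._genome_with_upstream("T" * 80)
        assert scan_early_promoters(genome, [orf]) == []

    def test_overlapping_hits_counted(self):
        # TGAAATGAAACCCCA contains two overlapping matches.
        genome, orf = self._genome_with_upstream("G" * 40 + "TGAAATGAAACCCCA" + "G" * 20)
        hits = scan_early_promoters(genome, [orf])
        win = upstream_window(genome, orf, 100)
        assert sorted(len(win) - (i + 10) + 1 for i in oracles.motif_oracle(win)) == sorted(
            h.offset for h in hits
        )
        assert len(hits) == 2

    def test_minus_strand_window(self):
        # Motif downstream of the ORF end on the forward strand, read on '-'.
        body = reverse_complement("ATG" + "AAA" * 60 + "TAA")
        upstream_rc = reverse_complement("G" * 50 + "TGAAACCCCA" + "G" * 10)
        seq = body + upstream_rc
        orf = OrfRecord("o1", 0, len(body), "-", "M" + "K" * 60)
        (hit,) = scan_early_promoters(Genome("g", seq), [orf])
        assert hit.matched_seq == "TGAAACCCCA"
        assert hit.offset == 11

    def test_window_truncated_at_genome_start(self):
        genome, orf = self._genome_with_upstream("TGAAACGTAA")
        (hit,) = scan_early_promoters(genome, [orf], window=100)
        assert hit.offset == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sliding_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        # AT-rich windows make TGAAA-like text reasonably likely.
        upstream = random_dna(rng, 100, gc=0.2)
        genome, orf = self._genome_with_upstream(upstream)
        hits = scan_early_promoters(genome, [orf])
        win = upstream_window(genome, orf, 100)
        expected = [len(win) - (i + 10) + 1 for i in oracles.motif_oracle(win)]
        assert sorted(h.offset for h in hits) == sorted(expected)

    def test_hit_count_invariant_to_orf_order(self, rng):
        ups = [random_dna(rng, 80, gc=0.2) for _ in range(3)]
        parts, orfs = [], []
        pos = 0
        for i, up in enumerate(ups):
            body = "ATG" + "AAA" * 60 + "TAA"
            parts.extend([up, body])
            orfs.append(OrfRecord(f"o{i}", pos + len(up), pos + len(up) + len(body), "+", "M" + "K" * 60))
            pos += len(up) + len(body)
        genome = Genome("g", "".join(parts))
        fwd = scan_early_promoters(genome, orfs)
        rev = scan_early_promoters(genome, orfs[::-1])
        assert sorted((h.orf_id, h.offset) for h in fwd) == sorted(
            (h.orf_id, h.offset) for h in rev
        )
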