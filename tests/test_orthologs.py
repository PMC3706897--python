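"""Ortholog search, supercontigs, alignment, indel extraction, coverage."""

import numpy as np
import pandas as pd
import pytest

from cghcnv import genomes as g
from cghcnv import orthologs as ort
from cghcnv.sequtils import random_dna, revcomp


def gotoh_local_score(a, b, match=5.0, mismatch=-4.0, open_=10.0, extend=0.5):
    """Quadratic affine-gap local alignment score (independent oracle).

    Gap of length L costs open_ + (L-1)*extend, matching the aligner's
    open/extend semantics.
    """
    n, m = len(a), len(b)
    NEG = -1e18
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), NEG)  # gap in a (consuming b)
    F = np.full((n + 1, m + 1), NEG)  # gap in b (consuming a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - open_, E[i][j - 1] - extend)
            F[i][j] = max(H[i - 1][j] - open_, F[i - 1][j] - extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


@pytest.fixture(scope="module")
def base_seq():
    return random_dna(np.random.default_rng(50), 3000)


class TestSelectAnalyzable:
    def _frags(self, contig, n):
        return pd.DataFrame(
            {
                "fragment_id": [f"{contig}_f{i}" for i in range(n)],
                "contig": contig,
                "start": np.arange(n) * 700,
                "end": np.arange(n) * 700 + 200,
            }
        )

    def test_internal_cnv_flanked_by_null_retained(self):
        frags = self._frags("c", 3)
        assert ort.select_analyzable_contigs({"c_f1"}, frags) == ["c"]

    def test_edge_cnv_rejected(self):
        frags = self._frags("c", 3)
        assert ort.select_analyzable_contigs({"c_f0"}, frags) == []

    def test_no_cnv_or_too_few_fragments_rejected(self):
        assert ort.select_analyzable_contigs(set(), self._frags("c", 2)) == []
        assert ort.select_analyzable_contigs({"c_f1"}, self._frags("c", 2)) == []


class TestFindOrthologs:
    def test_exact_copy_single_hit_identity_100(self, base_seq):
        match = ort.find_orthologs("r", base_seq, {"q1": base_seq})
        assert len(match.hits) == 1
        assert match.hits[0].identity == pytest.approx(100.0)
        assert match.hits[0].orientation == 1

    def test_ten_percent_divergence_no_hit(self, base_seq):
        rng = np.random.default_rng(51)
        seq = list(base_seq)
        for i in rng.choice(len(seq), size=len(seq) // 10, replace=False):
            seq[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[i]]
        with pytest.warns(UserWarning):
            match = ort.find_orthologs("r", base_seq, {"q1": "".join(seq)})
        assert not match.hits

    def test_split_reference_chained_in_order(self, base_seq):
        parts = {"qa": base_seq[1500:], "qb": base_seq[:1500]}
        match = ort.find_orthologs("r", base_seq, parts)
        assert [h.query_id for h in match.hits] == ["qb", "qa"]
        assert match.hits[0].ref_end <= match.hits[1].ref_start + 25

    def test_chance_kmer_share_rejected_by_coverage(self, base_seq):
        rng = np.random.default_rng(52)
        decoy = random_dna(rng, 1500) + base_seq[1000:1016] + random_dna(rng, 1500)
        with pytest.warns(UserWarning):
            match = ort.find_orthologs("r", base_seq, {"decoy": decoy})
        assert not match.hits

    def test_reverse_complement_hit_detected(self, base_seq):
        match = ort.find_orthologs("r", base_seq, {"q1": revcomp(base_seq)})
        assert len(match.hits) == 1
        assert match.hits[0].orientation == -1


class TestSupercontig:
    def test_single_hit_returns_contig(self, base_seq):
        match = ort.find_orthologs("r", base_seq, {"q1": base_seq})
        sc = ort.build_supercontig(match, {"q1": base_seq})
        assert sc.sequence == base_seq

    def test_two_part_chain_length_and_spacer(self, base_seq):
        parts = {"qa": base_seq[1500:], "qb": base_seq[:1500]}
        match = ort.find_orthologs("r", base_seq, parts)
        sc = ort.build_supercontig(match, parts)
        assert len(sc.sequence) == len(base_seq) + 50
        assert "N" * 50 in sc.sequence

    def test_reverse_hit_is_flipped_before_joining(self, base_seq):
        match = ort.find_orthologs("r", base_seq, {"q1": revcomp(base_seq)})
        sc = ort.build_supercontig(match, {"q1": revcomp(base_seq)})
        assert sc.sequence == base_seq

    def test_empty_match_raises(self):
        with pytest.raises(ValueError):
            ort.build_supercontig(ort.OrthologMatch("r"), {})


class TestAlignPair:
    def test_identical_sequences(self):
        seq = random_dna(np.random.default_rng(52), 500)
        aln = ort.align_pair(seq, seq)
        assert aln.score == 5 * 500  # EDNAFULL match score
        assert len(aln.blocks) == 1
        assert aln.identity() == 100.0
        # unit-match scoring: score equals the number of matched bases
        unit = ort.align_pair(seq, seq, aligner=ort.make_aligner(match=1.0, mismatch=-1.0))
        assert unit.score == 500

    def test_deletion_yields_two_blocks_with_ref_gap(self):
        seq = random_dna(np.random.default_rng(53), 700)
        query = seq[:300] + seq[400:]
        aln = ort.align_pair(seq, query)
        assert len(aln.blocks) == 2
        (r0, r1, _, _), (r2, _, q2, q2b) = aln.blocks[0], aln.blocks[1]
        assert r2 - r1 == 100

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_score_matches_quadratic_dp_oracle(self, seed):
        rng = np.random.default_rng(60 + seed)
        a = random_dna(rng, 220)
        # related sequence: copy with substitutions and an indel
        b = list(a[30:200])
        for i in rng.choice(len(b), size=8, replace=False):
            b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i]]
        b = "".join(b[:70]) + "".join(b[90:])
        aln = ort.align_pair(a, b)
        assert aln.score == pytest.approx(gotoh_local_score(a, b))

    def test_unrelated_sequences_score_small(self):
        rng = np.random.default_rng(70)
        a = random_dna(rng, 400)
        b = random_dna(rng, 400)
        aln = ort.align_pair(a, b)
        assert aln.score == pytest.approx(gotoh_local_score(a, b))
        # under unit-match scoring the best chance score is log-length noise
        unit = ort.make_aligner(match=1.0, mismatch=-1.0)
        assert ort.align_pair(a, b, aligner=unit).score < 40

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ort.align_pair("", "ACGT")
        with pytest.raises(ValueError):
            ort.align_pair("ACGT", "ACXT")


class TestExtractIndels:
    def test_small_gap_single_record(self):
        seq = random_dna(np.random.default_rng(54), 600)
        query = seq[:300] + seq[303:]
        recs = ort.extract_indels(ort.align_pair(seq, query))
        assert len(recs) == 1
        assert recs[0].side == "deletion"
        assert recs[0].size == 3

    def test_no_gaps_no_records(self):
        seq = random_dna(np.random.default_rng(55), 400)
        assert ort.extract_indels(ort.align_pair(seq, seq)) == []

    def test_adjacent_gap_runs_merge_to_replacement(self):
        rng = np.random.default_rng(56)
        seq = random_dna(rng, 700)
        filler = random_dna(rng, 25)
        query = seq[:300] + filler + seq[340:]  # 40 deleted, 25 inserted
        recs = ort.extract_indels(ort.align_pair(seq, query))
        assert len(recs) == 1
        rec = recs[0]
        assert rec.side == "replacement"
        # a couple of bp of junction slop from chance anchors is tolerated
        assert abs(len(rec.seq_ref) - 40) <= 2
        assert abs(len(rec.seq_query) - 25) <= 2

    def test_deletion_left_normalized_in_repeat_tract(self):
        rng = np.random.default_rng(57)
        left = random_dna(rng, 200)
        right = random_dna(rng, 200)
        seq = left + "ACGACGACG" + right  # 3x ACG tandem
        query = left + "ACGACG" + right  # one unit lost
        recs = ort.extract_indels(ort.align_pair(seq, query))
        assert len(recs) == 1
        assert recs[0].ref_start == 200  # leftmost equivalent placement
        assert recs[0].seq_ref == "ACG"

    def test_truncated_flank_flagged(self):
        seq = random_dna(np.random.default_rng(58), 100)
        query = seq[:5] + seq[15:]
        recs = ort.extract_indels(ort.align_pair(seq, query), min_flank=20)
        assert recs[0].flank_truncated


class TestFragmentCoverage:
    def _aln_with_deletion(self, rng, del_start, del_len, n=800):
        seq = random_dna(rng, n)
        query = seq[:del_start] + seq[del_start + del_len :]
        return ort.align_pair(seq, query), seq

    def test_half_covered_fragment(self):
        rng = np.random.default_rng(59)
        aln, _ = self._aln_with_deletion(rng, 300, 100)
        cov = ort.fragment_coverage(aln, "f", 200, 400)
        assert cov.percent == pytest.approx(50.0)
        assert cov.bin == "50-74"
        assert not cov.false_positive

    def test_fully_present_high_identity_flags_false_positive(self):
        seq = random_dna(np.random.default_rng(61), 600)
        query = seq[:100] + seq[101:]  # only a 1 bp indel outside nothing else
        aln = ort.align_pair(seq, query)
        cov = ort.fragment_coverage(aln, "f", 200, 400)
        assert cov.bin == "100"
        assert cov.false_positive

    def test_fragment_with_internal_big_indel_not_false_positive(self):
        rng = np.random.default_rng(62)
        aln, _ = self._aln_with_deletion(rng, 300, 2)
        cov = ort.fragment_coverage(aln, "f", 200, 402)
        assert cov.bin in ("75-99", "100")
        assert not cov.false_positive

    def test_absent_fragment_bin_zero(self):
        rng = np.random.default_rng(63)
        seq = random_dna(rng, 900)
        query = seq[:200] + seq[620:]  # fragment 250-450 fully deleted
        aln = ort.align_pair(seq, query)
        cov = ort.fragment_coverage(aln, "f", 250, 450)
        assert cov.percent == 0.0
        assert cov.bin == "0"

    @pytest.mark.parametrize(
        "percent,expected",
        [
            (0.0, "0"),
            (0.5, "0-24"),
            (24.9, "0-24"),
            (25.0, "25-49"),
            (49.9, "25-49"),
            (50.0, "50-74"),
            (74.9, "50-74"),
            (75.0, "75-99"),
            (99.9, "75-99"),
            (100.0, "100"),
        ],
    )
    def test_bins_partition_the_percent_axis(self, percent, expected):
        assert ort.coverage_bin(percent) == expected


class TestRoundTrip:
    @pytest.mark.parametrize("mech,size,kwargs", [
        ("SSA", 120, {"motif_len": 6}),
        ("none", 250, {}),
        ("slippage", 4, {}),
    ])
    def test_spiked_deletion_recovered_through_alignment(self, mech, size, kwargs):
        """Spike a deletion, run ortholog search -> supercontig -> alignment
        -> indel extraction: the size is exact and the position within 2 bp
        (microhomology permits equivalent placements)."""
        cfg = g.GenomeConfig(n_contigs=2, contig_length=5000, telomere_enriched=False)
        ref = g.generate_reference(cfg, seed=80)
        spec = g.VariantSpec("deletion", size, "contig_00001", 2500, mech, ("q",), **kwargs)
        spike = g.spike_variants(ref, [spec], seed=81)
        match = ort.find_orthologs(
            "contig_00001", spike.reference.contigs["contig_00001"], spike.genomes["q"]
        )
        sc = ort.build_supercontig(match, spike.genomes["q"])
        aln = ort.align_pair(spike.reference.contigs["contig_00001"], sc.sequence)
        recs = [r for r in ort.extract_indels(aln) if r.side == "deletion"]
        assert len(recs) == 1
        assert recs[0].size == size
        assert abs(recs[0].ref_start - 2500) <= 2


# ---------------------------------------------------------------------------
# property-based checks (hypothesis, derandomized)

from hypothesis import given, settings, strategies as st


@settings(max_examples=200, derandomize=True)
@given(percent=st.floats(min_value=0.0, max_value=100.0, allow_nan=False))
def test_coverage_bins_partition_percent_axis(percent):
    bins = [b for b in ort.COVERAGE_BINS if ort.coverage_bin(percent) == b]
    assert len(bins) == 1
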