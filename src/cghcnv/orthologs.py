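"""Sequence-level CNV confirmation.

Given a reference contig and a (more fragmented) query assembly, this module
finds orthologous query contigs (>95% identity local hits), concatenates them
into a supercontig ordered along the reference, aligns reference vs.
supercontig with an affine-gap Smith-Waterman (Bio.Align.PairwiseAligner),
extracts insertion/deletion records with breakpoint flanks, and bins how much
of each 200 bp array fragment is present in the query.

Indels are left-normalized: within a microhomology tract the gap is shifted to
its leftmost equivalent placement so that breakpoint-signature detection is
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .sequtils import canonical_kmer_codes, encode, revcomp

COVERAGE_BINS = ("0", "0-24", "25-49", "50-74", "75-99", "100")

SPACER_LEN = 50  # 'N' run joining supercontig parts; alignments never cross it


def make_aligner(
    match: float = 5.0,
    mismatch: float = -4.0,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    n_score: float = -10.0,
) -> Align.PairwiseAligner:
    """Local affine-gap aligner over ACGTN; N is heavily penalized so that
    alignments never bridge supercontig spacers.

    The default scoring is the EMBOSS Water convention (EDNAFULL match +5 /
    mismatch -4, gap open 10, extend 0.5). The strong mismatch penalty
    matters for breakpoint geometry: it makes an unalignable filler segment
    appear as adjacent ref-side and query-side gap runs (a replacement)
    instead of being absorbed as mismatch columns."""
    mat = substitution_matrices.Array("ACGTN", dims=2)
    for a in "ACGTN":
        for b in "ACGTN":
            if "N" in (a, b):
                mat[a, b] = n_score
            else:
                mat[a, b] = match if a == b else mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


_DEFAULT_ALIGNER: Align.PairwiseAligner | None = None


def default_aligner() -> Align.PairwiseAligner:
    global _DEFAULT_ALIGNER
    if _DEFAULT_ALIGNER is None:
        _DEFAULT_ALIGNER = make_aligner()
    return _DEFAULT_ALIGNER


# ---------------------------------------------------------------------------
# data types


@dataclass(frozen=True)
class OrthologHit:
    query_id: str
    orientation: int  # +1 forward, -1 reverse complement
    ref_start: int
    ref_end: int
    identity: float  # percent, matches / alignment columns * 100
    score: float


@dataclass
class OrthologMatch:
    ref_id: str
    hits: list[OrthologHit] = field(default_factory=list)

    def __bool__(self) -> bool:
        return bool(self.hits)


@dataclass
class SupercontigPart:
    query_id: str
    orientation: int
    offset: int  # start of this part in the supercontig
    length: int


@dataclass
class Supercontig:
    sequence: str
    parts: list[SupercontigPart]


@dataclass
class PairwiseAlignment:
    """A local alignment stored as coordinate blocks on both sequences."""

    ref_id: str
    query_id: str
    ref_seq: str
    query_seq: str
    score: float
    # each block: (ref_start, ref_end, q_start, q_end), strictly increasing
    blocks: list[tuple[int, int, int, int]]

    @property
    def ref_span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    def identity(self, count_gaps: bool = True) -> float:
        """Percent identity; with ``count_gaps=False`` gaps are excluded from
        the column count (gap-compressed identity, substitution divergence
        only)."""
        m, cols, aligned = alignment_identity_counts(self)
        denom = cols if count_gaps else aligned
        return 100.0 * m / denom if denom else 0.0


@dataclass
class IndelRecord:
    """An insertion/deletion (or replacement) from a pairwise alignment.

    `side` is relative to the query: "deletion" = sequence present in the
    reference but absent from the query; "insertion" = extra sequence in the
    query; "replacement" = a ref-only segment facing a query-only segment.
    Coordinates are 0-based half-open on the respective sequences.
    """

    ref_contig: str
    ref_start: int
    ref_end: int
    q_start: int
    q_end: int
    side: str  # deletion | insertion | replacement
    seq_ref: str  # ref-only sequence ("" for pure insertions)
    seq_query: str  # query-only sequence ("" for pure deletions)
    left_flank: str
    right_flank: str
    flank_truncated: bool = False

    @property
    def size(self) -> int:
        return max(len(self.seq_ref), len(self.seq_query))

    @property
    def indel_seq(self) -> str:
        """The deleted or inserted sequence (ref side wins for replacements)."""
        return self.seq_ref if self.seq_ref else self.seq_query

    @property
    def is_replacement(self) -> bool:
        return self.side == "replacement"


@dataclass(frozen=True)
class CoverageCategory:
    fragment_id: str
    percent: float
    bin: str
    identity: float
    false_positive: bool


# ---------------------------------------------------------------------------
# operations


def select_analyzable_contigs(called_fragments, fragments) -> list[str]:
    """Contigs suitable for sequence-level CNV confirmation.

    A contig qualifies when it carries >= 3 fragments and at least one called
    fragment whose immediate neighbours (in fragment order on the contig) are
    both uncalled, i.e. the CNV is internal and flanked by unaffected
    fragments.

    Parameters
    ----------
    called_fragments : set/iterable of fragment ids carrying a CNV call
        (one genotype's calls).
    fragments : DataFrame with columns fragment_id, contig, start.
    """
    called = set(called_fragments)
    out = []
    for contig, sub in fragments.groupby("contig", sort=False):
        ids = sub.sort_values("start")["fragment_id"].tolist()
        if len(ids) < 3:
            continue
        for i in range(1, len(ids) - 1):
            if ids[i] in called and ids[i - 1] not in called and ids[i + 1] not in called:
                out.append(contig)
                break
    return out


def alignment_identity_counts(aln: PairwiseAlignment) -> tuple[int, int, int]:
    """(matches, columns incl. internal gaps, aligned columns only)."""
    matches = 0
    aligned = 0
    for rs, re_, qs, qe in aln.blocks:
        for i in range(re_ - rs):
            if aln.ref_seq[rs + i] == aln.query_seq[qs + i]:
                matches += 1
        aligned += re_ - rs
    cols = aligned
    for (r0, r1, q0, q1), (r2, _, q2, _) in zip(aln.blocks, aln.blocks[1:]):
        cols += (r2 - r1) + (q2 - q1)
    return matches, cols, aligned


def _blocks_from_biopython(aln) -> list[tuple[int, int, int, int]]:
    tb, qb = aln.aligned
    return [
        (int(t0), int(t1), int(q0), int(q1))
        for (t0, t1), (q0, q1) in zip(tb.tolist(), qb.tolist())
    ]


def align_pair(
    ref_seq: str,
    query_seq: str,
    ref_id: str = "ref",
    query_id: str = "query",
    aligner: Align.PairwiseAligner | None = None,
) -> PairwiseAlignment:
    """Optimal local alignment of two sequences (affine gaps, Water-style).

    Deterministic: the aligner's first optimal path is taken.
    """
    if not ref_seq or not query_seq:
        raise ValueError("sequences must be non-empty")
    for seq, name in ((ref_seq, "ref"), (query_seq, "query")):
        if set(seq) - set("ACGTN"):
            raise ValueError(f"{name} sequence contains non-ACGTN symbols")
    if aligner is None:
        aligner = default_aligner()
    aln = aligner.align(ref_seq, query_seq)[0]
    return PairwiseAlignment(
        ref_id=ref_id,
        query_id=query_id,
        ref_seq=ref_seq,
        query_seq=query_seq,
        score=float(aln.score),
        blocks=_blocks_from_biopython(aln),
    )


def _kmer_set(seq: str, k: int) -> set[int]:
    try:
        codes = encode(seq)
    except ValueError:
        # tolerate N in query contigs: split on N
        parts = [p for p in seq.split("N") if len(p) >= k]
        out: set[int] = set()
        for p in parts:
            out |= set(canonical_kmer_codes(encode(p), k).tolist())
        return out
    return set(canonical_kmer_codes(codes, k).tolist())


def find_orthologs(
    ref_id: str,
    ref_seq: str,
    query_contigs: dict[str, str],
    min_identity: float = 95.0,
    prescreen_k: int = 16,
    min_score: float = 40.0,
    min_coverage: float = 0.5,
    overlap_tol: int = 25,
    aligner: Align.PairwiseAligner | None = None,
) -> OrthologMatch:
    """Best local-alignment hit per query contig, kept when gap-compressed
    identity > ``min_identity``, then chained along the reference
    best-identity-first.

    Besides the identity screen, a hit must cover the shorter of the two
    sequences: matched bases >= ``min_coverage`` * min(len(ref), len(query)).
    This rejects gappy chance chains, which can reach near-100% gap-compressed
    identity at low coverage. Query contigs sharing no ``prescreen_k``-mer
    with the reference are skipped without alignment. An empty match is
    returned (with a warning) when no query contig qualifies.
    """
    if aligner is None:
        aligner = default_aligner()
    ref_kmers = _kmer_set(ref_seq, prescreen_k)
    hits: list[OrthologHit] = []
    for qid, qseq in query_contigs.items():
        if len(qseq) < prescreen_k or not (_kmer_set(qseq, prescreen_k) & ref_kmers):
            continue
        best = None
        for orient, seq in ((1, qseq), (-1, revcomp(qseq))):
            aln = align_pair(ref_seq, seq, ref_id, qid, aligner=aligner)
            if best is None or aln.score > best[1].score:
                best = (orient, aln)
        orient, aln = best
        if aln.score < min_score or not aln.blocks:
            continue
        ident = aln.identity(count_gaps=False)
        if ident <= min_identity:
            continue
        matches, _cols, _aligned = alignment_identity_counts(aln)
        if matches < min_coverage * min(len(ref_seq), len(qseq)):
            continue
        rs, re_ = aln.ref_span
        hits.append(OrthologHit(qid, orient, rs, re_, ident, aln.score))

    # chain: accept best identity first, drop hits overlapping accepted span
    chained: list[OrthologHit] = []
    for hit in sorted(hits, key=lambda h: (-h.identity, -h.score, h.query_id)):
        ok = True
        for acc in chained:
            ov = min(hit.ref_end, acc.ref_end) - max(hit.ref_start, acc.ref_start)
            if ov > overlap_tol:
                ok = False
                break
        if ok:
            chained.append(hit)
    chained.sort(key=lambda h: h.ref_start)
    if not chained:
        warnings.warn(f"no orthologous sequence found for {ref_id}", stacklevel=2)
    return OrthologMatch(ref_id=ref_id, hits=chained)


def build_supercontig(
    match: OrthologMatch, query_contigs: dict[str, str], spacer_len: int = SPACER_LEN
) -> Supercontig:
    """Concatenate matched query contigs, oriented, in reference order,
    joined by an 'N' spacer."""
    if not match.hits:
        raise ValueError(f"empty ortholog match for {match.ref_id}")
    parts: list[SupercontigPart] = []
    chunks: list[str] = []
    offset = 0
    for i, hit in enumerate(match.hits):
        seq = query_contigs[hit.query_id]
        if hit.orientation == -1:
            seq = revcomp(seq)
        if i > 0:
            chunks.append("N" * spacer_len)
            offset += spacer_len
        parts.append(SupercontigPart(hit.query_id, hit.orientation, offset, len(seq)))
        chunks.append(seq)
        offset += len(seq)
    return Supercontig(sequence="".join(chunks), parts=parts)


def _left_normalize(
    ref: str, query: str, rs: int, re_: int, qs: int, qe: int, side: str
) -> tuple[int, int, int, int]:
    """Shift a pure gap run to its leftmost equivalent placement."""
    if side == "deletion":
        while rs > 0 and qs > 0 and ref[rs - 1] == ref[re_ - 1]:
            rs -= 1
            re_ -= 1
            qs -= 1
            qe -= 1
    elif side == "insertion":
        while qs > 0 and rs > 0 and query[qs - 1] == query[qe - 1]:
            qs -= 1
            qe -= 1
            rs -= 1
            re_ -= 1
    return rs, re_, qs, qe


def extract_indels(
    aln: PairwiseAlignment,
    min_flank: int = 20,
    flank: int = 60,
    merge_aligned_lt: int = 20,
) -> list[IndelRecord]:
    """Turn every gap run of an alignment into an IndelRecord.

    Adjacent gap runs separated by fewer than ``merge_aligned_lt`` aligned
    bases merge into one replacement record: the short aligned stretch is
    treated as junction noise rather than a real anchor, which is the typical
    shape of an SDSA filler junction (chance co-alignment of filler against
    the replaced sequence). Pure indels are left-normalized before flank
    extraction.
    """
    ref, query = aln.ref_seq, aln.query_seq
    raw: list[dict] = []
    for (r0, r1, q0, q1), (r2, r3, q2, q3) in zip(aln.blocks, aln.blocks[1:]):
        dr, dq = r2 - r1, q2 - q1
        if dr == 0 and dq == 0:
            continue
        raw.append({"rs": r1, "re": r2, "qs": q1, "qe": q2, "next_aligned": r3 - r2})

    # merge runs separated by short aligned stretches into replacements
    merged: list[dict] = []
    for ev in raw:
        if (
            merged
            and merged[-1]["next_aligned"] < merge_aligned_lt
            and (ev["rs"] - merged[-1]["re"]) < merge_aligned_lt
        ):
            prev = merged[-1]
            prev["re"] = ev["re"]
            prev["qe"] = ev["qe"]
            prev["next_aligned"] = ev["next_aligned"]
        else:
            merged.append(dict(ev))

    records: list[IndelRecord] = []
    for ev in merged:
        rs, re_, qs, qe = ev["rs"], ev["re"], ev["qs"], ev["qe"]
        dr, dq = re_ - rs, qe - qs
        if dr > 0 and dq > 0:
            side = "replacement"
        elif dr > 0:
            side = "deletion"
        elif dq > 0:
            side = "insertion"
        else:
            continue
        if side != "replacement":
            rs, re_, qs, qe = _left_normalize(ref, query, rs, re_, qs, qe, side)
        left = ref[max(0, rs - flank) : rs]
        right = ref[re_ : re_ + flank]
        records.append(
            IndelRecord(
                ref_contig=aln.ref_id,
                ref_start=rs,
                ref_end=re_,
                q_start=qs,
                q_end=qe,
                side=side,
                seq_ref=ref[rs:re_],
                seq_query=query[qs:qe],
                left_flank=left,
                right_flank=right,
                flank_truncated=len(left) < min_flank or len(right) < min_flank,
            )
        )
    return records


def coverage_bin(percent: float) -> str:
    """Map percent-present to the reporting bin (0 and 100 are exact)."""
    if percent <= 0.0:
        return "0"
    if percent >= 100.0:
        return "100"
    if percent < 25.0:
        return "0-24"
    if percent < 50.0:
        return "25-49"
    if percent < 75.0:
        return "50-74"
    return "75-99"


def fragment_coverage(
    aln: PairwiseAlignment,
    fragment_id: str,
    frag_start: int,
    frag_end: int,
    indels: list[IndelRecord] | None = None,
    min_identity: float = 95.0,
) -> CoverageCategory:
    """Fraction of a reference fragment aligned (non-gap) in the query.

    A fragment fully present (bin "100") at >= ``min_identity`` percent
    identity and containing no indel larger than 1 bp is flagged as a
    false-positive array call.
    """
    if frag_end <= frag_start:
        raise ValueError("empty fragment interval")
    if indels is None:
        indels = extract_indels(aln)
    covered = 0
    matches = 0
    for rs, re_, qs, qe in aln.blocks:
        lo, hi = max(rs, frag_start), min(re_, frag_end)
        if hi <= lo:
            continue
        covered += hi - lo
        for i in range(lo, hi):
            if aln.ref_seq[i] == aln.query_seq[qs + (i - rs)]:
                matches += 1
    length = frag_end - frag_start
    percent = 100.0 * covered / length
    ident = 100.0 * matches / covered if covered else 0.0
    bin_ = coverage_bin(percent)
    big_indel_inside = any(
        rec.size > 1
        and (
            (rec.ref_end > frag_start and rec.ref_start < frag_end)
            if rec.side != "insertion"
            else (frag_start < rec.ref_start < frag_end)
        )
        for rec in indels
    )
    fp = bin_ == "100" and ident >= min_identity and not big_indel_inside
    return CoverageCategory(fragment_id, percent, bin_, ident, fp)
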