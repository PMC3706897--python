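"""Breakpoint-signature classification of insertions/deletions.

Each indel from a pairwise genome alignment is assigned to one of four
double-strand-break repair / replication classes:

* ``slippage`` — template slippage: the whole 1-6 bp indel sequence is
  repeated perfectly in the immediately adjacent flank.
* ``SDSA`` — synthesis-dependent strand annealing: a replacement whose
  query-only segment ("filler") cannot be aligned to the local context.
* ``SSA`` — single-strand annealing: a 2-40 bp motif borders the breakpoint
  and is repeated at the other end inside the deleted region
  (breakpoint microhomology).
* ``unknown`` — none of the above.

Precedence is slippage > SDSA > SSA > unknown: the full-length adjacent
repeat is the most specific signature, the filler is categorical for
replacements, and microhomology is the residual homology signal. The four
classes partition the indel set.

A randomization null (`random_indel_null`) places indels of the observed
sizes at uniform random genome positions and records the microhomology class
counts {0, 1-2, >2 bp}; `signature_enrichment_test` turns observed counts
into add-one Monte-Carlo p-values against that null.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .orthologs import IndelRecord, make_aligner

MICROHOMOLOGY_CLASSES = ("0", "1-2", ">2")

# Filler detection uses unit match/mismatch scores with affine gaps: under
# this scoring, chance local alignment of a random segment against the local
# context explains well under half of its bases, while a segment copied from
# the context aligns fully. The EDNAFULL scoring used for genome alignment is
# unsuitable here — its cheap gap extension chains isolated matches and
# inflates the alignable fraction of genuinely random fillers.
_FILLER_ALIGNER = None


def _filler_aligner():
    global _FILLER_ALIGNER
    if _FILLER_ALIGNER is None:
        _FILLER_ALIGNER = make_aligner(match=1.0, mismatch=-1.0)
    return _FILLER_ALIGNER


@dataclass(frozen=True)
class MechanismCall:
    indel: IndelRecord
    klass: str  # SSA | SDSA | slippage | unknown
    signature_length: int = 0
    filler_length: int = 0
    slippage_unit: str = ""


@dataclass
class NullDistribution:
    n_sim: int
    seed: int
    # per-simulation counts of microhomology classes, shape (n_sim, 3)
    class_counts: np.ndarray
    # aggregate histogram over microhomology length (index = length)
    mh_histogram: np.ndarray = field(default=None)

    @property
    def class_means(self) -> dict[str, float]:
        m = self.class_counts.mean(axis=0)
        return dict(zip(MICROHOMOLOGY_CLASSES, m))


def microhomology_length(
    deleted_seq: str, left_flank: str, right_flank: str, max_len: int = 40
) -> int:
    """Longest motif bordering the breakpoint and repeated at the other end
    inside the deleted region; the maximum over the two junction directions,
    capped at ``max_len``.

    k_left = longest common prefix of the deleted sequence and the right
    flank; k_right = longest common suffix of the deleted sequence and the
    left flank.
    """
    if not deleted_seq:
        raise ValueError("deleted sequence must be non-empty")
    limit = min(max_len, len(deleted_seq))
    k_left = 0
    for i in range(min(limit, len(right_flank))):
        if deleted_seq[i] != right_flank[i]:
            break
        k_left += 1
    k_right = 0
    for i in range(min(limit, len(left_flank))):
        if deleted_seq[-1 - i] != left_flank[-1 - i]:
            break
        k_right += 1
    return min(max(k_left, k_right), max_len)


def detect_template_slippage(
    record: IndelRecord, min_size: int = 1, max_size: int = 6
) -> tuple[bool, str]:
    """True when the complete 1-6 bp indel sequence is repeated perfectly in
    the immediately adjacent flanking window (either side)."""
    if record.is_replacement:
        return False, ""
    seq = record.indel_seq
    n = len(seq)
    if not (min_size <= n <= max_size):
        return False, ""
    if record.left_flank[-n:] == seq or record.right_flank[:n] == seq:
        return True, seq
    return False, ""


def detect_filler(
    record: IndelRecord,
    min_filler: int = 5,
    max_identity: float = 60.0,
    aligner=None,
) -> tuple[bool, int]:
    """Filler detection for replacement records.

    The query-only segment counts as filler when it is at least ``min_filler``
    bp long and its best local alignment against the local context (deleted
    reference segment plus both flanks) explains at most ``max_identity``
    percent of its bases — i.e. the inserted stretch cannot be aligned to
    anything nearby.
    """
    if not record.is_replacement:
        return False, 0
    filler = record.seq_query
    if len(filler) < min_filler:
        return False, 0
    context = record.left_flank + record.seq_ref + record.right_flank
    if not context:
        return True, len(filler)
    if aligner is None:
        aligner = _filler_aligner()
    aln = aligner.align(context, filler)
    matches = 0
    if len(aln) and aln[0].score > 0:
        tb, qb = aln[0].aligned
        for (t0, t1), (q0, q1) in zip(tb.tolist(), qb.tolist()):
            for i in range(int(t1) - int(t0)):
                if context[int(t0) + i] == filler[int(q0) + i]:
                    matches += 1
    identity = 100.0 * matches / len(filler)
    return identity <= max_identity, len(filler)


def classify_mechanism(
    record: IndelRecord,
    min_micro: int = 2,
    max_micro: int = 40,
    min_filler: int = 5,
    max_identity: float = 60.0,
) -> MechanismCall:
    """Assign exactly one mechanism class to an indel (pure function)."""
    is_slip, unit = detect_template_slippage(record)
    if is_slip:
        return MechanismCall(record, "slippage", signature_length=len(unit), slippage_unit=unit)
    has_filler, flen = detect_filler(record, min_filler=min_filler, max_identity=max_identity)
    if has_filler:
        return MechanismCall(record, "SDSA", filler_length=flen)
    mh = microhomology_length(record.indel_seq, record.left_flank, record.right_flank, max_micro)
    if min_micro <= mh <= max_micro:
        return MechanismCall(record, "SSA", signature_length=mh)
    return MechanismCall(record, "unknown", signature_length=mh)


def classify_all(records: list[IndelRecord], **kwargs) -> list[MechanismCall]:
    return [classify_mechanism(r, **kwargs) for r in records]


def class_proportions(calls: list[MechanismCall]) -> dict[str, float]:
    n = len(calls)
    counts = Counter(c.klass for c in calls)
    return {k: counts.get(k, 0) / n for k in ("SSA", "SDSA", "slippage", "unknown")}


def _mh_class_index(mh: int) -> int:
    if mh == 0:
        return 0
    if mh <= 2:
        return 1
    return 2


def microhomology_class_counts(records: list[IndelRecord], max_len: int = 40) -> dict[str, int]:
    """Observed {0, 1-2, >2} bp microhomology class counts of an indel set."""
    counts = [0, 0, 0]
    for rec in records:
        mh = microhomology_length(rec.indel_seq, rec.left_flank, rec.right_flank, max_len)
        counts[_mh_class_index(mh)] += 1
    return dict(zip(MICROHOMOLOGY_CLASSES, counts))


def random_indel_null(
    sequences,
    sizes,
    n_sim: int,
    seed: int,
    max_len: int = 40,
) -> NullDistribution:
    """Microhomology class counts of randomly placed indels.

    For each of ``n_sim`` simulations, one deletion per observed size is
    placed at a uniformly random position (contigs weighted by eligible
    length) and its breakpoint microhomology computed.

    ``sequences`` may be a dict of contig sequences, a list of sequences, or a
    ReferenceGenome-like object with a ``contigs`` mapping.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if hasattr(sequences, "contigs"):
        seqs = list(sequences.contigs.values())
    elif isinstance(sequences, dict):
        seqs = list(sequences.values())
    else:
        seqs = list(sequences)
    sizes = [int(s) for s in sizes]
    max_size = max(sizes)
    if max_size >= max(len(s) for s in seqs):
        raise ValueError("an observed size exceeds every contig length")
    rng = np.random.default_rng(seed)

    # pre-compute eligible placement ranges and weights per distinct size
    lens = np.array([len(s) for s in seqs])
    placements: dict[int, np.ndarray] = {}
    for size in set(sizes):
        room = np.clip(lens - size - 2 * max_len, 0, None)
        if room.sum() == 0:
            raise ValueError(f"size {size} does not fit any contig")
        placements[size] = np.cumsum(room / room.sum())

    counts = np.zeros((n_sim, 3), dtype=np.int64)
    hist = np.zeros(max_len + 1, dtype=np.int64)
    for sim in range(n_sim):
        picks = rng.random(len(sizes))
        for j, size in enumerate(sizes):
            ci = int(np.searchsorted(placements[size], picks[j]))
            seq = seqs[ci]
            start = int(rng.integers(max_len, len(seq) - size - max_len))
            end = start + size
            # junction microhomology computed in place (no slicing)
            limit = min(max_len, size)
            k_left = 0
            while k_left < limit and seq[start + k_left] == seq[end + k_left]:
                k_left += 1
            k_right = 0
            while k_right < limit and seq[end - 1 - k_right] == seq[start - 1 - k_right]:
                k_right += 1
            mh = min(max(k_left, k_right), max_len)
            counts[sim, _mh_class_index(mh)] += 1
            hist[mh] += 1
    return NullDistribution(n_sim=n_sim, seed=seed, class_counts=counts, mh_histogram=hist)


def signature_enrichment_test(
    observed: dict[str, int], null: NullDistribution
) -> dict[str, dict]:
    """Add-one Monte-Carlo p-values per microhomology class.

    For ">2" the alternative is over-representation (upper tail); for "0" and
    "1-2" it is under-representation (lower tail).
    """
    if set(observed) != set(MICROHOMOLOGY_CLASSES):
        raise ValueError(f"observed counts must have classes {MICROHOMOLOGY_CLASSES}")
    out = {}
    for j, klass in enumerate(MICROHOMOLOGY_CLASSES):
        obs = observed[klass]
        sims = null.class_counts[:, j]
        if klass == ">2":
            extreme = int((sims >= obs).sum())
            direction = "over"
        else:
            extreme = int((sims <= obs).sum())
            direction = "under"
        p = (1 + extreme) / (1 + null.n_sim)
        out[klass] = {
            "observed": int(obs),
            "null_mean": float(sims.mean()),
            "direction": direction,
            "p_value": float(p),
        }
    return out
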