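"""Array probe design: candidate probes, repeat masking, uniqueness, fragments.

The design procedure mirrors long-oligo CGH array construction for a large
repeat-rich genome:

1. variable-length candidate probes (56-100-mers) on a 10 bp start grid, with
   per-start length chosen as the shortest grid length whose GC-based melting
   proxy reaches a target;
2. repeat masking: drop probes whose average genome-wide 15-mer frequency
   exceeds 25 (strict inequality);
3. uniqueness: drop probes with any exact secondary match of >= 30 bp
   elsewhere in the genome (either strand);
4. fragment assembly: greedy left-to-right grouping of 10 surviving probes
   clustered within 200 bp, adjacent fragments separated by >= 500 bp.

Probes and fragments are plain DataFrames (columns documented on each
function); coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sequtils import canonical_kmer_codes, encode, kmer_codes, revcomp

PROBE_COLUMNS = ["probe_id", "contig", "start", "length", "sequence"]
FRAGMENT_COLUMNS = ["fragment_id", "contig", "start", "end", "probe_ids"]

LENGTH_GRID_STEP = 10


@dataclass
class KmerTable:
    """Genome-wide k-mer occurrence counts, packed as sorted code/count arrays.

    With ``canonical=True`` (default) a k-mer and its reverse complement share
    one bucket — repeat masking is strand-agnostic because hybridization is
    double-stranded.
    """

    k: int
    canonical: bool
    codes: np.ndarray
    counts: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def lookup_codes(self, query: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.codes, query)
        idx = np.clip(idx, 0, len(self.codes) - 1)
        out = self.counts[idx].copy()
        out[self.codes[idx] != query] = 0
        return out

    def count(self, kmer: str) -> int:
        codes = encode(kmer)
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer")
        fn = canonical_kmer_codes if self.canonical else kmer_codes
        return int(self.lookup_codes(fn(codes, self.k))[0])


def _contig_seqs(genome) -> dict[str, str]:
    if hasattr(genome, "contigs"):
        return genome.contigs
    return dict(genome)


def build_kmer_table(genome, k: int = 15, canonical: bool = True) -> KmerTable:
    """Count every k-mer window of the genome (forward strand windows; with
    ``canonical`` the bucket key is min(k-mer, revcomp))."""
    if k < 1:
        raise ValueError("k must be >= 1")
    chunks = []
    for cid, seq in _contig_seqs(genome).items():
        if len(seq) < k:
            warnings.warn(f"contig {cid} shorter than k={k}; skipped", stacklevel=2)
            continue
        codes = encode(seq)
        fn = canonical_kmer_codes if canonical else kmer_codes
        chunks.append(fn(codes, k))
    if not chunks:
        raise ValueError("no contig long enough for the k-mer table")
    allcodes = np.concatenate(chunks)
    uniq, counts = np.unique(allcodes, return_counts=True)
    return KmerTable(k=k, canonical=canonical, codes=uniq, counts=counts)


def tm_proxy(gc_count: int, length: int) -> float:
    """GC-fraction melting proxy for an oligo (Wallace-type rule)."""
    return 64.9 + 41.0 * (gc_count - 16.4) / length


def length_grid(min_len: int = 56, max_len: int = 100, step: int = LENGTH_GRID_STEP):
    grid = list(range(min_len, max_len + 1, step))
    if grid[-1] != max_len:
        grid.append(max_len)
    return grid


def generate_candidate_probes(
    contig_id: str,
    sequence: str,
    min_len: int = 56,
    max_len: int = 100,
    step: int = 10,
    tm_target: float = 76.0,
) -> pd.DataFrame:
    """One candidate probe per 10 bp grid start.

    The per-start length is the smallest grid length {56, 66, ..., 96, 100}
    whose melting proxy reaches ``tm_target``; if none does (AT-rich
    sequence) the longest length that fits is used. Returns an empty frame
    for contigs shorter than ``min_len``.
    """
    L = len(sequence)
    if L < min_len:
        return pd.DataFrame(columns=PROBE_COLUMNS)
    codes = encode(sequence)
    is_gc = ((codes == 1) | (codes == 2)).astype(np.int64)
    gc_csum = np.concatenate([[0], np.cumsum(is_gc)])
    starts = np.arange(0, L - min_len + 1, step)
    chosen = np.zeros(len(starts), dtype=np.int64)
    for gl in length_grid(min_len, max_len, step):
        fits = starts + gl <= L
        gc = gc_csum[np.clip(starts + gl, 0, L)] - gc_csum[starts]
        ok = fits & (64.9 + 41.0 * (gc - 16.4) / gl >= tm_target) & (chosen == 0)
        chosen[ok] = gl
    # no length reached the target: fall back to the longest that fits
    for gl in reversed(length_grid(min_len, max_len, step)):
        unset = (chosen == 0) & (starts + gl <= L)
        chosen[unset] = gl
    rows = {
        "probe_id": [f"{contig_id}:{s}" for s in starts],
        "contig": contig_id,
        "start": starts,
        "length": chosen,
        "sequence": [sequence[s : s + l] for s, l in zip(starts, chosen)],
    }
    return pd.DataFrame(rows, columns=PROBE_COLUMNS)


def generate_all_candidates(genome, **kwargs) -> pd.DataFrame:
    frames = [
        generate_candidate_probes(cid, seq, **kwargs)
        for cid, seq in _contig_seqs(genome).items()
    ]
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(columns=PROBE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def probe_mean_kmer_freq(
    probes: pd.DataFrame, table: KmerTable, genome=None
) -> np.ndarray:
    """Mean k-mer table count over each probe's (length - k + 1) windows."""
    k = table.k
    if (probes["length"] < k).any():
        raise ValueError(f"probes shorter than k={k}")
    fn = canonical_kmer_codes if table.canonical else kmer_codes
    out = np.empty(len(probes))
    if genome is not None:
        seqs = _contig_seqs(genome)
        csums: dict[str, np.ndarray] = {}
        for cid in probes["contig"].unique():
            counts = table.lookup_codes(fn(encode(seqs[cid]), k)).astype(np.float64)
            csums[cid] = np.concatenate([[0.0], np.cumsum(counts)])
        for i, row in enumerate(probes.itertuples(index=False)):
            cs = csums[row.contig]
            nwin = row.length - k + 1
            out[i] = (cs[row.start + nwin] - cs[row.start]) / nwin
    else:
        for i, seq in enumerate(probes["sequence"]):
            out[i] = table.lookup_codes(fn(encode(seq), k)).mean()
    return out


def mask_repetitive_probes(
    probes: pd.DataFrame, table: KmerTable, max_avg_freq: float = 25.0, genome=None
) -> pd.DataFrame:
    """Drop probes whose average k-mer frequency exceeds ``max_avg_freq``
    (strict: a mean of exactly 25.0 is retained)."""
    mean_freq = probe_mean_kmer_freq(probes, table, genome=genome)
    return probes.loc[mean_freq <= max_avg_freq].reset_index(drop=True)


# ---------------------------------------------------------------------------
# uniqueness


def uniqueness_filter(
    probes: pd.DataFrame,
    genome,
    min_match: int = 30,
    max_gaps: int = 5,
) -> pd.DataFrame:
    """Keep probes whose only exact >= ``min_match``-bp genomic match is their
    source site.

    This realizes the repeat screen of a seeded genome aligner with a minimum
    match size of ``min_match``: a probe is eliminated when any of its
    ``min_match``-length substrings occurs elsewhere in the genome, on either
    strand. ``max_gaps`` documents the gap allowance of the emulated aligner
    when joining neighbouring seed matches into one secondary site; it does
    not change the keep/drop decision, because every gap-joined secondary
    alignment already contains a qualifying exact seed.
    """
    seqs = _contig_seqs(genome)
    k = min_match
    per_contig_keys: dict[str, list] = {}
    if 2 * k <= 62:  # packable into int64 codes (fast path)
        for cid, seq in seqs.items():
            if len(seq) >= k:
                per_contig_keys[cid] = canonical_kmer_codes(encode(seq), k).tolist()
    else:
        for cid, seq in seqs.items():
            keys = []
            for i in range(len(seq) - k + 1):
                sub = seq[i : i + k]
                rc = revcomp(sub)
                keys.append(sub if sub <= rc else rc)
            if keys:
                per_contig_keys[cid] = keys
    if not per_contig_keys:
        raise ValueError("genome shorter than min_match everywhere")
    from collections import Counter

    tally = Counter()
    for keys in per_contig_keys.values():
        tally.update(keys)
    dup_positions: dict = {}
    for cid, keys in per_contig_keys.items():
        for pos, key in enumerate(keys):
            if tally[key] >= 2:
                dup_positions.setdefault(key, []).append((cid, pos))

    keep = []
    for row in probes.itertuples(index=False):
        if seqs[row.contig][row.start : row.start + row.length] != row.sequence:
            raise ValueError(
                f"probe {row.probe_id} does not match the genome at its source site"
            )
        keys = per_contig_keys[row.contig][
            row.start : row.start + row.length - k + 1
        ]
        secondary = False
        for off, key in enumerate(keys):
            for cid, pos in dup_positions.get(key, ()):
                if cid != row.contig or pos != row.start + off:
                    secondary = True
                    break
            if secondary:
                break
        keep.append(not secondary)
    return probes.loc[keep].reset_index(drop=True)


# ---------------------------------------------------------------------------
# fragment assembly


def assemble_fragments(
    probes: pd.DataFrame,
    span: int = 200,
    per_fragment: int = 10,
    min_gap: int = 500,
) -> pd.DataFrame:
    """Greedy left-to-right assembly of probe clusters into contig fragments.

    The first window of <= ``span`` bp (anchored at a surviving probe start)
    that fully contains >= ``per_fragment`` probes yields a fragment made of
    the first ``per_fragment`` probes by start (ties by length, then id); the
    next search resumes ``min_gap`` bp after the fragment end.
    """
    rows = []
    frag_idx = 0
    for contig, sub in probes.groupby("contig", sort=False):
        sub = sub.sort_values(["start", "length", "probe_id"]).reset_index(drop=True)
        starts = sub["start"].to_numpy()
        ends = (sub["start"] + sub["length"]).to_numpy()
        n = len(sub)
        a = 0
        cursor = 0
        while a < n:
            if starts[a] < cursor:
                a += 1
                continue
            win_lo = starts[a]
            win_hi = win_lo + span
            members = [
                j for j in range(a, n) if starts[j] < win_hi and ends[j] <= win_hi
            ]
            if len(members) >= per_fragment:
                chosen = members[:per_fragment]
                fs = int(starts[chosen[0]])
                fe = int(max(ends[j] for j in chosen))
                frag_idx += 1
                rows.append(
                    {
                        "fragment_id": f"{contig}_frag{frag_idx:05d}",
                        "contig": contig,
                        "start": fs,
                        "end": fe,
                        "probe_ids": [sub["probe_id"].iloc[j] for j in chosen],
                    }
                )
                # resume after the full span window so adjacent regions are
                # separated by >= min_gap even when probes end early
                cursor = max(fe, win_lo + span) + min_gap
            else:
                a += 1
    return pd.DataFrame(rows, columns=FRAGMENT_COLUMNS)


# ---------------------------------------------------------------------------
# whole-design convenience


@dataclass
class DesignResult:
    probes: pd.DataFrame  # surviving probes (members of fragments)
    fragments: pd.DataFrame
    kmer_table: KmerTable
    summary: dict


def design_probes(
    genome,
    k: int = 15,
    max_avg_freq: float = 25.0,
    min_match: int = 30,
    max_gaps: int = 5,
    tm_target: float = 76.0,
    min_len: int = 56,
    max_len: int = 100,
    step: int = 10,
    span: int = 200,
    per_fragment: int = 10,
    min_gap: int = 500,
) -> DesignResult:
    """Run the full design: candidates -> masking -> uniqueness -> fragments."""
    table = build_kmer_table(genome, k=k)
    candidates = generate_all_candidates(
        genome, min_len=min_len, max_len=max_len, step=step, tm_target=tm_target
    )
    masked = mask_repetitive_probes(candidates, table, max_avg_freq, genome=genome)
    unique = uniqueness_filter(masked, genome, min_match=min_match, max_gaps=max_gaps)
    fragments = assemble_fragments(unique, span=span, per_fragment=per_fragment, min_gap=min_gap)
    member_ids = {pid for ids in fragments["probe_ids"] for pid in ids}
    probes = unique[unique["probe_id"].isin(member_ids)].reset_index(drop=True)
    summary = {
        "candidates": int(len(candidates)),
        "after_masking": int(len(masked)),
        "after_uniqueness": int(len(unique)),
        "fragments": int(len(fragments)),
        "probes_on_array": int(len(probes)),
    }
    return DesignResult(probes=probes, fragments=fragments, kmer_table=table, summary=summary)


def fragment_positions(fragments: pd.DataFrame, reference) -> pd.DataFrame:
    """Fragment table annotated with chromosome and genome-wide physical
    coordinates (from the reference's contig metadata)."""
    out = fragments.copy()
    chroms, phys = [], []
    for row in fragments.itertuples(index=False):
        chrom, gpos = reference.global_position(row.contig, row.start)
        chroms.append(chrom)
        phys.append(gpos)
    out["chromosome"] = chroms
    out["phys_start"] = phys
    out["phys_end"] = out["phys_start"] + (out["end"] - out["start"])
    return out
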