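"""Synthetic genomes, structural variants and simulated hybridizations.

This module makes every downstream stage testable without external data. It
emulates the study design of a two-channel CGH survey of an inbred plant
panel against a single reference genotype:

* `generate_reference` — a multi-contig reference genome with interspersed
  repeat families, chromosome assignments and a (optionally telomere-
  enriched) genetic map.
* `spike_variants` — derive genotype genomes carrying deletions,
  duplications, insertions and replacements whose breakpoints carry
  mechanism-diagnostic signatures (SSA border motifs, SDSA filler, template-
  slippage adjacent repeats) or, for "none"-tagged variants, verifiably carry
  no signature (rejection sampling).
* `simulate_hybridization` — per-probe two-channel intensities whose expected
  log2(sample/reference) ratio follows copy number, with breakpoint-
  interrupted probes dropping to background under a stringent-wash duplex
  model.
* `generate_population` — a wild + cultivated panel with configurable
  per-group variant rates and sharing spectrum.

All randomness flows through a single integer seed; identical seeds and
configurations give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .mechanisms import (
    classify_mechanism,
    detect_filler,
    detect_template_slippage,
    microhomology_length,
)
from .orthologs import IndelRecord
from .sequtils import BASES, random_dna

TRUTH_COLUMNS = [
    "genotype",
    "contig",
    "ref_start",
    "ref_end",
    "query_start",
    "query_end",
    "type",
    "size",
    "mechanism",
    "alt_seq",
    "motif_len",
]

PAPER_MECHANISM_MIX = {"SSA": 0.411, "SDSA": 0.127, "slippage": 0.157, "none": 0.304}

CHROMOSOMES = ("1H", "2H", "3H", "4H", "5H", "6H", "7H")


class SpikeError(ValueError):
    """Raised for conflicting or impossible variant specifications."""


# ---------------------------------------------------------------------------
# reference genome


@dataclass(frozen=True)
class RepeatFamily:
    motif: str
    copies: int


@dataclass(frozen=True)
class ContigMeta:
    chromosome: str
    phys_start: int


@dataclass
class GenomeConfig:
    n_contigs: int = 14
    contig_length: int = 10_000
    contig_lengths: tuple[int, ...] | None = None
    gc: float = 0.44
    chromosomes: tuple[str, ...] = CHROMOSOMES
    repeat_families: tuple[RepeatFamily, ...] = ()
    telomere_enriched: bool = True
    contig_spacing: int = 2_000
    map_points_per_chromosome: int = 21
    total_cm_per_chromosome: float = 150.0


@dataclass
class ReferenceGenome:
    contigs: dict[str, str]
    meta: dict[str, ContigMeta]
    genetic_map: pd.DataFrame  # columns: chromosome, bp, cM
    repeat_families: tuple[RepeatFamily, ...] = ()

    @property
    def contig_order(self) -> list[str]:
        return list(self.contigs)

    def chromosome_length(self, chromosome: str) -> int:
        ends = [
            m.phys_start + len(self.contigs[cid])
            for cid, m in self.meta.items()
            if m.chromosome == chromosome
        ]
        if not ends:
            raise KeyError(f"no contigs on chromosome {chromosome}")
        return max(ends)

    def global_position(self, contig: str, pos: int) -> tuple[str, int]:
        m = self.meta[contig]
        return m.chromosome, m.phys_start + pos

    def copy(self) -> "ReferenceGenome":
        return ReferenceGenome(
            contigs=dict(self.contigs),
            meta=dict(self.meta),
            genetic_map=self.genetic_map.copy(),
            repeat_families=self.repeat_families,
        )

    def to_fasta(self, path) -> None:
        from .io import write_fasta

        write_fasta(self.contigs, path)


def _telomere_density(x: np.ndarray) -> np.ndarray:
    # x in [0, 1] along the chromosome; high near both ends
    return 0.1 + 2.9 * (2.0 * np.abs(x - 0.5)) ** 3


def build_genetic_map(
    chrom_lengths: dict[str, int],
    telomere_enriched: bool = True,
    points_per_chromosome: int = 21,
    total_cm: float = 150.0,
) -> pd.DataFrame:
    """Per-chromosome monotone cM positions at evenly spaced physical points."""
    rows = []
    for chrom, L in chrom_lengths.items():
        bp = np.linspace(0, L, points_per_chromosome).round().astype(int)
        mids = (bp[:-1] + bp[1:]) / 2 / L
        dens = _telomere_density(mids) if telomere_enriched else np.ones(len(mids))
        inc = dens * np.diff(bp)
        cm = np.concatenate([[0.0], np.cumsum(inc)])
        cm = cm / cm[-1] * total_cm
        for b, c in zip(bp, cm):
            rows.append({"chromosome": chrom, "bp": int(b), "cM": float(c)})
    return pd.DataFrame(rows)


def generate_reference(config: GenomeConfig, seed: int) -> ReferenceGenome:
    """Deterministic synthetic reference genome.

    Repeat families are embedded at exactly the requested copy numbers
    (non-overlapping placements, motifs overwrite the background sequence).
    """
    lengths = list(config.contig_lengths or [config.contig_length] * config.n_contigs)
    if any(l <= 0 for l in lengths):
        raise ValueError("contig lengths must be positive")
    if any(l < 1000 for l in lengths):
        raise ValueError("contig lengths must be >= 1 kb")
    for fam in config.repeat_families:
        if set(fam.motif) - set("ACGT"):
            raise ValueError("repeat motif must be over ACGT")
        if len(fam.motif) > max(lengths):
            raise ValueError("repeat motif longer than every contig")
        if fam.copies < 0:
            raise ValueError("repeat copy count must be >= 0")

    rng = np.random.default_rng(seed)
    contigs: dict[str, str] = {}
    meta: dict[str, ContigMeta] = {}
    chrom_cursor = {c: 0 for c in config.chromosomes}
    seqs: dict[str, bytearray] = {}
    for i, L in enumerate(lengths):
        cid = f"contig_{i + 1:05d}"
        chrom = config.chromosomes[i % len(config.chromosomes)]
        meta[cid] = ContigMeta(chromosome=chrom, phys_start=chrom_cursor[chrom])
        chrom_cursor[chrom] += L + config.contig_spacing
        seqs[cid] = bytearray(random_dna(rng, L, gc=config.gc), "ascii")

    # embed repeat families at exact copy numbers, non-overlapping
    occupied: dict[str, list[tuple[int, int]]] = {cid: [] for cid in seqs}
    ids = list(seqs)
    lens = np.array([len(seqs[c]) for c in ids], dtype=float)
    for fam in config.repeat_families:
        m = len(fam.motif)
        for _ in range(fam.copies):
            for _try in range(1000):
                ci = ids[int(rng.choice(len(ids), p=lens / lens.sum()))]
                L = len(seqs[ci])
                if L < m:
                    continue
                s = int(rng.integers(0, L - m + 1))
                if all(s + m <= a or s >= b for a, b in occupied[ci]):
                    seqs[ci][s : s + m] = fam.motif.encode("ascii")
                    occupied[ci].append((s, s + m))
                    break
            else:
                raise ValueError("could not place all repeat copies without overlap")

    contigs = {cid: seqs[cid].decode("ascii") for cid in ids}
    chrom_lengths = {}
    for chrom in config.chromosomes:
        ends = [
            meta[cid].phys_start + len(contigs[cid])
            for cid in ids
            if meta[cid].chromosome == chrom
        ]
        if ends:
            chrom_lengths[chrom] = max(ends)
    gmap = build_genetic_map(
        chrom_lengths,
        telomere_enriched=config.telomere_enriched,
        points_per_chromosome=config.map_points_per_chromosome,
        total_cm=config.total_cm_per_chromosome,
    )
    return ReferenceGenome(
        contigs=contigs, meta=meta, genetic_map=gmap, repeat_families=tuple(config.repeat_families)
    )


# ---------------------------------------------------------------------------
# variant specification and spiking


@dataclass(frozen=True)
class VariantSpec:
    kind: str  # deletion | duplication | insertion | replacement
    size: int
    contig: str
    position: int
    mechanism: str = "none"  # SSA | SDSA | slippage | none
    genotypes: tuple[str, ...] = ("genotype_1",)
    motif_len: int | None = None  # SSA border motif length
    filler_len: int | None = None  # SDSA inserted (query-only) length

    def validate(self) -> None:
        if self.kind not in ("deletion", "duplication", "insertion", "replacement"):
            raise SpikeError(f"unknown variant kind {self.kind!r}")
        if self.mechanism not in ("SSA", "SDSA", "slippage", "none"):
            raise SpikeError(f"unknown mechanism {self.mechanism!r}")
        if self.size < 1:
            raise SpikeError("variant size must be >= 1")
        if self.position < 0:
            raise SpikeError("position must be >= 0")
        if not self.genotypes:
            raise SpikeError("variant must be assigned to at least one genotype")
        if self.mechanism == "slippage":
            if self.kind not in ("deletion", "insertion"):
                raise SpikeError("slippage variants must be deletions or insertions")
            if not 1 <= self.size <= 6:
                raise SpikeError("slippage variants must have size in [1, 6]")
        if self.mechanism == "SSA":
            if self.kind != "deletion":
                raise SpikeError("SSA variants must be deletions")
            if self.motif_len is None or not 2 <= self.motif_len <= 40:
                raise SpikeError("SSA motif length must be in [2, 40]")
            if self.motif_len >= self.size:
                raise SpikeError("SSA motif must be shorter than the deletion")
        if self.mechanism == "SDSA":
            if self.kind != "replacement":
                raise SpikeError("SDSA variants must be replacements")
            if self.filler_len is None or self.filler_len < 1:
                raise SpikeError("SDSA replacements need filler_len >= 1")
        if self.kind == "replacement" and self.mechanism != "SDSA":
            raise SpikeError("replacements are SDSA (filler) variants")


@dataclass
class SpikeResult:
    """Derived genomes plus the signature-implanted reference and ground truth."""

    reference: ReferenceGenome
    genomes: dict[str, dict[str, str]]  # genotype -> contig -> sequence
    truth: pd.DataFrame  # TRUTH_COLUMNS


_HALO = 60  # flank reserved around each variant for signatures / detectors


def _footprint(spec: VariantSpec) -> tuple[int, int]:
    extra = 0
    if spec.mechanism == "SSA":
        extra = spec.motif_len + 1
    elif spec.mechanism == "slippage" and spec.kind == "deletion":
        extra = spec.size
    if spec.kind == "insertion":
        return spec.position - spec.size - _HALO, spec.position + _HALO
    return spec.position - _HALO, spec.position + spec.size + extra + _HALO


def _other_base(rng: np.random.Generator, *avoid: str) -> str:
    choices = [b for b in BASES if b not in avoid]
    return choices[int(rng.integers(0, len(choices)))]


def _record_for(
    seq: str, spec: VariantSpec, alt_seq: str = "", flank: int = _HALO
) -> IndelRecord:
    p, n = spec.position, spec.size
    lf = seq[max(0, p - flank) : p]
    if spec.kind == "deletion":
        return IndelRecord(
            spec.contig, p, p + n, p, p, "deletion", seq[p : p + n], "", lf,
            seq[p + n : p + n + flank],
        )
    if spec.kind == "insertion":
        return IndelRecord(
            spec.contig, p, p, p, p + len(alt_seq), "insertion", "", alt_seq,
            lf, seq[p : p + flank],
        )
    if spec.kind == "replacement":
        return IndelRecord(
            spec.contig, p, p + n, p, p + len(alt_seq), "replacement", seq[p : p + n], alt_seq,
            lf, seq[p + n : p + n + flank],
        )
    raise SpikeError(f"no indel record for kind {spec.kind!r}")


def _implant_signature(
    seq: bytearray, spec: VariantSpec, rng: np.random.Generator
) -> str:
    """Write the diagnostic signature for one spec into the reference sequence;
    returns the alt (inserted) sequence where the variant has one."""
    p, n = spec.position, spec.size
    text = lambda: seq.decode("ascii")  # noqa: E731

    if spec.mechanism == "SSA":
        m = spec.motif_len
        motif = random_dna(rng, m)
        seq[p : p + m] = motif.encode("ascii")
        seq[p + n : p + n + m] = motif.encode("ascii")
        # suppress right-junction homology so the detector returns exactly m
        if seq[p + n - 1] == seq[p - 1]:
            seq[p + n - 1] = ord(_other_base(rng, chr(seq[p - 1])))
        if seq[p + m] == seq[p + n + m]:
            seq[p + n + m] = ord(_other_base(rng, chr(seq[p + m])))
        return ""

    if spec.mechanism == "slippage":
        if spec.kind == "deletion":
            seq[p + n : p + 2 * n] = seq[p : p + n]
            return ""
        # insertion: duplicate the left-adjacent unit; no reference edit
        return seq[p - n : p].decode("ascii")

    if spec.mechanism == "SDSA":
        for _ in range(200):
            filler = random_dna(rng, spec.filler_len)
            rec = _record_for(text(), spec, alt_seq=filler)
            ok, _ = detect_filler(rec)
            if ok:
                return filler
        raise SpikeError("could not sample an unalignable SDSA filler")

    # mechanism "none": scrub any accidental signature at the breakpoint
    if spec.kind in ("deletion", "insertion"):
        alt = random_dna(rng, n) if spec.kind == "insertion" else ""
        for _ in range(200):
            rec = _record_for(text(), spec, alt_seq=alt)
            slip, _ = detect_template_slippage(rec)
            mh = microhomology_length(rec.indel_seq, rec.left_flank, rec.right_flank)
            if not slip and mh <= 1:
                return alt
            if spec.kind == "insertion":
                alt = random_dna(rng, n)
                continue
            # targeted mutations in the reference copy (within the halo)
            if slip:
                j = p + n // 2
                seq[j] = ord(_other_base(rng, chr(seq[j])))
            elif mh >= 2:
                # break both junction homologies
                seq[p + n] = ord(_other_base(rng, chr(seq[p]), chr(seq[p + n])))
                seq[p - 1] = ord(_other_base(rng, chr(seq[p + n - 1]), chr(seq[p - 1])))
        raise SpikeError("could not scrub signatures from a 'none' variant")
    return ""  # duplication: no signature


def spike_variants(
    reference: ReferenceGenome,
    specs: list[VariantSpec],
    seed: int,
    genotypes: list[str] | None = None,
) -> SpikeResult:
    """Derive genotype genomes carrying the specified variants.

    Diagnostic breakpoint signatures are implanted into a copy of the
    reference before edits are applied (detectors read the deleted segment and
    its reference flanks), so the returned ``reference`` — not the input one —
    is the coordinate frame for the truth table and all downstream stages.
    """
    rng = np.random.default_rng(seed)
    for spec in specs:
        spec.validate()
        if spec.contig not in reference.contigs:
            raise SpikeError(f"unknown contig {spec.contig!r}")
        L = len(reference.contigs[spec.contig])
        lo, hi = _footprint(spec)
        if lo < 0 or hi > L:
            raise SpikeError(
                f"variant at {spec.contig}:{spec.position} (size {spec.size}) too close "
                f"to a contig end (need {_HALO} bp of flank)"
            )

    # overlap check on footprints (shared reference frame)
    by_contig: dict[str, list[tuple[int, int, VariantSpec]]] = {}
    for spec in specs:
        lo, hi = _footprint(spec)
        for a, b, other in by_contig.get(spec.contig, []):
            # signatures live in the shared reference frame, so overlap is
            # forbidden regardless of genotype sharing
            if lo < b and a < hi:
                raise SpikeError(
                    f"variants at {spec.contig}:{spec.position} and "
                    f"{other.contig}:{other.position} overlap (incl. signature halo)"
                )
        by_contig.setdefault(spec.contig, []).append((lo, hi, spec))

    # implant signatures into a mutable copy of the reference
    ref = reference.copy()
    edited: dict[str, bytearray] = {}
    alt_seqs: dict[int, str] = {}
    for idx, spec in enumerate(sorted_specs := sorted(
        specs, key=lambda s: (s.contig, s.position)
    )):
        buf = edited.setdefault(spec.contig, bytearray(ref.contigs[spec.contig], "ascii"))
        alt_seqs[idx] = _implant_signature(buf, spec, rng)
    for cid, buf in edited.items():
        ref.contigs[cid] = buf.decode("ascii")

    all_genotypes = list(genotypes) if genotypes is not None else sorted(
        {g for s in specs for g in s.genotypes}
    )
    genomes: dict[str, dict[str, str]] = {}
    rows = []
    for genotype in all_genotypes:
        contigs = dict(ref.contigs)
        per_contig: dict[str, list[tuple[int, VariantSpec]]] = {}
        for idx, spec in enumerate(sorted_specs):
            if genotype in spec.genotypes:
                per_contig.setdefault(spec.contig, []).append((idx, spec))
        for cid, items in per_contig.items():
            seq = contigs[cid]
            parts = []
            cursor = 0
            offset = 0
            for idx, spec in items:  # already position-sorted
                p, n = spec.position, spec.size
                alt = alt_seqs[idx]
                if spec.kind == "deletion":
                    parts.append(seq[cursor:p])
                    q0 = p + offset
                    q1 = q0
                    cursor = p + n
                    offset -= n
                elif spec.kind == "insertion":
                    parts.append(seq[cursor:p])
                    parts.append(alt)
                    q0 = p + offset
                    q1 = q0 + len(alt)
                    cursor = p
                    offset += len(alt)
                elif spec.kind == "duplication":
                    parts.append(seq[cursor : p + n])
                    parts.append(seq[p : p + n])
                    q0 = p + offset
                    q1 = p + n + offset + n
                    cursor = p + n
                    offset += n
                elif spec.kind == "replacement":
                    parts.append(seq[cursor:p])
                    parts.append(alt)
                    q0 = p + offset
                    q1 = q0 + len(alt)
                    cursor = p + n
                    offset += len(alt) - n
                rows.append(
                    {
                        "genotype": genotype,
                        "contig": cid,
                        "ref_start": p,
                        "ref_end": p if spec.kind == "insertion" else p + n,
                        "query_start": q0,
                        "query_end": q1,
                        "type": spec.kind,
                        "size": n,
                        "mechanism": spec.mechanism,
                        "alt_seq": alt,
                        "motif_len": spec.motif_len if spec.motif_len is not None else 0,
                    }
                )
            parts.append(seq[cursor:])
            contigs[cid] = "".join(parts)
        genomes[genotype] = contigs

    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    return SpikeResult(reference=ref, genomes=genomes, truth=truth)


def truth_record(spike: SpikeResult, row, flank: int = _HALO) -> IndelRecord:
    """Build the IndelRecord for one truth-table row (deletion, insertion or
    replacement) directly from the reference coordinates."""
    seq = spike.reference.contigs[row["contig"]]
    spec = VariantSpec(
        kind=row["type"],
        size=int(row["size"]),
        contig=row["contig"],
        position=int(row["ref_start"]),
        mechanism=row["mechanism"],
        motif_len=int(row["motif_len"]) or None,
        filler_len=len(row["alt_seq"]) or None,
    )
    rec = _record_for(seq, spec, alt_seq=row["alt_seq"], flank=flank)
    return replace(rec, q_start=int(row["query_start"]), q_end=int(row["query_end"]))


def verify_signatures(spike: SpikeResult) -> pd.DataFrame:
    """Re-run the mechanism detectors at truth coordinates.

    Returns the truth table with a ``detected`` column; "none" maps to
    "unknown". Raises AssertionError-free — callers assert as needed.
    """
    detected = []
    for _, row in spike.truth.iterrows():
        if row["type"] == "duplication":
            detected.append("duplication")
            continue
        call = classify_mechanism(truth_record(spike, row))
        detected.append(call.klass)
    out = spike.truth.copy()
    out["detected"] = detected
    out["intended"] = out["mechanism"].replace({"none": "unknown"})
    return out


# ---------------------------------------------------------------------------
# hybridization simulation


@dataclass(frozen=True)
class NoiseModel:
    sigma_log2: float = 0.2  # per-probe log2-ratio noise
    additive: float = 0.0  # mean additive channel background
    multiplicative: float = 0.0  # sd of log-scale channel gain noise

    def validate(self) -> None:
        if self.sigma_log2 < 0 or self.additive < 0 or self.multiplicative < 0:
            raise ValueError("noise parameters must be non-negative")


def probe_copy_yield(
    probe_start: int,
    probe_end: int,
    variants: list[dict],
    duplex_frac_min: float = 0.9,
    loopout_bp: int = 21,
) -> float:
    """Effective copy number of a probe's target site in a derived genome.

    The probe's reference interval is cut by deletions/replacements and split
    at disruptive insertion breakpoints (insertions larger than ``loopout_bp``
    — smaller ones loop out of the duplex). The surviving site contributes a
    linear yield in its longest contiguous match fraction when that fraction
    is at least ``duplex_frac_min``; below this a stringent wash removes the
    probe's duplex and only background remains. Duplications add whole or
    near-whole extra copies.
    """
    L = probe_end - probe_start
    cuts: list[tuple[int, int]] = []
    points: list[int] = []
    extra = 0.0
    for v in variants:
        if v["type"] in ("deletion", "replacement"):
            lo, hi = max(probe_start, v["ref_start"]), min(probe_end, v["ref_end"])
            if hi > lo:
                cuts.append((lo, hi))
        elif v["type"] == "insertion":
            if v["size"] > loopout_bp and probe_start < v["ref_start"] < probe_end:
                points.append(v["ref_start"])
        elif v["type"] == "duplication":
            lo, hi = max(probe_start, v["ref_start"]), min(probe_end, v["ref_end"])
            if v["ref_start"] <= probe_start and v["ref_end"] >= probe_end:
                extra += 1.0
            elif hi > lo:
                f = (hi - lo) / L
                if f >= duplex_frac_min:
                    extra += f
    segments = [(probe_start, probe_end)]
    for lo, hi in sorted(cuts):
        nxt = []
        for a, b in segments:
            if hi <= a or lo >= b:
                nxt.append((a, b))
            else:
                if a < lo:
                    nxt.append((a, lo))
                if hi < b:
                    nxt.append((hi, b))
        segments = nxt
    for p in sorted(points):
        nxt = []
        for a, b in segments:
            if a < p < b:
                nxt.extend([(a, p), (p, b)])
            else:
                nxt.append((a, b))
        segments = nxt
    longest = max((b - a for a, b in segments), default=0)
    frac = longest / L
    site = frac if frac >= duplex_frac_min else 0.0
    return site + extra


def expected_probe_log2(
    probes: pd.DataFrame,
    truth: pd.DataFrame,
    genotype: str,
    eps: float = 0.01,
    duplex_frac_min: float = 0.9,
    loopout_bp: int = 21,
) -> np.ndarray:
    """Noise-free per-probe log2(sample/reference), aligned to ``probes`` rows."""
    sub = truth[truth["genotype"] == genotype]
    by_contig = {cid: g.to_dict("records") for cid, g in sub.groupby("contig")}
    out = np.zeros(len(probes))
    for i, row in enumerate(probes.itertuples(index=False)):
        variants = by_contig.get(row.contig, [])
        c = (
            probe_copy_yield(
                row.start, row.start + row.length, variants, duplex_frac_min, loopout_bp
            )
            if variants
            else 1.0
        )
        out[i] = math.log2((c + eps) / (1.0 + eps))
    return out


def simulate_hybridization(
    reference: ReferenceGenome,
    probes: pd.DataFrame,
    truth: pd.DataFrame,
    genotypes: list[str] | None = None,
    noise: NoiseModel | None = None,
    n_replicates: int = 2,
    seed: int = 0,
    eps: float = 0.01,
    duplex_frac_min: float = 0.9,
    loopout_bp: int = 21,
    base_intensity: float = 500.0,
    base_sigma: float = 0.6,
) -> pd.DataFrame:
    """Per-probe two-channel intensities for every genotype and replicate.

    Returns a tidy table (probe_id, genotype, replicate, ch_sample, ch_ref).
    With all noise parameters zero the channel ratio is exactly
    (c_eff + eps) / (1 + eps).
    """
    noise = noise or NoiseModel()
    noise.validate()
    for row in probes.itertuples(index=False):
        if row.contig not in reference.contigs:
            raise KeyError(f"probe {row.probe_id} references unknown contig {row.contig}")
        if row.start + row.length > len(reference.contigs[row.contig]):
            raise ValueError(f"probe {row.probe_id} extends past its contig")
    if genotypes is None:
        genotypes = sorted(truth["genotype"].unique())
    rng = np.random.default_rng(seed)
    n = len(probes)
    brightness = base_intensity * np.exp(rng.normal(0.0, base_sigma, size=n))
    frames = []
    for genotype in genotypes:
        mu = expected_probe_log2(probes, truth, genotype, eps, duplex_frac_min, loopout_bp)
        c_ratio = 2.0**mu  # (c_eff + eps) / (1 + eps)
        for rep in range(1, n_replicates + 1):
            gain_s = math.exp(rng.normal(0.0, noise.multiplicative)) if noise.multiplicative else 1.0
            gain_r = math.exp(rng.normal(0.0, noise.multiplicative)) if noise.multiplicative else 1.0
            ratio_noise = (
                np.exp2(rng.normal(0.0, noise.sigma_log2, size=n)) if noise.sigma_log2 else 1.0
            )
            ch_ref = brightness * (1.0 + eps) * gain_r
            ch_smp = brightness * (1.0 + eps) * c_ratio * ratio_noise * gain_s
            if noise.multiplicative:
                ch_ref = ch_ref * np.exp(rng.normal(0.0, noise.multiplicative, size=n))
                ch_smp = ch_smp * np.exp(rng.normal(0.0, noise.multiplicative, size=n))
            if noise.additive:
                ch_ref = ch_ref + np.clip(
                    rng.normal(noise.additive, noise.additive / 4, size=n), 0, None
                )
                ch_smp = ch_smp + np.clip(
                    rng.normal(noise.additive, noise.additive / 4, size=n), 0, None
                )
            frames.append(
                pd.DataFrame(
                    {
                        "probe_id": probes["probe_id"].to_numpy(),
                        "genotype": genotype,
                        "replicate": rep,
                        "ch_sample": ch_smp,
                        "ch_ref": ch_ref,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# population panels


@dataclass
class PanelConfig:
    n_wild: int = 6
    n_cultivated: int = 8
    n_variants: int = 80
    singleton_fraction: float = 0.391
    wild_rate_multiplier: float = 1.5
    share_geom_p: float = 0.35
    mechanism_mix: dict = field(default_factory=lambda: dict(PAPER_MECHANISM_MIX))
    size_log_mean: float = math.log(400.0)
    size_log_sigma: float = 1.0
    min_size: int = 60
    max_size: int = 4000
    filler_log_mean: float = math.log(80.0)
    filler_min: int = 10
    duplication_fraction_of_none: float = 0.25
    placement: str = "uniform"  # uniform | recombination
    chromosome_rate_multipliers: dict = field(default_factory=dict)


@dataclass
class PopulationResult:
    reference: ReferenceGenome
    genomes: dict[str, dict[str, str]]
    truth: pd.DataFrame
    groups: dict[str, str]  # genotype -> wild | cultivated
    specs: list[VariantSpec] = field(default_factory=list)


def _largest_remainder_counts(proportions: dict[str, float], n: int) -> dict[str, int]:
    raw = {k: v * n for k, v in proportions.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    rest = n - sum(counts.values())
    order = sorted(raw, key=lambda k: raw[k] - counts[k], reverse=True)
    for k in order[:rest]:
        counts[k] += 1
    return counts


def _position_weights(reference: ReferenceGenome, config: PanelConfig) -> dict[str, float]:
    """Relative placement weight per contig (recombination and chromosome biases)."""
    weights = {}
    gmap = reference.genetic_map
    for cid, meta in reference.meta.items():
        w = 1.0
        w *= config.chromosome_rate_multipliers.get(meta.chromosome, 1.0)
        if config.placement == "recombination":
            sub = gmap[gmap["chromosome"] == meta.chromosome]
            bp = sub["bp"].to_numpy(float)
            cm = sub["cM"].to_numpy(float)
            mid = meta.phys_start + len(reference.contigs[cid]) / 2
            # local cM/Mb from the flanking map interval
            j = int(np.clip(np.searchsorted(bp, mid) - 1, 0, len(bp) - 2))
            dens = (cm[j + 1] - cm[j]) / max(bp[j + 1] - bp[j], 1) * 1e6
            w *= max(dens, 1e-3)
        weights[cid] = w
    return weights


def _sample_specs(
    reference: ReferenceGenome, config: PanelConfig, rng: np.random.Generator, genotype_pool
) -> list[VariantSpec]:
    ids = list(reference.contigs)
    lens = np.array([len(reference.contigs[c]) for c in ids], dtype=float)
    wmap = _position_weights(reference, config)
    weights = np.array([wmap[c] for c in ids]) * lens
    weights = weights / weights.sum()
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in ids}

    geno_ids = [g for g, _ in genotype_pool]
    geno_w = np.array([w for _, w in genotype_pool], dtype=float)
    geno_w = geno_w / geno_w.sum()

    mech_counts = _largest_remainder_counts(config.mechanism_mix, config.n_variants)
    mechanisms = [m for m, c in mech_counts.items() for _ in range(c)]
    rng.shuffle(mechanisms)

    # a variant (with signature halo) must fit the largest contig
    size_cap = max(int((lens.max() - 6 * _HALO) // 4), config.min_size)

    specs = []
    for mech in mechanisms:
        # realized kind + size for this mechanism
        if mech == "slippage":
            kind = "deletion" if rng.random() < 0.5 else "insertion"
            size = int(rng.integers(1, 7))
        elif mech == "SDSA":
            kind = "replacement"
            size = int(
                np.clip(
                    rng.lognormal(config.size_log_mean, config.size_log_sigma),
                    config.min_size,
                    min(config.max_size, size_cap),
                )
            )
        elif mech == "SSA":
            kind = "deletion"
            size = int(
                np.clip(
                    rng.lognormal(config.size_log_mean, config.size_log_sigma),
                    config.min_size,
                    min(config.max_size, size_cap),
                )
            )
        else:
            kind = (
                "duplication"
                if rng.random() < config.duplication_fraction_of_none
                else "deletion"
            )
            size = int(
                np.clip(
                    rng.lognormal(config.size_log_mean, config.size_log_sigma),
                    config.min_size,
                    min(config.max_size, size_cap),
                )
            )
        # sharing pattern
        if rng.random() < config.singleton_fraction or len(geno_ids) == 1:
            members = [geno_ids[int(rng.choice(len(geno_ids), p=geno_w))]]
        else:
            k = min(2 + int(rng.geometric(config.share_geom_p)) - 1, len(geno_ids))
            members = list(
                np.array(geno_ids)[
                    rng.choice(len(geno_ids), size=k, replace=False, p=geno_w)
                ]
            )
        # placement
        placed = False
        for _try in range(500):
            ci = ids[int(rng.choice(len(ids), p=weights))]
            L = len(reference.contigs[ci])
            need = size + 2 * (_HALO + size)
            if L <= need + 2 * _HALO:
                continue
            pos = int(rng.integers(_HALO + size, L - size - 2 * _HALO - size))
            spec = VariantSpec(
                kind=kind,
                size=size,
                contig=ci,
                position=pos,
                mechanism=mech,
                genotypes=tuple(sorted(members)),
                motif_len=(
                    int(rng.integers(2, min(40, size - 1) + 1)) if mech == "SSA" else None
                ),
                filler_len=(
                    max(
                        config.filler_min,
                        int(rng.lognormal(config.filler_log_mean, 0.6)),
                    )
                    if mech == "SDSA"
                    else None
                ),
            )
            lo, hi = _footprint(spec)
            if all(hi <= a or lo >= b for a, b in occupied[ci]):
                occupied[ci].append((lo, hi))
                specs.append(spec)
                placed = True
                break
        if not placed:
            raise SpikeError("genome too small for the requested variant load")
    return specs


def generate_population(
    reference: ReferenceGenome, config: PanelConfig, seed: int
) -> PopulationResult:
    """A wild + cultivated genotype panel with spiked structural variants."""
    if config.n_wild < 0 or config.n_cultivated < 0:
        raise ValueError("panel sizes must be >= 0")
    if config.n_wild + config.n_cultivated == 0:
        raise ValueError("panel must contain at least one genotype")
    rng = np.random.default_rng(seed)
    wild = [f"wild_{i + 1}" for i in range(config.n_wild)]
    cult = [f"cv_{i + 1}" for i in range(config.n_cultivated)]
    groups = {g: "wild" for g in wild} | {g: "cultivated" for g in cult}
    pool = [(g, config.wild_rate_multiplier) for g in wild] + [(g, 1.0) for g in cult]
    specs = (
        _sample_specs(reference, config, rng, pool) if config.n_variants > 0 else []
    )
    spike = spike_variants(reference, specs, seed=int(rng.integers(0, 2**31)), genotypes=wild + cult)
    return PopulationResult(
        reference=spike.reference,
        genomes=spike.genomes,
        truth=spike.truth,
        groups=groups,
        specs=specs,
    )


def generate_mechanism_set(
    n_indels: int = 299,
    proportions: dict[str, float] | None = None,
    seed: int = 0,
    genome_config: GenomeConfig | None = None,
    size_log_mean: float = math.log(80.0),
    size_log_sigma: float = 1.9,
    max_size: int = 7500,
) -> tuple[SpikeResult, list[IndelRecord], list[str]]:
    """A rejection-sampled indel set with a prescribed mechanism mixture.

    Class counts are realized deterministically by largest remainder, sizes
    follow a heavy-tailed lognormal (mean ≈ 490 bp, about half under 100 bp),
    slippage indels are 1-6 bp. Returns the spiked genomes, the indel records
    built at truth coordinates, and the intended class labels ("none" →
    "unknown").
    """
    proportions = proportions or PAPER_MECHANISM_MIX
    genome_config = genome_config or GenomeConfig(
        n_contigs=8, contig_length=250_000, repeat_families=(), telomere_enriched=False
    )
    rng = np.random.default_rng(seed)
    reference = generate_reference(genome_config, seed=int(rng.integers(0, 2**31)))
    counts = _largest_remainder_counts(proportions, n_indels)
    mechanisms = [m for m, c in counts.items() for _ in range(c)]
    rng.shuffle(mechanisms)

    ids = list(reference.contigs)
    lens = np.array([len(reference.contigs[c]) for c in ids], dtype=float)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in ids}
    specs = []
    for mech in mechanisms:
        if mech == "slippage":
            kind = "deletion" if rng.random() < 0.5 else "insertion"
            size = int(rng.integers(1, 7))
            motif_len = None
            filler_len = None
        elif mech == "SSA":
            kind = "deletion"
            size = int(np.clip(rng.lognormal(size_log_mean, size_log_sigma), 4, max_size))
            motif_len = int(rng.integers(2, min(40, size - 1) + 1))
            filler_len = None
        elif mech == "SDSA":
            kind = "replacement"
            size = int(np.clip(rng.lognormal(size_log_mean, size_log_sigma), 10, max_size))
            motif_len = None
            filler_len = max(10, int(rng.lognormal(math.log(60.0), 0.8)))
        else:
            kind = "deletion" if rng.random() < 0.8 else "insertion"
            size = int(np.clip(rng.lognormal(size_log_mean, size_log_sigma), 1, max_size))
            motif_len = None
            filler_len = None
        for _try in range(1000):
            ci = ids[int(rng.choice(len(ids), p=lens / lens.sum()))]
            L = len(reference.contigs[ci])
            margin = _HALO + size + 50
            if L <= 2 * margin:
                continue
            pos = int(rng.integers(margin, L - margin))
            spec = VariantSpec(
                kind=kind,
                size=size,
                contig=ci,
                position=pos,
                mechanism=mech,
                genotypes=("query",),
                motif_len=motif_len,
                filler_len=filler_len,
            )
            lo, hi = _footprint(spec)
            if all(hi <= a or lo >= b for a, b in occupied[ci]):
                occupied[ci].append((lo - 20, hi + 20))
                specs.append(spec)
                break
        else:
            raise SpikeError("mechanism-set genome too small")

    spike = spike_variants(reference, specs, seed=int(rng.integers(0, 2**31)))
    records = [truth_record(spike, row) for _, row in spike.truth.iterrows()]
    intended = [
        "unknown" if m == "none" else m for m in spike.truth["mechanism"].tolist()
    ]
    return spike, records, intended
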