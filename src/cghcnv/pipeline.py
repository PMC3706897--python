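"""Pipeline orchestration: config validation, staged execution, manifest.

The pipeline chains the package's stages over files in a run directory:

    genomes -> design -> hybridize -> normalize -> call -> landscape
                                                -> orthologs -> mech

Each stage reads its upstream outputs from the run directory, so any suffix
of the chain can be re-run when the upstream files already exist. One global
seed deterministically derives per-stage seeds; re-running a stage with the
same config and inputs reproduces identical outputs.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from . import __version__
from .sequtils import derive_seed


class ConfigError(ValueError):
    """Invalid pipeline configuration (all violations listed)."""


class DataError(RuntimeError):
    """Missing or inconsistent stage inputs."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GenomeSection(_Model):
    n_contigs: int = Field(14, ge=1)
    contig_length: int = Field(10_000, ge=1000)
    gc: float = Field(0.44, gt=0.0, lt=1.0)
    telomere_enriched: bool = True
    repeat_motif_bp: int = Field(300, ge=0)
    repeat_copies: int = Field(0, ge=0)


class PopulationSection(_Model):
    n_wild: int = Field(2, ge=0)
    n_cultivated: int = Field(2, ge=0)
    n_variants: int = Field(40, ge=0)
    singleton_fraction: float = Field(0.391, ge=0.0, le=1.0)
    wild_rate_multiplier: float = Field(1.5, gt=0.0)


class DesignSection(_Model):
    k: int = Field(15, ge=1)
    max_avg_freq: float = Field(25.0, gt=0.0)
    min_match: int = Field(30, ge=1)
    max_gaps: int = Field(5, ge=0)
    tm_target: float = 76.0
    min_len: int = Field(56, ge=1)
    max_len: int = Field(100, ge=1)
    step: int = Field(10, ge=1)
    span: int = Field(200, ge=1)
    per_fragment: int = Field(10, ge=1)
    min_gap: int = Field(500, ge=0)


class HybridizationSection(_Model):
    sigma_log2: float = Field(0.2, ge=0.0)
    additive: float = Field(0.0, ge=0.0)
    multiplicative: float = Field(0.0, ge=0.0)
    n_replicates: int = Field(2, ge=1)
    eps: float = Field(0.01, gt=0.0)


class CallingSection(_Model):
    p_min: float = Field(0.95, gt=0.0, lt=1.0)
    min_abs_log2: float = Field(0.9, gt=0.0)


class LandscapeSection(_Model):
    window_bp: int = Field(1_500_000, ge=1)
    recombination_bin_bp: int = Field(10_000_000, ge=1)


class OrthologSection(_Model):
    query_genotype: str | None = None
    min_identity: float = Field(95.0, ge=0.0, le=100.0)


class MechanismSection(_Model):
    n_sim: int = Field(1000, ge=1)
    max_micro: int = Field(40, ge=1)
    min_filler: int = Field(5, ge=1)
    max_identity: float = Field(60.0, ge=0.0, le=100.0)


class PipelineConfig(_Model):
    seed: int = Field(1, ge=0)
    outdir: str = "runs/run1"
    genome: GenomeSection = GenomeSection()
    population: PopulationSection = PopulationSection()
    design: DesignSection = DesignSection()
    hybridization: HybridizationSection = HybridizationSection()
    calling: CallingSection = CallingSection()
    landscape: LandscapeSection = LandscapeSection()
    orthologs: OrthologSection = OrthologSection()
    mechanisms: MechanismSection = MechanismSection()

    @field_validator("outdir")
    @classmethod
    def _nonempty(cls, v: str) -> str:
        if not v:
            raise ValueError("outdir must be non-empty")
        return v


def validate_config(path) -> PipelineConfig:
    """Load and fully validate a YAML config; unknown keys are rejected and
    all violations are reported together."""
    import yaml

    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    data = yaml.safe_load(path.read_text()) or {}
    try:
        return PipelineConfig.model_validate(data)
    except ValidationError as err:
        lines = [
            f"{'.'.join(str(p) for p in e['loc'])}: {e['msg']}" for e in err.errors()
        ]
        raise ConfigError("invalid config:\n  " + "\n  ".join(lines)) from None


def config_hash(cfg: PipelineConfig) -> str:
    import hashlib

    blob = json.dumps(cfg.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    stages: dict = dc_field(default_factory=dict)  # stage -> {outputs, sha256, seconds}

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


STAGE_ORDER = [
    "genomes",
    "design",
    "hybridize",
    "normalize",
    "call",
    "landscape",
    "orthologs",
    "mech",
]


def _require(outdir: Path, stage: str, *names: str) -> None:
    missing = [n for n in names if not (outdir / n).exists()]
    if missing:
        raise DataError(f"stage '{stage}' is missing upstream outputs: {missing}")


def _stage_genomes(cfg: PipelineConfig, outdir: Path) -> list[str]:
    from . import genomes as g
    from .io import write_fasta, write_tsv
    from .sequtils import random_dna
    import numpy as np

    seed = derive_seed(cfg.seed, "genomes")
    fams = ()
    if cfg.genome.repeat_copies:
        motif = random_dna(
            np.random.default_rng(derive_seed(cfg.seed, "repeat-motif")),
            cfg.genome.repeat_motif_bp,
        )
        fams = (g.RepeatFamily(motif, cfg.genome.repeat_copies),)
    gconf = g.GenomeConfig(
        n_contigs=cfg.genome.n_contigs,
        contig_length=cfg.genome.contig_length,
        gc=cfg.genome.gc,
        telomere_enriched=cfg.genome.telomere_enriched,
        repeat_families=fams,
    )
    ref = g.generate_reference(gconf, seed)
    pconf = g.PanelConfig(
        n_wild=cfg.population.n_wild,
        n_cultivated=cfg.population.n_cultivated,
        n_variants=cfg.population.n_variants,
        singleton_fraction=cfg.population.singleton_fraction,
        wild_rate_multiplier=cfg.population.wild_rate_multiplier,
    )
    pop = g.generate_population(ref, pconf, derive_seed(cfg.seed, "population"))
    write_fasta(pop.reference.contigs, outdir / "reference.fa")
    (outdir / "genomes").mkdir(exist_ok=True)
    for genotype, contigs in pop.genomes.items():
        write_fasta(contigs, outdir / "genomes" / f"{genotype}.fa")
    write_tsv(pop.truth, outdir / "truth.tsv")
    meta = pd.DataFrame(
        {
            "contig": list(pop.reference.meta),
            "chromosome": [m.chromosome for m in pop.reference.meta.values()],
            "phys_start": [m.phys_start for m in pop.reference.meta.values()],
        }
    )
    write_tsv(meta, outdir / "contig_meta.tsv")
    write_tsv(pop.reference.genetic_map, outdir / "genetic_map.tsv")
    groups = pd.DataFrame(
        {"genotype": list(pop.groups), "group": list(pop.groups.values())}
    )
    write_tsv(groups, outdir / "groups.tsv")
    return [
        "reference.fa",
        "truth.tsv",
        "contig_meta.tsv",
        "genetic_map.tsv",
        "groups.tsv",
    ]


def _load_reference(outdir: Path):
    from .genomes import ContigMeta, ReferenceGenome
    from .io import read_fasta, read_tsv

    contigs = read_fasta(outdir / "reference.fa")
    meta_df = read_tsv(outdir / "contig_meta.tsv")
    meta = {
        r.contig: ContigMeta(r.chromosome, int(r.phys_start))
        for r in meta_df.itertuples(index=False)
    }
    gmap = read_tsv(outdir / "genetic_map.tsv")
    return ReferenceGenome(contigs=contigs, meta=meta, genetic_map=gmap)


def _stage_design(cfg: PipelineConfig, outdir: Path) -> list[str]:
    from .design import design_probes
    from .io import write_fragments_bed, write_fragments_tsv, write_json, write_tsv

    _require(outdir, "design", "reference.fa", "contig_meta.tsv")
    ref = _load_reference(outdir)
    d = cfg.design
    res = design_probes(
        ref,
        k=d.k,
        max_avg_freq=d.max_avg_freq,
        min_match=d.min_match,
        max_gaps=d.max_gaps,
        tm_target=d.tm_target,
        min_len=d.min_len,
        max_len=d.max_len,
        step=d.step,
        span=d.span,
        per_fragment=d.per_fragment,
        min_gap=d.min_gap,
    )
    write_tsv(res.probes, outdir / "probes.tsv")
    write_fragments_tsv(res.fragments, outdir / "fragments.tsv")
    write_fragments_bed(res.fragments, outdir / "fragments.bed")
    write_json(res.summary, outdir / "design_summary.json")
    return ["probes.tsv", "fragments.tsv", "fragments.bed", "design_summary.json"]


def _stage_hybridize(cfg: PipelineConfig, outdir: Path) -> list[str]:
    from .genomes import NoiseModel, simulate_hybridization
    from .io import read_tsv, write_tsv

    _require(outdir, "hybridize", "reference.fa", "probes.tsv", "truth.tsv")
    ref = _load_reference(outdir)
    probes = read_tsv(outdir / "probes.tsv")
    truth = read_tsv(outdir / "truth.tsv").fillna({"alt_seq": ""})
    groups = read_tsv(outdir / "groups.tsv")
    h = cfg.hybridization
    raw = simulate_hybridization(
        ref,
        probes,
        truth,
        genotypes=groups["genotype"].tolist(),
        noise=NoiseModel(h.sigma_log2, h.additive, h.multiplicative),
        n_replicates=h.n_replicates,
        seed=derive_seed(cfg.seed, "hybridize"),
        eps=h.eps,
    )
    write_tsv(raw, outdir / "intensities.tsv")
    return ["intensities.tsv"]


def _stage_normalize(cfg: PipelineConfig, outdir: Path) -> list[str]:
    from .io import read_fragments_tsv, read_tsv, write_tsv
    from .signals import aggregate_fragment_signal, normalize

    _require(outdir, "normalize", "intensities.tsv", "fragments.tsv")
    raw = read_tsv(outdir / "intensities.tsv")
    ratios = normalize(raw)
    fragments = read_fragments_tsv(outdir / "fragments.tsv")
    signals = aggregate_fragment_signal(ratios, fragments)
    write_tsv(ratios, outdir / "probe_log2.tsv")
    write_tsv(signals, outdir / "fragment_signals.tsv")
    return ["probe_log2.tsv", "fragment_signals.tsv"]


def _stage_call(cfg: PipelineConfig, outdir: Path) -> list[str]:
    from .calling import call_genotypes, merge_consecutive_events
    from .io import read_fragments_tsv, read_tsv, write_tsv

    _require(outdir, "call", "fragment_signals.tsv", "fragments.tsv")
    signals = read_tsv(outdir / "fragment_signals.tsv")
    fragments = read_fragments_tsv(outdir / "fragments.tsv")
    calls, _fits = call_genotypes(
        signals, p_min=cfg.calling.p_min, min_abs_log2=cfg.calling.min_abs_log2
    )
    events = merge_consecutive_events(calls, fragments)
    events = events.assign(fragment_ids=events["fragment_ids"].map(",".join))
    write_tsv(calls, outdir / "calls.tsv")
    write_tsv(events, outdir / "events.tsv")
    return ["calls.tsv", "events.tsv"]


def _stage_landscape(cfg: PipelineConfig, outdir: Path) -> list[str]:
    from .design import fragment_positions
    from .io import read_fragments_tsv, read_tsv, write_json, write_tsv
    from . import landscape as ls

    _require(outdir, "landscape", "calls.tsv", "fragments.tsv", "genetic_map.tsv")
    calls = read_tsv(outdir / "calls.tsv")
    fragments = read_fragments_tsv(outdir / "fragments.tsv")
    ref = _load_reference(outdir)
    groups_df = read_tsv(outdir / "groups.tsv")
    groups = dict(zip(groups_df["genotype"], groups_df["group"]))
    positions = fragment_positions(fragments, ref)
    spectrum = ls.frequency_spectrum(calls, n_genotypes=len(groups))
    wins = ls.window_proportions(calls, positions, cfg.landscape.window_bp)
    rates = ls.chromosome_rates(calls, positions, cfg.landscape.window_bp)
    diff = ls.group_difference_profile(calls, positions, groups, cfg.landscape.window_bp)
    write_tsv(spectrum, outdir / "frequency_spectrum.tsv")
    write_tsv(wins, outdir / "window_proportions.tsv")
    write_tsv(rates, outdir / "chromosome_rates.tsv")
    write_tsv(diff, outdir / "group_difference.tsv")
    summary = {
        "n_variant_fragments": int(calls["fragment_id"].nunique()),
        "singleton_fraction": ls.singleton_fraction(calls),
    }
    try:
        rho, p, _tab = ls.recombination_cnv_correlation(
            calls, positions, ref.genetic_map, cfg.landscape.recombination_bin_bp
        )
        summary["recombination_spearman_rho"] = rho
        summary["recombination_spearman_p"] = p
    except ValueError:
        summary["recombination_spearman_rho"] = None
    write_json(summary, outdir / "landscape_summary.json")
    return [
        "frequency_spectrum.tsv",
        "window_proportions.tsv",
        "chromosome_rates.tsv",
        "group_difference.tsv",
        "landscape_summary.json",
    ]


def _stage_orthologs(cfg: PipelineConfig, outdir: Path) -> list[str]:
    from .io import read_fasta, read_fragments_tsv, read_tsv, write_tsv
    from . import orthologs as ort

    _require(outdir, "orthologs", "calls.tsv", "fragments.tsv", "reference.fa")
    calls = read_tsv(outdir / "calls.tsv")
    fragments = read_fragments_tsv(outdir / "fragments.tsv")
    ref = _load_reference(outdir)
    genotype = cfg.orthologs.query_genotype
    if genotype is None:
        genotype = sorted(calls["genotype"].unique())[0] if len(calls) else None
    if genotype is None:
        raise DataError("no calls available to pick a query genotype")
    qpath = outdir / "genomes" / f"{genotype}.fa"
    if not qpath.exists():
        raise DataError(f"query genome not found: {qpath}")
    query = read_fasta(qpath)
    called = set(calls.loc[calls["genotype"] == genotype, "fragment_id"])
    contigs = ort.select_analyzable_contigs(called, fragments)
    indel_rows, cov_rows = [], []
    for cid in contigs:
        match = ort.find_orthologs(
            cid, ref.contigs[cid], query, min_identity=cfg.orthologs.min_identity
        )
        if not match:
            continue
        sc = ort.build_supercontig(match, query)
        aln = ort.align_pair(ref.contigs[cid], sc.sequence, cid, f"{genotype}:{cid}")
        indels = ort.extract_indels(aln)
        for rec in indels:
            indel_rows.append(
                {
                    "ref_contig": rec.ref_contig,
                    "ref_start": rec.ref_start,
                    "ref_end": rec.ref_end,
                    "q_start": rec.q_start,
                    "q_end": rec.q_end,
                    "side": rec.side,
                    "size": rec.size,
                    "seq_ref": rec.seq_ref,
                    "seq_query": rec.seq_query,
                    "left_flank": rec.left_flank,
                    "right_flank": rec.right_flank,
                }
            )
        for frag in fragments[fragments["contig"] == cid].itertuples(index=False):
            cov = ort.fragment_coverage(aln, frag.fragment_id, frag.start, frag.end, indels)
            cov_rows.append(
                {
                    "fragment_id": cov.fragment_id,
                    "percent_present": cov.percent,
                    "bin": cov.bin,
                    "identity": cov.identity,
                    "false_positive": cov.false_positive,
                }
            )
    write_tsv(
        pd.DataFrame(
            indel_rows,
            columns=[
                "ref_contig",
                "ref_start",
                "ref_end",
                "q_start",
                "q_end",
                "side",
                "size",
                "seq_ref",
                "seq_query",
                "left_flank",
                "right_flank",
            ],
        ),
        outdir / "indels.tsv",
    )
    write_tsv(
        pd.DataFrame(
            cov_rows,
            columns=["fragment_id", "percent_present", "bin", "identity", "false_positive"],
        ),
        outdir / "coverage.tsv",
    )
    return ["indels.tsv", "coverage.tsv"]


def _stage_mech(cfg: PipelineConfig, outdir: Path) -> list[str]:
    from .io import read_tsv, write_json, write_tsv
    from .orthologs import IndelRecord
    from . import mechanisms as mech

    _require(outdir, "mech", "indels.tsv", "reference.fa")
    table = read_tsv(outdir / "indels.tsv").fillna(
        {"seq_ref": "", "seq_query": "", "left_flank": "", "right_flank": ""}
    )
    records = [
        IndelRecord(
            r.ref_contig,
            int(r.ref_start),
            int(r.ref_end),
            int(r.q_start),
            int(r.q_end),
            r.side,
            r.seq_ref,
            r.seq_query,
            r.left_flank,
            r.right_flank,
        )
        for r in table.itertuples(index=False)
    ]
    m = cfg.mechanisms
    calls = mech.classify_all(
        records, max_micro=m.max_micro, min_filler=m.min_filler, max_identity=m.max_identity
    )
    out = table.copy()
    out["class"] = [c.klass for c in calls]
    out["signature_length"] = [c.signature_length for c in calls]
    out["filler_length"] = [c.filler_length for c in calls]
    out["slippage_unit"] = [c.slippage_unit for c in calls]
    write_tsv(out, outdir / "mechanisms.tsv")
    report: dict = {"n_indels": len(records), "class_counts": {}}
    for c in calls:
        report["class_counts"][c.klass] = report["class_counts"].get(c.klass, 0) + 1
    if records:
        ref = _load_reference(outdir)
        null = mech.random_indel_null(
            ref,
            [r.size for r in records],
            n_sim=m.n_sim,
            seed=derive_seed(cfg.seed, "mech-null"),
            max_len=m.max_micro,
        )
        observed = mech.microhomology_class_counts(records, max_len=m.max_micro)
        report["enrichment"] = mech.signature_enrichment_test(observed, null)
    write_json(report, outdir / "mechanism_report.json")
    return ["mechanisms.tsv", "mechanism_report.json"]


_STAGES = {
    "genomes": _stage_genomes,
    "design": _stage_design,
    "hybridize": _stage_hybridize,
    "normalize": _stage_normalize,
    "call": _stage_call,
    "landscape": _stage_landscape,
    "orthologs": _stage_orthologs,
    "mech": _stage_mech,
}


def run_pipeline(cfg: PipelineConfig, stages: list[str] | None = None) -> RunManifest:
    """Execute the selected stages (default: all) in dependency order."""
    from .io import sha256_file

    if stages is None:
        stages = list(STAGE_ORDER)
    unknown = set(stages) - set(STAGE_ORDER)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    stages = [s for s in STAGE_ORDER if s in stages]
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config_hash(cfg), version=__version__, seed=cfg.seed)
    for stage in stages:
        t0 = time.perf_counter()
        outputs = _STAGES[stage](cfg, outdir)
        manifest.stages[stage] = {
            "outputs": outputs,
            "sha256": {name: sha256_file(outdir / name) for name in outputs},
            "seconds": round(time.perf_counter() - t0, 3),
        }
    manifest.to_json(outdir / "manifest.json")
    return manifest
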