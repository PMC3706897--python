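"""Call copy-number variants from simulated two-channel hybridizations.

Spikes one full-fragment deletion (a presence/absence variant) and one
tandem duplication into a derived genotype, simulates noisy two-channel
probe intensities, normalizes them, averages to fragment signals, and calls
CNVs with the two-component EM mixture (posterior > 0.95, |log2| > 0.9).
"""

from cghcnv.calling import call_genotypes
from cghcnv.design import design_probes
from cghcnv.genomes import (
    GenomeConfig,
    NoiseModel,
    VariantSpec,
    generate_reference,
    simulate_hybridization,
    spike_variants,
)
from cghcnv.signals import aggregate_fragment_signal, normalize

reference = generate_reference(GenomeConfig(n_contigs=6, contig_length=30_000), seed=1)
design = design_probes(reference)

del_frag = design.fragments.iloc[3]
dup_frag = design.fragments.iloc[10]
specs = [
    VariantSpec(
        "deletion",
        int(del_frag.end - del_frag.start) + 400,
        del_frag.contig,
        int(del_frag.start) - 200,
        "none",
        ("barke_like",),
    ),
    VariantSpec(
        "duplication",
        int(dup_frag.end - dup_frag.start) + 400,
        dup_frag.contig,
        int(dup_frag.start) - 200,
        "none",
        ("barke_like",),
    ),
]
spike = spike_variants(reference, specs, seed=2)
raw = simulate_hybridization(
    spike.reference,
    design.probes,
    spike.truth,
    noise=NoiseModel(sigma_log2=0.2, additive=50.0, multiplicative=0.1),
    seed=3,
)
signals = aggregate_fragment_signal(normalize(raw), design.fragments)
calls, fits = call_genotypes(signals)

fit = fits["barke_like"]
print(f"fragments tested: {len(signals)}")
print(
    f"mixture fit: pi={fit.pi:.4f}  variant N({fit.mu_variant:.2f}, {fit.sigma_variant:.2f}^2)"
    f"  null N({fit.mu_null:.3f}, {fit.sigma_null:.3f}^2)  ({fit.n_iter} EM iterations)"
)
print()
print(calls.to_string(index=False))
print()
print(
    "The deleted fragment appears as DownCNV/PAV (strongly negative log2);\n"
    "the duplicated one as UpCNV near +1 (log2 of a two-fold gain). All other\n"
    "fragments stay below both call thresholds."
)
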