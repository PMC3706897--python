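# Methods

This note documents the models implemented in `cghcnv`, the defaults that
matter, and what the synthetic data do and do not emulate. All coordinates
are 0-based half-open; all sequences are uppercase over {A, C, G, T} (plus
`N` only in supercontig spacers); every stochastic routine takes an explicit
integer seed and is bit-reproducible.

## Array design

Candidate probes are generated at a 10 bp start grid. The length of each
probe is chosen from the grid {56, 66, 76, 86, 96, 100} as the shortest
length whose melting proxy

    Tm = 64.9 + 41 * (n_GC - 16.4) / L          (Wallace-type rule)

reaches `tm_target` (default 76). The original design procedure does not
state how per-probe lengths were chosen within 56–100; this rule is a
documented stand-in whose default reproduces a median length of 76 for
~50% GC sequence. AT-rich sequence falls back to the longest length that
fits, GC-rich sequence to the minimum.

**Repeat masking.** A genome-wide 15-mer table counts every forward window;
by default a k-mer and its reverse complement share one bucket, because
hybridization is double-stranded (configurable with `canonical=False`). A
probe is removed iff its mean count over all (L−14) windows exceeds 25
(strictly: a mean of exactly 25.0 is retained).

**Uniqueness.** A probe is eliminated when any of its 30 bp substrings
occurs a second time anywhere in the genome, on either strand. This is the
"minimum match size 30" semantics of a seeded genome aligner: a qualifying
secondary site is detected through its exact ≥ 30 bp stretch. The `max_gaps`
parameter documents the gap allowance such an aligner uses when joining
neighbouring seed matches into one reported site; it does not change
keep/drop decisions, because any gap-joined secondary alignment already
contains a qualifying seed.

**Fragments.** Greedy left-to-right per contig: the first window of ≤ 200 bp
that fully contains ≥ 10 surviving probes becomes a fragment (first 10
probes by start; ties by length, then id). The next search resumes at
`window_start + 200 + 500`, which guarantees both an inter-fragment gap
≥ 500 bp and fragment starts ≥ 700 bp apart.

## Hybridization model

Each probe's expected log2 ratio is

    mu = log2((c_eff + eps) / (1 + eps)),   eps = 0.01

where `c_eff` is the effective copy number of the probe's target in the
derived genome and the pseudo-copy `eps` models array background (absent
sequence reports background, not −inf). A full tandem duplication gives
c_eff = 2 (mu ≈ 0.993), a homozygous deletion c_eff = 0 (mu = log2(0.01/1.01)
≈ −6.66), an unaffected probe exactly 0.

**Breakpoint degradation (stringent-wash model).** A probe whose target is
interrupted by a breakpoint retains only its longest contiguous matching
stretch. If that stretch is at least `duplex_frac_min` (default 0.9) of the
probe length the probe contributes a linear yield (stretch / length);
below the threshold the truncated duplex is assumed to melt off during the
stringent wash and the probe contributes only background. A purely linear
yield cannot reproduce the empirically observed artifact in which a small
mid-fragment insertion produces a DownCNV/PAV signal — with linear yield a
50 bp central insertion depresses the fragment mean to only ≈ −0.33 — so the
threshold model is used. Insertions smaller than `loopout_bp` (default
21 bp) are assumed to loop out of the probe–target duplex and leave the
signal unchanged; from 22 bp on they split the probe's matching stretch.
Under these defaults any ≥ 22 bp mid-fragment insertion drags the noise-free
fragment mean below the −0.9 call threshold, i.e. an insertion masquerades
as a DownCNV/PAV — the false-positive mode the sequence-level analysis is
designed to catch.

**Noise.** Per-probe brightness is lognormal (median 500, sd 0.6 on the log
scale) and identical across genotypes. Three independent noise sources
exercise the normalization: `sigma_log2` (default 0.2) — Gaussian noise on
the log2 ratio; `multiplicative` — per-array channel gains and per-probe
lognormal factors; `additive` — nonnegative Gaussian background per channel.
With all three at zero the channel ratio equals the expected ratio exactly.

## Normalization

Per array (one genotype × replicate) and per channel, an additive background
is estimated as `a = max(0, 2*q05 − q50)` — a scale-equivariant quantile
statistic that is ≈ 0 for background-free lognormal intensities — and the
channel is transformed with the generalized log

    h(x) = log2((x − a + sqrt((x − a)^2 + c^2)) / 2),   c = a.

The output ratio h(sample) − h(reference) is recentred so that its median
equals the median raw log2 ratio, which removes the transform's additive
constant while preserving genuine global dosage (an arm-dosage shift
survives normalization). Properties guaranteed by construction and asserted
in tests: monotone in each channel; exactly invariant to per-channel
scaling; exact log-ratio recovery for noise-free proportional channels; and
variance flatness of null ratios across intensity deciles (< 2-fold). The
transform is a contract-level variance-stabilizing calibration, not a
reimplementation of any specific package.

Replicates are averaged per probe first, then the fragment signal is the
arithmetic mean of its 10 probes.

## CNV calling

One EM fit per genotype over all its fragment signals (the per-genotype
choice is configurable in principle by pooling the input). Initialization is
deterministic: null component at (median, (1.4826·MAD)^2); variant component
from the values with |v| > 0.9 (their mean, and at least twice the null sd),
or a weakly-informative fallback when fewer than two such values exist.
Convergence at log-likelihood gain < 1e-8, max 500 iterations; component sds
floored at 1e-4. After fitting, the variant component is the one whose mean
is farther from 0 (tie → larger variance); it is two-sided, and the call
direction comes from the ratio's sign, not from separate fits. Degenerate
(near-constant) input returns a null-only fit with all posteriors 0.

Calls require posterior > 0.95 and |log2| > 0.9, both strict. Events are
maximal runs of same-class calls consecutive in the contig's fragment order;
singleton runs are kept with `n_fragments = 1` so event-level filtering
(≥ 2 fragments) is a downstream choice. Cross-design concordance is
|A∩B| / |A| over (fragment, genotype, class) triples, with the symmetric
fraction reported alongside.

## Landscape statistics

A fragment is *variant* when called in ≥ 1 genotype. Windows (1.5 Mbp
default) are half-open and tile each chromosome; fragments are assigned by
their start coordinate, so nothing is double-counted; empty windows get a
null proportion. The chromosome test is a one-vs-rest Welch t-test over
window-level proportions — the sampling unit of the original chromosome
tests is not defined, so the window was chosen and the exact published
p-values are not reproduction targets. Recombination correlation: per 10 Mb
bin, cM/Mb is computed from map positions linearly interpolated at the bin
edges, CNV frequency as the proportion of the bin's fragments that are
variant; Spearman's rho is taken over all bins of all chromosomes pooled.
Exon overlap is ≥ 1 bp intersection with annotation intervals, half-open.

## Sequence-level confirmation

Contigs are analyzable when they carry ≥ 3 fragments and an internal called
fragment flanked on both sides by uncalled ones. Ortholog search aligns each
query contig (both orientations, after a shared-16-mer prescreen) to the
reference contig and keeps the hit when (i) gap-compressed identity —
matches / aligned columns, gaps excluded — exceeds 95% and (ii) matched
bases cover ≥ 50% of the shorter sequence. Gap-compressed identity is used
because one real 300 bp deletion in a 6 kb contig would otherwise sink a
perfect ortholog to exactly 95%; the coverage screen rejects gappy chance
chains, which can reach near-100% gap-compressed identity at low coverage.
Retained hits are chained along the reference best-identity-first (overlaps
beyond 25 bp dropped) and concatenated into a supercontig, oriented, joined
by 50 'N' spacers.

**Alignment.** Local affine-gap Smith–Waterman via Biopython's
`PairwiseAligner` with the EMBOSS Water convention: match +5, mismatch −4,
gap open 10, gap extend 0.5; `N` scores −10 so alignments never cross
spacers. The strong mismatch penalty is load-bearing: under a unit
match/mismatch scoring an unalignable filler segment is absorbed as cheap
mismatch columns and replacement junctions never form. Scoring is
configurable through `make_aligner`.

**Indel extraction.** Every gap run becomes a record; adjacent runs
separated by fewer than 20 aligned bases merge into one replacement record
(ref-only segment + query-only segment). The 20 bp threshold treats short
aligned stretches as junction noise: around a genuine filler the aligner
typically anchors 10–20 bp of chance co-alignment against the replaced
sequence. Pure indels are left-normalized — shifted to the leftmost
equivalent placement within their microhomology tract — so signature
detection is deterministic. Flanks of up to 60 bp are cut from the reference
sequence; records with < 20 bp of flank are flagged truncated.

**Coverage bins.** Percent of fragment bases aligned (non-gap), binned as
exactly 0 → "0"; (0,25) → "0-24"; [25,50) → "25-49"; [50,75) → "50-74";
[75,100) → "75-99"; exactly 100 → "100". The interior edge convention (e.g.
24.5% is "0-24") is a package decision. A fragment fully present at ≥ 95%
identity with no internal indel > 1 bp is flagged a false-positive array
call.

## Mechanism classification

`microhomology_length` returns max(k_left, k_right) capped at 40, where
k_left is the longest common prefix of the deleted sequence and the right
flank, and k_right the longest common suffix of the deleted sequence and the
left flank. Both junction directions are tested because the available
evidence does not fix which side carries the motif; indels are
left-normalized first. Slippage requires the complete 1–6 bp indel sequence
immediately repeated in either adjacent flank. Filler detection applies only
to replacements: the query-only segment must be ≥ `min_filler` (5 bp,
free parameter) long and its best local alignment against the local context
(deleted segment + both flanks) may explain at most `max_identity` (60%,
free parameter) of its bases; this detector uses unit match/mismatch
scoring, since EDNAFULL's cheap gap extension chains isolated matches and
inflates the alignable fraction of genuinely random fillers. Precedence is
slippage > SDSA > SSA (2 ≤ microhomology ≤ 40) > unknown: the full-length
adjacent repeat is the most specific signature, the filler is categorical,
microhomology is the residual signal; the four classes partition the set.
Classification is a pure function of the indel record.

**Null model.** Each simulation places one deletion per observed size at a
uniformly random position (contigs weighted by eligible length) and computes
junction microhomology in place. On equal-base-frequency sequence the
fraction with microhomology ≥ 3 bp has the closed form 1 − (1 − 4⁻³)² ≈
0.031 (two independent junction tests), which the simulation reproduces;
GC-skew raises it. Enrichment p-values are add-one Monte-Carlo:
p = (1 + #{simulations at least as extreme}) / (1 + n_sim), upper tail for
the ">2 bp" class, lower tail for "0" and "1–2".

## Synthetic data: what it emulates, what it does not

The generator emulates the study conditions: a multi-contig reference with
interspersed repeat families; an inbred (fully homozygous) panel of wild and
cultivated genotypes, wild at a higher variant rate (default 1.5×, matching
the observed ~4.5% vs ~3% per-genotype rates) and a singleton fraction of
0.391; two-channel intensities with the noise structure above; and a
telomere-enriched genetic map (cM/Mb rising toward chromosome ends).
Mechanism-tagged variants are implanted with verifiable signatures: SSA
border motifs are written into both required positions of the reference copy
(with junction bases adjusted so the detector returns exactly the intended
motif length), slippage deletions get a perfect adjacent unit copy, SDSA
fillers are rejection-sampled until unalignable, and "none" variants are
rejection-sampled/scrubbed until they carry no signature (microhomology ≤ 1,
no adjacent repeat). Because signatures must live in the reference sequence,
`spike_variants` returns the implanted reference along with the derived
genomes; downstream stages use the returned reference.

The mechanism evaluation set holds 299 indels with class counts fixed by
largest remainder from the proportions 41.1 / 12.7 / 15.7 / 30.4% (i.e.
123/38/47/91); sizes are lognormal(ln 80, 1.9) clipped to [1, 7500] bp
(mean ≈ 490 bp, about half under 100 bp), slippage sizes uniform on 1–6 bp,
SSA motif lengths uniform on [2, min(40, size−1)].

Not emulated: heterozygosity (the panel is inbred, as in the target
species), read-level sequencing artifacts, SNP attenuation of probe signal
(how point mismatches attenuate hybridization is unquantified; the option is
off by default and the simulator places no SNPs), transposon biology,
spatial (x, y) array artifacts, and dye-specific bias beyond replicate
averaging. Passing tests therefore demonstrate the correctness of the
algorithms under the stated generative model, not robustness to every
artifact of physical arrays.

## Problem sizes and numerics

The test suite runs on genomes of 0.1–1.5 Mb (6–70 contigs of 5–30 kb),
panels of up to 8 genotypes, 10,000-simulation nulls, and 20,000-point EM
fits; the full pipeline demo uses 8 × 6 kb contigs and 4 genotypes. These
sizes were chosen so every stage, including exhaustive oracles, runs in
seconds while keeping each statistical check well-powered (3-standard-error
bands on 299–20,000 observations). Determinism: per-stage seeds derive from
one global seed via SHA-256; EM is seed-free by construction; alignment
tie-breaking takes the aligner's first optimal path; indel left-
normalization removes the remaining placement ambiguity.

## Known limitations

- UpCNV copy number is not resolved beyond "higher signal"; multi-copy
  duplications are simulated as single tandem events.
- DownCNV and PAV are indistinguishable by design (single-reference array).
- The uniqueness screen detects exact secondary stretches; a secondary site
  composed only of < 30 bp pieces joined by gaps is not flagged.
- Supercontig coordinates are not mapped back through to source query
  contigs in the indel records (records carry supercontig coordinates plus
  reference coordinates, which downstream analysis uses).
- The 95% ortholog-identity and 50% coverage screens assume the query
  assembly derives from the same subspecies; diverged material yields empty
  matches, which mirrors the real difficulty of confirming strong copy
  losses at the sequence level.
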