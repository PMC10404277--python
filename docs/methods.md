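# Methods

This note documents the models, estimators, and numerical conventions the
package implements, the design choices that were genuinely open, and what
the synthetic-data generators do and do not emulate.

## Count model and simulation design

Fraction counts are negative binomial with mean μ and dispersion α,
Var = μ + αμ² (the edgeR-style parameterization the DE stage assumes).
Sampling is gamma–Poisson; **α = 0 is deterministic** — counts equal the
rounded expected means — so planted truths are exactly recoverable in
noise-free tests. A `noise="poisson"` mode draws Poisson counts instead
(for pure counting-noise experiments such as size-factor recovery).

Expected counts for gene *g* in library (genotype, fraction, replicate):

```
μ = mean_depth · 2^{rna_effect(g)·[mutant]} · L(fraction) · scale_factor(library)
```

A planted TE log2FC of δ is split symmetrically — polysome loading
× 2^{+δ/2} and monosome loading × 2^{−δ/2} in the mutant — so RNA
abundance carries no signal unless an `rna_effect` is planted too, and the
TE pipeline's estimand equals δ exactly. Spike-in expected counts are
`input_amount × scale_factor × spikein_unit_counts`, independent of
genotype and fraction (equal amounts added to every sample).

Defaults mirror the emulated study design where it is stated — 2
genotypes × 3 fractions × **2 replicates**, **92** spike-in species, the
**28–32 nt** footprint size selection — and are package choices where it is
not: mean depth 500 counts/gene, dispersion α = 0.05 (a typical bulk
RNA-seq value for replicate larval samples), footprint lengths uniform on
25–35 nt so the 28–32 filter is exercised non-trivially.

**Spike-in amounts.** The real ERCC mix spans ~2²⁰ in concentration; at
the simulated depths (total spike counts ~10⁴/library) the bottom of such
a ladder yields zero counts and contributes nothing to a median-of-ratios
estimator. The default synthetic mix therefore uses 92 species spanning
2⁸ — a mid-dynamic-range slice of an ERCC-like ladder — scaled to a chosen
total amount. Span and count are configurable.

## Size factors

Median over spike species of count/amount per library, using the species
that reach `min_count` (default 5, a ratio-stability guard) in **every**
library, so the median is over the same species everywhere; a library
where fewer than 3 species pass raises an error naming it. Factors are
anchored to geometric mean 1 so they are comparable across runs; the
normalized scale is therefore defined up to that anchoring, and invariants
are stated on between-library ratios. A library-total alternative
(`spikes.sum()` ratios) would be more efficient under pure Poisson noise
but is not robust to single-species dropout or contamination; the median
rule is the default.

## Translation efficiency

TE per condition is the geometric mean over replicates of
`(poly_r + c)/(mono_r + c)` with pseudocount c = 1.0 on normalized counts
(a `pooled` mode — mean counts then one ratio — is selectable; geometric
mean is the default because TE is a ratio and log-averaging treats the two
fractions symmetrically). Classification uses strict inequalities at the
thresholds (default 1.0 on both TE and RNA log2FC): values exactly at a
threshold are `unchanged`.

**Expected operating characteristics.** With per-library CV²
≈ 1/μ + α, the TE log2FC contrast over 8 libraries (2 genotypes × 2
fractions × 2 replicates) has standard deviation
≈ √(4·CV²)/ln 2 ≈ 0.47 at μ = 500, α = 0.05. Planted |δ| = 2 effects are
recovered with ≥ 95% power at the |log2FC| > 1 threshold, but null genes
cross it at ~3% — an information-theoretic floor of the 2-replicate
design, not an estimator defect; no shrinkage is applied because the
estimator is kept unbiased (noise-free planted effects are recovered to
1e-6). Users wanting a lower false-call rate should raise the threshold or
the replicate count.

## Differential expression

A minimal NB exact test approximating common edgeR usage, without claiming
numerical equality with it:

1. **Dispersion**: one common α by pooled method of moments — within-group
   sample variance v and mean m per gene, α̂ = Σ(v − m)/Σm², floored at
   1e-8. With thousands of genes this is stable even at 2 replicates per
   group.
2. **Test**: group sums of n i.i.d. NB(μ, α) libraries are NB with size
   n/α; conditioning on the total, the two-sided p-value sums the
   probabilities of all splits no more probable than the observed one
   (with a 1+1e-10 tie guard against floating-point equality). For a
   common α this conditional law is free of μ (negative hypergeometric /
   beta-binomial with integer shapes) — a property the test suite uses as
   an independent oracle.
3. **Adjustment and calls**: Benjamini–Hochberg FDR; `up`/`down` at
   FDR < 0.05 and |log2FC| > 1 (group means with pseudocount 1).

Normalized counts are rounded to integers for the exact test. Genes with
zero counts in all libraries are dropped (log2FC undefined). Null
calibration measured by simulation: empirical type-I at p < 0.05 is
0.047–0.057 across seeds (2000 genes, α = 0.05, depth 500).

## uORF annotation

Starts are AUG-only by default — near-cognate codons (CUG/GUG/UUG) are
selectable via `start_codons` but off, since no criteria beyond "putative
upstream ORFs" are being emulated. No minimum length (AUG + stop counts).
A uORF without an in-frame stop before the transcript end is reported with
a `None` stop sentinel rather than dropped. Coordinates are 0-based
half-open internally; GFF3 export converts to 1-based inclusive. DNA input
(T) is transcribed to U on read.

Start-codon mutagenesis checks the edit window for newly created AUG
trigrams and refuses rather than silently introducing a uORF. Note that
even UAA can create one (its trailing A followed by downstream UG), so the
check is unconditional.

## Ribosome occupancy

Raw density at a base is the number of footprints covering it
(full-coverage counting); the profile is raw density over its sum, so it
sums to 1 by construction for any non-empty read set. A `five_prime` mode
counts start positions only, for sensitivity analysis — which convention a
given published profile used is often unstated, so the choice is a
parameter, not a guess. Zero-read inputs return a flagged all-zero profile
that comparison utilities exclude instead of propagating NaN. Region
proportions over a non-overlapping partition sum to 1; overlapping regions
(an out-of-frame uORF extending into the CDS vs the CDS itself) are summed
independently and may double-count shared bases — deliberately, since both
quantities are biologically meaningful.

**Planted overlapping uORFs and detectability.** The transcriptome
generator places the overlapping uORF's AUG ≥ 24 nt upstream of the main
start when the UTR allows (uniformly over smaller offsets otherwise).
This matches the configuration of known long CDS-overlapping uORFs and is
also what makes an occupancy redistribution measurable: a bare AUG
abutting the CDS would put essentially every uORF footprint inside the CDS
span, so coverage counting could not separate "ribosomes on the uORF" from
"ribosomes on the CDS". With ~30 nt footprints and a 24+ nt UTR-resident
span, shifting read starts from uORF2 to CDS moves measurable mass out of
the 5'UTR, and the mutant−control differences show the expected sign
pattern (uORF2 down, CDS up) in 100/100 seeded runs at 20 000 reads.

## Reporter statistics

Per-well ratio Renilla/Firefly (Firefly is the transfection control);
relative activity is the ratio divided by the mean control ratio —
normalization to the control mean, not per-replicate pairing, because
wells are independent transfections. Group comparison is Student's
pooled-variance two-tailed t-test (df = n₁ + n₂ − 2) by default, matching
the generic "unpaired t-test" convention; Welch's is available via
`equal_var=False`. The luciferase simulator plants a per-construct
relative activity, a shared lognormal transfection scale (CV 0.3) on both
channels — the nuisance the ratio cancels — and per-channel measurement
noise (CV 0.05 default).

## Pipeline determinism

One root seed; stage *k* derives its seed as
`SeedSequence([root, stage_index]) mod 2³¹` in the fixed stage order, so
toggling stages does not shift other stages' randomness. No output
contains timestamps; a rerun with the same config is byte-identical.

## What the simulations do not emulate

No raw reads, sequencing error, alignment ambiguity, or rRNA
contamination; no gene-length effects (counts are per gene, not per
kilobase); no tagwise dispersion variation between genes; no P-site
offsetting or codon periodicity in footprints; no plate or batch effects
in luciferase wells. Passing tests therefore demonstrate estimator
correctness against the assumed generative model, not robustness to the
full messiness of real libraries — in particular, real ERCC normalization
depends on alignment and mix-lot details the median-of-ratios rule
abstracts away.

## Problem sizes

The test and acceptance simulations use 2000 genes (100 planted effects),
92 spike-ins at ~10⁴ total spike counts per library, 20 000 footprints per
occupancy run (100 runs), 1000 random transcripts for scanner validation,
and 500 random indels — sizes at which every Monte-Carlo band in the suite
is comfortably resolved while a full run completes in seconds.
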