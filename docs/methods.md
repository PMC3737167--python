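# Methods

This note records the models behind each stage, the parameters that
matter, what the synthetic-data generator does and does not emulate,
and the numerical and design choices made where the design was open.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic data model (`simdata`)

**Population model.** Each locus has an ancestral allele frequency *p*
drawn from a configurable distribution (default uniform on
[0.05, 0.95]). The two population samples' frequencies are
Balding–Nichols draws: Beta(p(1−F)/F, (1−p)(1−F)/F), the standard
island-model frequency prior with divergence parameter F
(E[p_i] = p, Var[p_i] = F·p(1−p)). Neutral loci use `fst_neutral`
(default 0.03, the order of the background differentiation in a
strongly structured two-ecotype system) with independent draws per
population. Divergent loci use `fst_divergent` (default 0.4) with
**antithetically coupled** draws — p₁ = F⁻¹(U), p₂ = F⁻¹(1−U) on the
same Beta marginal. Rationale: diversifying selection drives ecotypes
in opposite directions; with independent draws roughly a third of
"divergent" loci land on the same side of *p* and carry no
between-population signal at all, which would make a planted-divergence
panel internally inconsistent (loci labelled divergent that are not).
Antithetic coupling preserves the marginal Balding–Nichols law while
realising the labelled divergence. The outlier-test null (below) keeps
fully independent draws.

**Ancestral-frequency modes.** `("uniform", lo, hi)` — the default
panel; note a uniform frequency spectrum is *not* neutral-equilibrium
(it over-represents intermediate frequencies and pushes Tajima's D
strongly positive). `("neutral_sfs", p_min)` — density ∝ 1/p truncated
at p_min; binomial sampling from it yields sample allele counts
∝ 1/i, the standard neutral spectrum, so windowed Tajima's D averages
≈ 0. `("fixed", p)` — degenerate, for planted classes.

**PSVs.** A paralogous sequence variant is simulated as two co-stacked
duplicated copies fixed for alternative bases: every individual's reads
at that tag are the union of two independent Poisson depth draws, one
copy per allele, so all individuals — doubled haploids included — show
both alleles near 50:50. This is the canonical PSV signature (ubiquitous
apparent heterozygosity) without simulating genome duplication. PSV
loci carry no true SNP; their true genotype table is monomorphic.

**Doubled haploids** (default 2) are homozygous at every non-PSV locus
by construction: one allele draw at the ancestral frequency, doubled.
They carry population label `reference` and are excluded from all
frequency-based statistics; their only analytic role is the PSV screen.

**Sequencing.** Depth is Poisson(`mean_depth`, default 30 — chosen as a
plausible genotyping depth; the genotype-scoring rule assumes depths of
this order) per locus/individual, optionally negative-binomial via
`depth_dispersion`. Heterozygote reads split 50:50 binomially; each
read flips allele with probability `error_rate` (default 0.005). Reads
are exact 89-bp allele sequences (the error model acts at the allele
level, not per base); read emission and the count matrix agree exactly,
so stacking emitted reads reproduces the counts.

**Discovery depth.** De novo discovery pools reads across the
discovery subset (default 20 individuals, mirroring a database built
from a small panel), and the stack-retention band [5, 200] presumes
pooled per-allele depths of order 10–200. `discovery_mean_depth`
(default 8) sets the per-individual depth of the emitted discovery
reads so that a 20-individual pool lands inside the band; genotyping
keeps the full `mean_depth`.

**Linkage map.** A configurable fraction (default 0.25) of loci is
placed uniformly on 29 chromosomes at uniform positions in
[0, `map_length_cm`]. Positions are genetic (cM), so the smoothing
bandwidth is specified in cM. Simulated loci are unlinked: D′ between
mapped markers reflects sampling noise only, which is the intended
negative control for the LD machinery (chromosome means shrink with
sample size).

**What the generator does not emulate.** Library/lane effects, base-call
quality, indels, multi-SNP tags (discovery tolerates them; the
generator plants one SNP per tag), genuine linkage/LD structure,
migration-drift non-equilibrium, and locus-specific depth biases.
Passing tests therefore demonstrate correctness of the inference chain
under its own model assumptions, not robustness to every artefact of
real libraries.

## Discovery

Stacks are exact-identity groups of 89-mers; depths outside [5, 200]
are discarded (bounds read literally from the retention rule: "fewer
than five" and "more than 200" are discarded, so 5 and 200 survive).
Candidate pairing is exact Hamming distance 1–3 with no indel
alignment (tags are fixed-length). Partner search uses a pigeonhole
index — four exact chunks of the tag; two sequences within distance 3
must share a chunk — which is semantically identical to exhaustive
pairwise comparison (a test checks this against a brute-force oracle)
but near-linear. Groups implying more than two alleles at any offset
are discarded; within a group each stack pairs greedily with its
highest-depth partner, ties broken toward the lexicographically smaller
sequence. Databases from multiple individual-subset comparisons are
merged on the allele-sequence pair, making the result independent of
subset order; ids are assigned after sorting, so they are stable.

## Genotype calling

The caller is a fixed-threshold rule on r = log₁₀(count_A/count_B):
total < 8 → missing (`low_depth`); |r| ≤ 0.61 → AB; r > 0.9 → AA;
r < −0.9 → BB; the gaps (0.61, 0.9] and [−0.9, −0.61) → missing
(`ambiguous_ratio`, kept as an explicit reason so filter reports can
count removed cells). A zero denominator maps to ±∞ rather than a
pseudocount, preserving (8, 0) → AA. The ±0.61 band is treated as a
fixed constant of the protocol, not re-estimated from data. No
likelihood model is attempted — fidelity to the thresholds is the
point; the caller is symmetric under allele swap and monotone in each
count, and both properties are property-tested.

## Filter cascade

Stage order: doubled-haploid PSV screen → heterozygosity excess
(≥ 90% of called genotypes heterozygous; the boundary is inclusive
removal) → missingness (> 50% removed; exactly 50% survives) → minor
allele frequency (< 2% removed; exactly 2% survives) → Hardy–Weinberg
(−log₁₀P > 5 removed) → optionally polymorphic-in-both-populations.
The order follows the narrative logic of removing technical artefacts
(PSVs) before population-genetic filters. A locus with zero non-missing
calls is removed at the heterozygosity stage with reason `all_missing`.

The HWE test is a two-sided exact test: the heterozygote count's
conditional distribution given the allele counts (Levene/Haldane) is
enumerated by recurrence and the p-value sums all configurations no
more probable than the observed one, with no mid-p correction — chosen
over the χ² approximation because post-MAF-filter expected counts can
still be small. A hand-written enumeration is used because no
pre-installed package exposes this test. HWE is tested within each
population for single-system datasets and on the pooled sample in
combined-dataset mode (`require_polymorphic_both=True`). Note the
interaction documented in `examples/config.yml`: pooled HWE on a
structured sample rejects strongly divergent loci (Wahlund effect), so
combined-dataset mode is deliberately conservative about outliers,
while single-system mode tests within populations and keeps them.

Frequency-based filters are computed over non-doubled-haploid
individuals at the time of the stage (no re-use of pre-filter counts).

## Per-locus and windowed statistics

Heterozygosities: H_O is the heterozygote fraction among non-missing
calls; H_E = H_T = 2p̄q̄ from pooled sample frequencies; H_S is the
unweighted mean of within-population 2p_i q_i. The default per-locus
F_ST is Nei's (H_T − H_S)/H_T (never negative for two demes);
Weir–Cockerham θ with the full a/b/c variance components (including the
observed-heterozygosity terms) is available, and the multilocus
estimate Σa/Σ(a+b+c) — nearly unbiased — is reported alongside the mean
of per-locus values, which is not. Reported per-locus values clip
negatives to zero; raw values are kept in `fst_raw`.

Tajima's D uses the standard constants a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂
as functions of the allele count n; π is the exact mean pairwise
difference from per-site minor-allele counts. One 89-bp tag is one
window under the 100-bp window setting. Sites need ≥ `min_coverage`
called genotypes (the genotype-level reading of a per-site depth
threshold, since allele counts here come from called genotypes rather
than pooled reads — pooled-sequencing bias corrections are deliberately
not reimplemented, genotype-derived counts being strictly more
informative) and ≥ `min_rare_count` copies of the rarer allele; n is
twice the called-individual count by default, or the nominal pool size
with `n_mode="pool"`.

**Known bias, by construction.** With one SNP per tag, the
`min_rare_count = 2` filter removes singleton windows from both π and
S; since Tajima's D is calibrated for the *unfiltered* number of
segregating sites, the filtered scan is shifted positive (the analytic
expectation at n = 100 is ≈ +0.25 per the truncated 1/i spectrum).
The neutrality check of the D machinery therefore runs with
`min_rare_count = 1`, where the statistic is unbiased under the
neutral-spectrum generator; the default configuration keeps the
protocol value 2, and its windowed output should be read relative to
the genome-wide distribution, not against 0.

## Outlier scan

The null is the same Balding–Nichols island model (independent draws,
ancestral frequencies uniform on [0.05, 0.95]), pushed through binomial
genotype sampling at the configured sample sizes and the same F_ST
estimator used for the observed loci — an expectation-equivalent,
desk-scale stand-in for an explicit coalescent island simulation.

Calibration: F is adjusted multiplicatively (common random numbers per
iteration, ≤50 iterations, tolerance 0.002 on the mean) until the mean
simulated F_ST matches the trimmed mean of the observed F_ST. The trim
envelope is the per-heterozygosity-bin 99% quantile of the current
null, applied to *both* sides: observed loci above their bin's envelope
leave the target mean, and the simulated mean is trimmed at the same
envelope. One-sided trimming (observed only) would equate a trimmed
target with an untrimmed simulated mean and bias F* low by the null's
own tail mass; symmetric trimming makes the fixed point self-consistent
(F* recovers the generating parameter on synthetic data, which is
tested).

Conditioning on heterozygosity uses equal-count quantile bins (default
20) merged below 50 simulations per bin — equal-count rather than
fixed-width because tail bins of a fixed grid starve and destabilise
the envelope quantiles. P is the within-bin fraction of simulated loci
strictly below the observed F_ST with ties counted half (avoiding
saturation at P = 1 on coarse grids). Classification: candidate
positive requires P > 0.995 *and* Benjamini–Hochberg rejection at FDR
0.05 applied to 1 − P (the empirical-probability analogue of the
scan's FDR setting); 0.1 < P < 0.9 is labelled neutral; everything else
unclassified. There is no balancing-selection class: under this null,
low-F_ST candidates are indistinguishable from loci with F_ST ≈ 0.

## LD and smoothing

Haplotype frequencies for each locus pair come from the standard
two-locus EM on the 3×3 genotype table (only the double heterozygote is
phase-ambiguous; convergence 1e−8 on frequencies, ≤1000 iterations; EM
equals direct gamete counting whenever no double heterozygotes exist,
which is tested). D′ = |D|/D_max with the usual sign-dependent D_max;
pairs with D_max = 0 or a monomorphic locus (pairwise-complete subset)
are skipped. Missing genotypes are handled pairwise-complete, not
listwise. Chromosome summaries average all same-chromosome pairs (an
optional per-chromosome cap subsamples pairs for very dense maps), and
the between-population comparison is a Welch two-tailed t-test on the
vectors of chromosome means.

Kernel smoothing evaluates Σw_j v_j / Σw_j with Gaussian weights
w_j = exp(−d²/2σ²) truncated at 3σ, on a fixed grid (default 0.5 cM)
rather than at marker positions only, so tracks are plottable and peak
regions (contiguous runs above a percentile, default 95th) are
definable. The bandwidth default of 5 cM is a map-space choice — a
physical-distance bandwidth has no direct analogue on a genetic map —
and smoothed tracks are qualitative descriptions, not test statistics.
Grid points with no marker within 3σ are gaps (NaN), not zeros.

## Numerical details and degenerate inputs

- Genotypes are int8 codes (AA=0, AB=1, BB=2, missing=−1); text forms
  `AA/AB/BB/NA`.
- Monomorphic pooled loci have undefined F_ST (NaN) and are excluded
  from means; the HWE convention for monomorphic input is p = 1.
- All randomness flows from explicit seeds; every simdata stage derives
  its generator from (stage constant, seed), so stages rerun
  independently still reproduce bit-identically, and the `pipeline`
  subcommand is deterministic end to end (tested byte-for-byte).
- Window evaluability requires S > 0 and n ≥ 4; Tajima's D is NaN
  otherwise and flagged, never silently zero.
- TSV round-trips use full float precision (`float_precision=
  "round_trip"` on read).

## Problem sizes

Default test and acceptance runs use panels of 400–5,000 loci, 50
diploids per population, 10,000–55,000 null simulations and three
replicates for rate estimates — sizes at which every documented
tolerance (caller concordance ≥99%, PSV recall ≥95%, F-recovery ±0.02,
KS < 0.02, type-I ≤1%, power ≥50%) is attainable and the whole suite
runs in well under a minute of compute per stage. These are the
package's reference conditions; larger panels only tighten the
Monte-Carlo tolerances.

## Known limitations

- The discovery stage assumes error-free-at-the-base-level reads (the
  generator's error model is allele-level); base-call errors would
  create singleton stacks that the depth-5 floor absorbs only at
  sufficient depth.
- The outlier null conditions on heterozygosity via binning, not on the
  joint (H_E, sample-size) configuration; loci with extreme missingness
  are compared against a null simulated at full sample size.
- Calibration matches means, not the full F_ST distribution; a
  demographic history whose neutral distribution differs in shape from
  Balding–Nichols at equal mean will mis-calibrate the envelope, as it
  does for every FDIST-family method.
- The windowed scan's `min_rare_count` bias (above) is inherent to
  count-filtered Tajima's D and is documented rather than corrected.
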