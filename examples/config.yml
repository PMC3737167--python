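# radpopgen run configuration.  Every key is optional; absent keys fall
# back to the defaults shown here.  The top-level seed drives all
# randomness (it propagates into the sim and outliers sections unless
# those set their own).

seed: 1
outdir: radpopgen_out
log_level: INFO
# individuals whose reads build the de novo SNP database
n_discovery_individuals: 20

sim:
  n_loci: 2000
  n_divergent: 100        # loci drawn with the divergent parameter
  n_psv: 50               # paralogous sequence variants (co-stacked duplicates)
  ancestral_freq: [uniform, 0.05, 0.95]  # or [neutral_sfs, 0.001] / [fixed, p]
  fst_neutral: 0.03       # background Balding-Nichols divergence
  fst_divergent: 0.4
  n_per_pop: 50           # diploids per population sample
  mean_depth: 30.0        # reads per locus per individual (genotyping)
  discovery_mean_depth: 8.0   # shallower reads pooled for locus discovery
  error_rate: 0.005       # per-read allele-flip probability
  n_doubled_haploid: 2
  n_chromosomes: 29
  map_length_cm: 100.0
  map_fraction: 0.25      # fraction of loci placed on the linkage map

thresholds:
  min_total_depth: 8      # genotypes scored only at >= 8 reads
  het_band: 0.61          # |log10(a/b)| <= band -> heterozygote
  hom_cutoff: 0.9         # log10(a/b) > cutoff -> AA; < -cutoff -> BB

filters:
  het_excess_max: 0.90    # remove loci >= 90% heterozygous calls
  maf_min: 0.02           # remove minor allele frequency < 2%
  missing_max: 0.50       # remove loci missing > 50% genotypes
  hwe_neglog10p_max: 5.0  # remove -log10 P(HWE exact) > 5
  # Combined-dataset mode: also require both alleles within each
  # population, and test HWE on the pooled sample instead of within
  # populations.  Leave false for a single two-ecotype system: pooled
  # HWE on a structured sample rejects strongly divergent loci (the
  # Wahlund effect), which is exactly the signal an outlier scan seeks.
  require_polymorphic_both: false

outliers:
  n_sims: 55000
  ci: 0.995               # candidate-positive probability threshold
  fdr: 0.05               # Benjamini-Hochberg level on 1 - P
  neutral_band: [0.1, 0.9]
  he_bins: 20             # equal-count heterozygosity bins for the null
  sample_sizes: [50, 50]

windows:
  window_bp: 100          # one window per 89-bp tag
  min_rare_count: 2
  min_coverage: 4         # minimum called genotypes per site
  pool_n: 50
  n_mode: called          # "called" (2 x called individuals) or "pool"

smoothing:
  sigma_cm: 5.0           # Gaussian bandwidth along the linkage map
  truncation_sigmas: 3.0
  grid_step_cm: 0.5
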