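"""Synthetic two-population RAD-seq data with known truth.

The generator emulates a two-ecotype sampling design: two population
samples whose allele frequencies diverge around a shared ancestral
frequency under a Balding–Nichols island model, a minority of loci under
divergent selection (drawn with a larger divergence parameter), paralogous
sequence variants (PSVs) arising from co-stacked duplicated loci, Poisson
sequencing depth with per-read allele-flip errors, doubled-haploid
reference individuals, and a partial linkage map in centimorgans.

Everything is deterministic given ``SimConfig.seed``: each stage derives
its random generator from the seed plus a fixed stage constant, so stages
may be re-run independently and still reproduce bit-identically.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import (
    AA, AB, BB,
    GenotypeMatrix,
    ParameterError,
    REFERENCE_POP,
    ReadCountMatrix,
)

TAG_LENGTH = 89  # bp per RAD tag after barcode/overhang trimming

NEUTRAL = "neutral"
DIVERGENT = "divergent"
PSV = "psv"

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# stage constants mixed into the seed so stages are independent streams
_STAGE_FREQS = 11
_STAGE_GENO = 23
_STAGE_READS = 37
_STAGE_EMIT = 41
_STAGE_MAP = 53


@dataclass(frozen=True)
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the emulated design: two samples of 50 diploids,
    ~30x expected genotyping depth, 0.5% per-read allele-flip error,
    background divergence 0.03 with selected loci at 0.4, two doubled
    haploids and a 29-chromosome map.  ``discovery_mean_depth`` is the
    shallower per-individual depth of the reads pooled for de novo locus
    discovery: database construction stacks reads across the discovery
    subset, and its [5, 200] stack-depth retention band presumes pooled
    per-allele depths of that order.
    """

    n_loci: int = 2000
    n_divergent: int = 0
    n_psv: int = 0
    ancestral_freq: tuple = ("uniform", 0.05, 0.95)
    fst_neutral: float = 0.03
    fst_divergent: float = 0.4
    n_per_pop: int = 50
    mean_depth: float = 30.0
    discovery_mean_depth: float = 8.0
    error_rate: float = 0.005
    n_doubled_haploid: int = 2
    n_chromosomes: int = 29
    map_length_cm: float = 100.0
    map_fraction: float = 0.25
    depth_dispersion: float | None = None  # NB size parameter; None = Poisson
    pop_names: tuple = ("migrant", "resident")
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fst_neutral < 1) or not (0 < self.fst_divergent < 1):
            raise ParameterError("divergence parameters must lie in (0, 1)")
        if self.fst_divergent <= self.fst_neutral:
            raise ParameterError("fst_divergent must exceed fst_neutral")
        if self.n_divergent + self.n_psv > self.n_loci:
            raise ParameterError("n_divergent + n_psv exceeds n_loci")
        for name in ("n_loci", "n_per_pop", "n_chromosomes"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if not (0 <= self.error_rate <= 0.1):
            raise ParameterError("error_rate must be in [0, 0.1]")
        if not (0 <= self.map_fraction <= 1):
            raise ParameterError("map_fraction must be in [0, 1]")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class PopulationTruth:
    """Per-locus truth: ancestral and population frequencies, class labels,
    parametric FST, and the tag sequences carrying each SNP."""

    table: pd.DataFrame  # index locus id

    @property
    def loci(self) -> pd.Index:
        return self.table.index

    def class_mask(self, label: str) -> np.ndarray:
        return (self.table["locus_class"] == label).to_numpy()


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([stage, config.seed])


def _draw_ancestral(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    spec = config.ancestral_freq
    kind = spec[0]
    if kind == "uniform":
        lo, hi = spec[1], spec[2]
        return rng.uniform(lo, hi, size=config.n_loci)
    if kind == "neutral_sfs":
        # density proportional to 1/p on [p_min, 1): the standard neutral
        # derived-allele spectrum; binomial sampling from it yields sample
        # counts proportional to 1/i.
        p_min = spec[1] if len(spec) > 1 else 1e-3
        u = rng.uniform(size=config.n_loci)
        return p_min ** (1.0 - u)
    if kind == "fixed":
        return np.full(config.n_loci, float(spec[1]))
    raise ParameterError(f"unknown ancestral_freq spec: {spec!r}")


def _balding_nichols(p: np.ndarray, F: float, rng: np.random.Generator) -> np.ndarray:
    """One population's frequencies given ancestral ``p`` and divergence F."""
    if not (0 < F < 1):
        raise ParameterError("divergence parameter F must lie in (0, 1)")
    scale = (1.0 - F) / F
    return rng.beta(np.maximum(p * scale, 1e-12), np.maximum((1.0 - p) * scale, 1e-12))


def draw_population_frequencies(config: SimConfig,
                                rng: np.random.Generator | None = None) -> PopulationTruth:
    """Draw per-locus ancestral and population allele frequencies.

    Each population's frequency is an independent Beta draw with
    parameters ``p(1-F)/F`` and ``(1-p)(1-F)/F`` (Balding–Nichols), with
    ``F`` the class-specific divergence parameter.  PSV loci carry no true
    SNP (both duplicated copies are fixed); their frequencies are set to
    the degenerate values of a fixed difference between copies.
    """
    rng = _rng(config, _STAGE_FREQS) if rng is None else rng
    n = config.n_loci
    p = _draw_ancestral(config, rng)

    classes = np.array([NEUTRAL] * n, dtype=object)
    # deterministic placement: divergent loci first, PSVs last
    classes[: config.n_divergent] = DIVERGENT
    if config.n_psv:
        classes[n - config.n_psv:] = PSV

    p1 = np.empty(n)
    p2 = np.empty(n)
    m = classes == NEUTRAL
    p1[m] = _balding_nichols(p[m], config.fst_neutral, rng)
    p2[m] = _balding_nichols(p[m], config.fst_neutral, rng)
    m = classes == DIVERGENT
    if m.any():
        # diversifying selection pushes the ecotypes in opposite directions:
        # antithetic Beta draws share the Balding-Nichols marginals but are
        # maximally negatively coupled, so the drawn divergence is realised
        # as a between-population difference rather than a shared drift
        F = config.fst_divergent
        if not (0 < F < 1):
            raise ParameterError("divergence parameter F must lie in (0, 1)")
        scale = (1.0 - F) / F
        u = rng.uniform(size=int(m.sum()))
        a = np.maximum(p[m] * scale, 1e-12)
        b = np.maximum((1.0 - p[m]) * scale, 1e-12)
        p1[m] = sps.beta.ppf(u, a, b)
        p2[m] = sps.beta.ppf(1.0 - u, a, b)
    psv_mask = classes == PSV
    # copy 1 fixed for A in both populations; the co-stacked paralog is
    # fixed for B, so the apparent SNP is ubiquitous heterozygosity
    p1[psv_mask] = 1.0
    p2[psv_mask] = 1.0

    pbar = 0.5 * (p1 + p2)
    hs = 0.5 * (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2))
    ht = 2 * pbar * (1 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst_true = np.where(ht > 0, (ht - hs) / ht, 0.0)

    # tag sequences: random 89-mer per locus with the SNP at a random offset
    seq_mat = _BASES[rng.integers(0, 4, size=(n, TAG_LENGTH))]
    snp_pos = rng.integers(0, TAG_LENGTH, size=n)
    ref_base = seq_mat[np.arange(n), snp_pos]
    alt_shift = rng.integers(1, 4, size=n)
    alt_base = _BASES[(np.searchsorted(_BASES, ref_base) + alt_shift) % 4]

    loci = pd.Index([f"L{i:06d}" for i in range(n)], name="locus")
    table = pd.DataFrame(
        {
            "p_anc": p,
            "p_pop1": p1,
            "p_pop2": p2,
            "locus_class": classes,
            "fst_true": fst_true,
            "seq_a": [row.tobytes().decode() for row in seq_mat],
            "snp_pos": snp_pos + 1,  # 1-based within the tag
            "alt_base": [b.decode() for b in alt_base],
        },
        index=loci,
    )
    return PopulationTruth(table)


def allele_b_sequence(seq_a: str, snp_pos_1based: int, alt_base: str) -> str:
    i = snp_pos_1based - 1
    return seq_a[:i] + alt_base + seq_a[i + 1:]


def sample_genotypes(truth: PopulationTruth, config: SimConfig,
                     rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw true genotypes: binomial(2, population frequency) per individual.

    Doubled haploids carry two identical copies of one allele draw at every
    non-PSV locus and therefore are never heterozygous.  At PSV loci all
    individuals are homozygous for copy 1 (the apparent heterozygosity of a
    PSV is a read-level artifact produced in :func:`simulate_read_counts`).
    """
    rng = _rng(config, _STAGE_GENO) if rng is None else rng
    t = truth.table
    n_loci = len(t)
    pop1, pop2 = config.pop_names

    names, pops, dh_flags = [], [], []
    for pop in (pop1, pop2):
        for i in range(config.n_per_pop):
            names.append(f"{pop}_{i + 1:03d}")
            pops.append(pop)
            dh_flags.append(False)
    for i in range(config.n_doubled_haploid):
        names.append(f"dh_{i + 1}")
        pops.append(REFERENCE_POP)
        dh_flags.append(True)

    p1 = t["p_pop1"].to_numpy()[:, None]
    p2 = t["p_pop2"].to_numpy()[:, None]
    g1 = rng.binomial(2, np.broadcast_to(p1, (n_loci, config.n_per_pop)))
    g2 = rng.binomial(2, np.broadcast_to(p2, (n_loci, config.n_per_pop)))
    # genotype code: number of B alleles; frequency columns are for allele A
    calls = np.concatenate([2 - g1, 2 - g2], axis=1)

    if config.n_doubled_haploid:
        p_anc = t["p_anc"].to_numpy()[:, None]
        hap = rng.binomial(
            1, np.broadcast_to(p_anc, (n_loci, config.n_doubled_haploid))
        )
        calls = np.concatenate([calls, 2 * (1 - hap)], axis=1)

    psv = truth.class_mask(PSV)
    calls[psv, :] = AA

    metadata = pd.DataFrame(
        {
            "population": pops,
            "phenotype": [p if p != REFERENCE_POP else "none" for p in pops],
            "doubled_haploid": dh_flags,
        },
        index=pd.Index(names, name="individual"),
    )
    return GenotypeMatrix(
        loci=t.index, individuals=metadata.index,
        calls=calls.astype(np.int8), metadata=metadata,
    )


def _draw_depth(shape, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    if config.depth_dispersion is None:
        return rng.poisson(config.mean_depth, size=shape)
    k = config.depth_dispersion
    lam = rng.gamma(k, config.mean_depth / k, size=shape)
    return rng.poisson(lam)


def simulate_read_counts(genotypes: GenotypeMatrix, truth: PopulationTruth,
                         config: SimConfig,
                         rng: np.random.Generator | None = None) -> ReadCountMatrix:
    """Simulate per-allele read counts from true genotypes.

    Depth is Poisson(mean_depth) per locus/individual (negative-binomial if
    ``depth_dispersion`` is set).  Heterozygote reads split 50:50
    binomially; each read then flips allele with probability
    ``error_rate``.  PSV loci emit the union of two duplicated copies fixed
    for alternative bases, so every individual — including doubled
    haploids — shows both alleles at roughly equal depth.
    """
    rng = _rng(config, _STAGE_READS) if rng is None else rng
    calls = genotypes.calls
    shape = calls.shape
    e = config.error_rate

    depth = _draw_depth(shape, config, rng)
    true_a = np.where(calls == AA, depth, 0)
    het = calls == AB
    true_a[het] = rng.binomial(depth[het], 0.5)

    psv = truth.class_mask(PSV)
    if psv.any():
        extra = _draw_depth((int(psv.sum()), shape[1]), config, rng)
        depth = depth.copy()
        depth[psv] += extra  # copy-2 reads, all allele B

    true_b = depth - true_a
    if e > 0:
        counts_a = rng.binomial(true_a, 1 - e) + rng.binomial(true_b, e)
    else:
        counts_a = true_a
    counts_b = depth - counts_a
    return ReadCountMatrix(
        loci=genotypes.loci, individuals=genotypes.individuals,
        counts_a=counts_a, counts_b=counts_b,
    )


def emit_reads(genotypes: GenotypeMatrix, truth: PopulationTruth,
               config: SimConfig, path,
               counts: ReadCountMatrix | None = None,
               fmt: str = "fasta",
               rng: np.random.Generator | None = None) -> int:
    """Write simulated 89-bp reads to FASTA or FASTQ; returns the read count.

    Reads are exact copies of the allele-A or allele-B tag sequence; the
    error model acts at the allele level (a read drawn from the wrong
    allele), matching :func:`simulate_read_counts`, whose counts are used
    verbatim when supplied.  Read ids are ``individual:locus:serial``.
    """
    if counts is None:
        counts = simulate_read_counts(
            genotypes, truth, config,
            rng=_rng(config, _STAGE_EMIT) if rng is None else rng,
        )
    t = truth.table
    seq_a = t["seq_a"].to_numpy()
    seq_b = np.array([
        allele_b_sequence(s, p, a)
        for s, p, a in zip(t["seq_a"], t["snp_pos"], t["alt_base"])
    ])
    individuals = list(genotypes.individuals)
    loci = list(t.index)
    qual = "I" * TAG_LENGTH
    n_written = 0
    chunks: list[str] = []
    with open(path, "w") as fh:
        for li, locus in enumerate(loci):
            sa, sb = seq_a[li], seq_b[li]
            for ii, ind in enumerate(individuals):
                for seq, k in ((sa, counts.counts_a[li, ii]),
                               (sb, counts.counts_b[li, ii])):
                    for r in range(int(k)):
                        rid = f"{ind}:{locus}:{n_written}"
                        if fmt == "fasta":
                            chunks.append(f">{rid}\n{seq}\n")
                        else:
                            chunks.append(f"@{rid}\n{seq}\n+\n{qual}\n")
                        n_written += 1
                if len(chunks) > 20000:
                    fh.write("".join(chunks))
                    chunks.clear()
        fh.write("".join(chunks))
    return n_written


def generate_linkage_map(loci, config: SimConfig,
                         fraction: float | None = None,
                         rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Assign a fraction of loci (default ``config.map_fraction``) to
    chromosomes and uniform cM positions; the rest stay unmapped.

    Returns a DataFrame (marker, chromosome, position_cm) covering mapped
    markers only.
    """
    rng = _rng(config, _STAGE_MAP) if rng is None else rng
    loci = pd.Index(loci)
    frac = config.map_fraction if fraction is None else fraction
    n = len(loci)
    n_mapped = int(round(frac * n))
    idx = np.sort(rng.choice(n, size=n_mapped, replace=False))
    chroms = rng.integers(1, config.n_chromosomes + 1, size=n_mapped)
    pos = rng.uniform(0.0, config.map_length_cm, size=n_mapped)
    return pd.DataFrame(
        {
            "marker": loci[idx],
            "chromosome": [f"chr{c:02d}" for c in chroms],
            "position_cm": pos,
        }
    )


@dataclass
class SimulatedDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    config: SimConfig
    truth: PopulationTruth
    genotypes: GenotypeMatrix  # true genotypes, not calls
    read_counts: ReadCountMatrix
    linkage_map: pd.DataFrame


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator: truth, genotypes, read counts and map."""
    truth = draw_population_frequencies(config)
    genotypes = sample_genotypes(truth, config)
    read_counts = simulate_read_counts(genotypes, truth, config)
    linkage_map = generate_linkage_map(truth.loci, config)
    return SimulatedDataset(config, truth, genotypes, read_counts, linkage_map)
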