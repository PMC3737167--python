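"""SNP quality-control filter cascade.

Stages, in fixed order:

1. ``dh_psv``      — loci heterozygous in any doubled haploid (paralogous
                     sequence variants) are removed;
2. ``het_excess``  — loci with >= 90% heterozygous calls removed (the
                     residual PSV signature);
3. ``missing``     — loci missing > 50% of genotypes removed;
4. ``maf``         — minor allele frequency < 2% removed;
5. ``hwe``         — exact Hardy–Weinberg test, -log10 P > 5 removed;
6. ``polymorphic_both`` (optional, combined datasets) — loci must show
                     two alleles within each population separately.

Frequency-based stages are computed over non-doubled-haploid individuals;
the doubled haploids are reference material for PSV detection only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import AB, MISSING, GenotypeMatrix, ParameterError


@dataclass(frozen=True)
class FilterConfig:
    het_excess_max: float = 0.90
    maf_min: float = 0.02
    missing_max: float = 0.50
    hwe_neglog10p_max: float = 5.0
    require_polymorphic_both: bool = False

    def __post_init__(self) -> None:
        for name in ("het_excess_max", "maf_min", "missing_max"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ParameterError(f"{name} must lie in (0, 1)")
        if self.hwe_neglog10p_max <= 0:
            raise ParameterError("hwe_neglog10p_max must be positive")


@dataclass
class FilterReport:
    """Ordered per-stage bookkeeping: loci in, removed, out."""

    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def add(self, name: str, n_in: int, n_removed: int) -> None:
        self.stages.append(
            {"stage": name, "loci_in": n_in, "loci_removed": n_removed,
             "loci_out": n_in - n_removed}
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.stages, columns=["stage", "loci_in", "loci_removed", "loci_out"]
        )

    def lines(self) -> list[str]:
        out = [
            f"{s['stage']}: {s['loci_in']} in, {s['loci_removed']} removed, "
            f"{s['loci_out']} out"
            for s in self.stages
        ]
        return out + [f"warning: {w}" for w in self.warnings]


def detect_psv_doubled_haploid(matrix: GenotypeMatrix) -> np.ndarray:
    """Boolean mask of loci called heterozygous in any doubled haploid.

    A doubled haploid carries two identical genome copies, so a
    heterozygous call in one marks the locus as a paralogous sequence
    variant (two co-stacked duplicated loci), not a true SNP.
    """
    dh = matrix.individual_mask(doubled_haploid=True)
    if not dh.any():
        raise ParameterError("no doubled-haploid individuals present")
    return (matrix.calls[:, dh] == AB).any(axis=1)


def het_excess_fraction(matrix: GenotypeMatrix,
                        mask: np.ndarray | None = None) -> np.ndarray:
    calls = matrix.calls if mask is None else matrix.calls[:, mask]
    called = (calls != MISSING).sum(axis=1)
    het = (calls == AB).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(called > 0, het / called, np.nan)


def filter_het_excess(matrix: GenotypeMatrix, het_excess_max: float = 0.90,
                      mask: np.ndarray | None = None) -> np.ndarray:
    """Keep-mask: loci whose heterozygote fraction is below the cutoff.

    The cutoff is removal at >= ``het_excess_max`` (a 90%-heterozygous
    locus is removed); loci with zero non-missing calls are removed too.
    """
    frac = het_excess_fraction(matrix, mask)
    return ~(np.isnan(frac) | (frac >= het_excess_max))


def filter_missing(matrix: GenotypeMatrix, missing_max: float = 0.50,
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Keep-mask: loci with missing fraction <= ``missing_max`` (strictly
    more than the cutoff is removed)."""
    calls = matrix.calls if mask is None else matrix.calls[:, mask]
    frac = (calls == MISSING).sum(axis=1) / calls.shape[1]
    return frac <= missing_max


def minor_allele_frequency(matrix: GenotypeMatrix,
                           mask: np.ndarray | None = None) -> np.ndarray:
    p = matrix.allele_freq(mask)
    return np.fmin(p, 1.0 - p)


def filter_maf(matrix: GenotypeMatrix, maf_min: float = 0.02,
               mask: np.ndarray | None = None) -> np.ndarray:
    """Keep-mask: minor allele frequency >= ``maf_min`` (strictly below is
    removed, so a locus at exactly 2% survives); all-missing loci are
    removed."""
    maf = minor_allele_frequency(matrix, mask)
    return ~np.isnan(maf) & (maf >= maf_min)


def hwe_exact_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Two-sided exact Hardy–Weinberg test p-value.

    Enumerates every heterozygote count consistent with the observed
    allele counts and sums the probabilities of configurations no more
    probable than the observed one (Wigginton-style, no mid-p).
    Monomorphic input returns 1 by convention.
    """
    if min(n_aa, n_ab, n_bb) < 0:
        raise ParameterError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if n < 1:
        raise ParameterError("at least one genotype is required")
    n_rare = 2 * min(n_aa, n_bb) + n_ab
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    # probabilities over het counts with the parity of n_rare, via the
    # standard recurrence; normalised at the end
    het_min = n_rare % 2
    hets = list(range(het_min, min(n_rare, 2 * n - n_rare) + 1, 2))
    probs = {}
    h = hets[0]
    probs[h] = 1.0
    for h in hets[:-1]:
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        # move two rare alleles from homozygote into two heterozygotes
        probs[h + 2] = probs[h] * (4.0 * rare_hom * common_hom) / ((h + 2.0) * (h + 1.0))
    total = sum(probs.values())
    obs = probs[n_ab]
    # tolerance guards against float noise when comparing equal configs
    p = sum(v for v in probs.values() if v <= obs * (1 + 1e-12)) / total
    return min(p, 1.0)


def hwe_pvalues(matrix: GenotypeMatrix,
                mask: np.ndarray | None = None) -> np.ndarray:
    n_aa, n_ab, n_bb, _ = matrix.counts(mask)
    out = np.ones(len(matrix.loci))
    for i in range(len(out)):
        tot = n_aa[i] + n_ab[i] + n_bb[i]
        if tot >= 1:
            out[i] = hwe_exact_test(int(n_aa[i]), int(n_ab[i]), int(n_bb[i]))
    return out


def filter_hwe(matrix: GenotypeMatrix, neglog10p_max: float = 5.0,
               mask: np.ndarray | None = None,
               per_population: bool = False) -> np.ndarray:
    """Keep-mask: loci not out of Hardy-Weinberg equilibrium.

    Removal when -log10 P exceeds the threshold.  With ``per_population``
    the test runs within each population and a locus is removed if it
    fails in any of them (population datasets); otherwise the test is
    pooled over the masked individuals (combined dataset).
    """
    if not per_population:
        p = hwe_pvalues(matrix, mask)
        return -np.log10(np.maximum(p, 1e-300)) <= neglog10p_max
    keep = np.ones(len(matrix.loci), dtype=bool)
    for pop in matrix.populations:
        pm = matrix.individual_mask(population=pop)
        if mask is not None:
            pm &= mask
        p = hwe_pvalues(matrix, pm)
        keep &= -np.log10(np.maximum(p, 1e-300)) <= neglog10p_max
    return keep


def require_polymorphic_both(matrix: GenotypeMatrix,
                             populations: list[str] | None = None) -> np.ndarray:
    """Keep-mask: loci with two observed alleles within each population."""
    pops = populations or matrix.populations
    if len(pops) != 2:
        raise ParameterError(f"exactly two populations required, got {pops}")
    keep = np.ones(len(matrix.loci), dtype=bool)
    for pop in pops:
        pm = matrix.individual_mask(population=pop)
        if not pm.any():
            raise ParameterError(f"population {pop!r} has no individuals")
        maf = minor_allele_frequency(matrix, pm)
        keep &= ~np.isnan(maf) & (maf > 0)
    return keep


def run_filter_cascade(matrix: GenotypeMatrix,
                       config: FilterConfig = FilterConfig()
                       ) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply all stages in order and report per-stage survivor counts."""
    report = FilterReport()
    current = matrix
    analysis = None  # recomputed after each subset

    def apply(name: str, keep: np.ndarray) -> None:
        nonlocal current
        report.add(name, len(current.loci), int((~keep).sum()))
        current = current.subset_loci(keep)

    try:
        psv = detect_psv_doubled_haploid(current)
        apply("dh_psv", ~psv)
    except ParameterError as err:
        report.warnings.append(f"dh_psv skipped: {err}")
        warnings.warn(str(err), stacklevel=2)
        report.add("dh_psv", len(current.loci), 0)

    analysis = current.analysis_mask()
    apply("het_excess",
          filter_het_excess(current, config.het_excess_max, analysis))
    apply("missing", filter_missing(current, config.missing_max, analysis))
    apply("maf", filter_maf(current, config.maf_min, analysis))
    apply("hwe", filter_hwe(current, config.hwe_neglog10p_max, analysis,
                            per_population=not config.require_polymorphic_both))
    if config.require_polymorphic_both:
        apply("polymorphic_both", require_polymorphic_both(current))
    return current, report
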