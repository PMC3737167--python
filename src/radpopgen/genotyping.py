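"""Genotype calling from per-allele read counts by log10 read-ratio.

A genotype is scored only when the total read count reaches 8.  With
``r = log10(count_A / count_B)`` (zero denominators mapped to +/-inf):
heterozygous for r in [-0.61, 0.61], AA for r > 0.9, BB for r < -0.9.
Ratios falling in the gaps between the bands yield a missing call with an
explicit ``ambiguous_ratio`` reason so filter reports can count them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    AA, AB, BB, MISSING,
    GenotypeMatrix,
    InputError,
    ReadCountMatrix,
)

# call reasons
CALLED = 0
LOW_DEPTH = 1
AMBIGUOUS_RATIO = 2

REASON_NAMES = {CALLED: "called", LOW_DEPTH: "low_depth",
                AMBIGUOUS_RATIO: "ambiguous_ratio"}


@dataclass(frozen=True)
class GenotypeThresholds:
    """Read-ratio calling thresholds."""

    min_total_depth: int = 8
    het_band: float = 0.61     # |r| <= het_band -> heterozygote
    hom_cutoff: float = 0.9    # r > cutoff -> AA; r < -cutoff -> BB

    def __post_init__(self) -> None:
        if self.het_band <= 0 or self.hom_cutoff <= self.het_band:
            raise InputError("hom cutoff must lie outside the het band")


DEFAULT_THRESHOLDS = GenotypeThresholds()


@dataclass(frozen=True)
class GenotypeCall:
    state: int   # AA / AB / BB / MISSING
    reason: int  # CALLED / LOW_DEPTH / AMBIGUOUS_RATIO

    @property
    def state_name(self) -> str:
        from .core import CODE_TO_STR
        return CODE_TO_STR[self.state]

    @property
    def reason_name(self) -> str:
        return REASON_NAMES[self.reason]


def log10_ratio(count_a: float, count_b: float) -> float:
    if count_a < 0 or count_b < 0:
        raise InputError("read counts must be non-negative")
    if count_b == 0:
        return np.inf if count_a > 0 else np.nan
    if count_a == 0:
        return -np.inf
    return float(np.log10(count_a / count_b))


def call_genotype(count_a: int, count_b: int,
                  thresholds: GenotypeThresholds = DEFAULT_THRESHOLDS) -> GenotypeCall:
    """Call one genotype from a pair of allele read counts."""
    if count_a < 0 or count_b < 0:
        raise InputError("read counts must be non-negative")
    if count_a + count_b < thresholds.min_total_depth:
        return GenotypeCall(MISSING, LOW_DEPTH)
    r = log10_ratio(count_a, count_b)
    if -thresholds.het_band <= r <= thresholds.het_band:
        return GenotypeCall(AB, CALLED)
    if r > thresholds.hom_cutoff:
        return GenotypeCall(AA, CALLED)
    if r < -thresholds.hom_cutoff:
        return GenotypeCall(BB, CALLED)
    return GenotypeCall(MISSING, AMBIGUOUS_RATIO)


def call_matrix(read_counts: ReadCountMatrix, metadata,
                thresholds: GenotypeThresholds = DEFAULT_THRESHOLDS) -> GenotypeMatrix:
    """Vectorised elementwise :func:`call_genotype` over a count matrix.

    ``metadata`` must cover every individual in the counts (population,
    phenotype, doubled_haploid); it is carried through onto the result.
    """
    a = read_counts.counts_a.astype(np.float64)
    b = read_counts.counts_b.astype(np.float64)
    total = a + b

    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.log10(a) - np.log10(b)  # ±inf when one count is zero
    calls = np.full(a.shape, MISSING, dtype=np.int8)
    reasons = np.full(a.shape, LOW_DEPTH, dtype=np.int8)

    deep = total >= thresholds.min_total_depth
    het = deep & (np.abs(r) <= thresholds.het_band)
    hom_a = deep & (r > thresholds.hom_cutoff)
    hom_b = deep & (r < -thresholds.hom_cutoff)
    calls[het] = AB
    calls[hom_a] = AA
    calls[hom_b] = BB
    reasons[deep] = AMBIGUOUS_RATIO
    reasons[het | hom_a | hom_b] = CALLED

    return GenotypeMatrix(
        loci=read_counts.loci,
        individuals=read_counts.individuals,
        calls=calls,
        metadata=metadata,
        reasons=reasons,
    )
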