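"""Independent brute-force oracles used to cross-check the package.

Everything here is written from first principles (exact rational
arithmetic where possible) and deliberately shares no code with
radpopgen: these are the reference values the implementation must hit.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction


# ---------------------------------------------------------------------------
# Tajima's D machinery, exact per the 1989 definitions

def tajima_d_oracle(pi: float, S: int, n: int) -> float:
    """Tajima's D from scratch with rational constants."""
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return (pi - S / float(a1)) / math.sqrt(float(var))


def pi_from_site_counts(minor_counts, n: int) -> float:
    """Mean pairwise differences by literally comparing all allele pairs."""
    total_pairs = n * (n - 1) // 2
    diffs = 0
    for k in minor_counts:
        diffs += k * (n - k)  # pairs differing at this site
    return diffs / total_pairs


def site_frequency_configurations(n: int, max_s: int):
    """All multisets of per-site minor... derived allele counts 1..n-1 with
    1..max_s sites."""
    for s in range(1, max_s + 1):
        yield from itertools.combinations_with_replacement(range(1, n), s)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test by direct multinomial enumeration

def hwe_exact_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE p-value from the conditional distribution of the
    heterozygote count given the allele counts, computed with exact
    factorials (Levene/Haldane distribution)."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    if n_a == 0 or n_b == 0:
        return 1.0

    def prob(h: int) -> Fraction:
        # P(N_AB = h | allele counts) = n! / (naa! nab! nbb!) * na! nb! /
        #   (2n)! * 2^h  with naa=(n_a-h)/2 etc.
        if (n_a - h) % 2 or h > min(n_a, n_b) or (n_a - h) < 0 or (n_b - h) < 0:
            return Fraction(0)
        naa = (n_a - h) // 2
        nbb = (n_b - h) // 2
        num = (
            Fraction(math.factorial(n), math.factorial(naa)
                     * math.factorial(h) * math.factorial(nbb))
            * math.factorial(n_a) * math.factorial(n_b) * 2 ** h
        )
        return num / math.factorial(2 * n)

    p_obs = prob(n_ab)
    total = Fraction(0)
    p_sum = Fraction(0)
    for h in range(0, min(n_a, n_b) + 1):
        p_h = prob(h)
        total += p_h
        if p_h <= p_obs:
            p_sum += p_h
    return float(p_sum / total)


# ---------------------------------------------------------------------------
# exhaustive stack pairing (discovery oracle)

def exhaustive_pairs(sequences, max_mismatch: int = 3):
    """All unordered index pairs within the mismatch radius, by direct
    comparison of every pair."""
    out = set()
    for i, j in itertools.combinations(range(len(sequences)), 2):
        d = sum(a != b for a, b in zip(sequences[i], sequences[j]))
        if 1 <= d <= max_mismatch:
            out.add((i, j))
    return out


# ---------------------------------------------------------------------------
# direct haplotype counting when phase is unambiguous

def haplotype_freqs_by_counting(genotype_pairs):
    """Haplotype frequencies (AB, Ab, aB, ab) by direct gamete counting.

    ``genotype_pairs`` is a list of (g1, g2) with g in {0: hom A, 1: het,
    2: hom a}; raises if any individual is a double heterozygote (phase
    ambiguous).
    """
    counts = {"AB": 0, "Ab": 0, "aB": 0, "ab": 0}
    for g1, g2 in genotype_pairs:
        if g1 == 1 and g2 == 1:
            raise ValueError("phase-ambiguous double heterozygote")
        first = {0: "AA", 1: "Aa", 2: "aa"}[g1]
        second = {0: "BB", 1: "Bb", 2: "bb"}[g2]
        for hap in (first[0] + second[0], first[1] + second[1]):
            counts[hap] += 1
    total = sum(counts.values())
    return tuple(counts[k] / total for k in ("AB", "Ab", "aB", "ab"))
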