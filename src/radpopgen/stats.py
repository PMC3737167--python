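"""Per-locus and windowed population-genetic statistics.

Per-locus: observed/expected heterozygosity, Nei and Weir–Cockerham
pairwise FST, private alleles.  Windowed (one 89-bp tag is one window
under the 100-bp setting): segregating sites S, mean pairwise diversity
pi, Watterson's theta ``S/a1(n)`` and Tajima's D with the standard
constants

    a1 = sum_{i<n} 1/i          a2 = sum_{i<n} 1/i^2
    b1 = (n+1)/(3(n-1))         b2 = 2(n^2+n+3)/(9n(n-1))
    c1 = b1 - 1/a1              c2 = b2 - (n+2)/(a1 n) + a2/a1^2
    e1 = c1/a1                  e2 = c2/(a1^2 + a2)

    D = (pi - S/a1) / sqrt(e1 S + e2 S (S-1))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AB, MISSING, GenotypeMatrix, ParameterError


# ---------------------------------------------------------------------------
# heterozygosities and FST

def _pop_masks(matrix: GenotypeMatrix, populations=None):
    pops = list(populations) if populations is not None else matrix.populations
    if len(pops) != 2:
        raise ParameterError(f"exactly two populations required, got {pops}")
    masks = []
    for pop in pops:
        m = matrix.individual_mask(population=pop)
        if not m.any():
            raise ParameterError(f"population {pop!r} has no individuals")
        masks.append(m)
    return pops, masks


def heterozygosities(matrix: GenotypeMatrix, populations=None) -> pd.DataFrame:
    """Per-locus H_O, H_E, H_S, H_T.

    H_O is the heterozygote fraction among non-missing calls (pooled over
    both populations); H_E = 1 - p^2 - q^2 from pooled frequencies (= H_T);
    H_S is the unweighted mean of within-population H_E.
    """
    pops, masks = _pop_masks(matrix, populations)
    both = masks[0] | masks[1]
    calls = matrix.calls[:, both]
    called = (calls != MISSING).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        h_o = np.where(called > 0, (calls == AB).sum(axis=1) / called, np.nan)
    p_pool = matrix.allele_freq(both)
    h_t = 2 * p_pool * (1 - p_pool)
    p1 = matrix.allele_freq(masks[0])
    p2 = matrix.allele_freq(masks[1])
    h_s = 0.5 * (2 * p1 * (1 - p1) + 2 * p2 * (1 - p2))
    return pd.DataFrame(
        {"h_o": h_o, "h_e": h_t, "h_s": h_s, "h_t": h_t,
         "p_" + pops[0]: p1, "p_" + pops[1]: p2},
        index=matrix.loci,
    )


def nei_fst(p1, p2) -> np.ndarray:
    """Nei FST (G_ST for two demes): (H_T - H_S) / H_T from frequencies."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    pbar = 0.5 * (p1 + p2)
    h_t = 2 * pbar * (1 - pbar)
    h_s = p1 * (1 - p1) + p2 * (1 - p2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(h_t > 0, (h_t - h_s) / h_t, np.nan)


def weir_cockerham_components(n1, p1, h1, n2, p2, h2):
    """Weir & Cockerham variance components (a, b, c) for two populations.

    ``n`` are sampled-individual counts, ``p`` allele-A frequencies and
    ``h`` observed heterozygote frequencies; all may be arrays over loci.
    theta = a / (a + b + c).
    """
    n1 = np.asarray(n1, dtype=float)
    n2 = np.asarray(n2, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    h1 = np.asarray(h1, dtype=float)
    h2 = np.asarray(h2, dtype=float)
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    return a, b, c


def pairwise_fst(matrix: GenotypeMatrix, populations=None,
                 method: str = "nei") -> pd.DataFrame:
    """Per-locus pairwise FST between two populations, plus summaries.

    ``method`` is ``"nei"`` ((H_T - H_S)/H_T, the per-locus default) or
    ``"wc"`` (Weir–Cockerham theta).  The ``fst`` column clips negative
    estimates to 0 (reported ranges start at 0); ``fst_raw`` keeps the
    unclipped value.  Loci monomorphic in the pooled sample are NaN and
    excluded from means.  The frame carries two scalar attrs:
    ``mean_fst`` (mean of clipped per-locus values) and
    ``fst_multilocus`` (WC ratio-of-sums, a nearly unbiased multilocus
    estimate; for Nei, the (H_T-H_S)/H_T of summed heterozygosities).
    """
    pops, masks = _pop_masks(matrix, populations)
    p1 = matrix.allele_freq(masks[0])
    p2 = matrix.allele_freq(masks[1])
    if method == "nei":
        raw = nei_fst(p1, p2)
        pbar = 0.5 * (p1 + p2)
        h_t = 2 * pbar * (1 - pbar)
        h_s = p1 * (1 - p1) + p2 * (1 - p2)
        ok = ~np.isnan(raw)
        multilocus = float(
            (h_t[ok].sum() - h_s[ok].sum()) / h_t[ok].sum()
        ) if ok.any() else np.nan
    elif method == "wc":
        counts1 = _pop_genotype_counts(matrix, masks[0])
        counts2 = _pop_genotype_counts(matrix, masks[1])
        a, b, c = weir_cockerham_components(*counts1, *counts2)
        with np.errstate(invalid="ignore", divide="ignore"):
            raw = a / (a + b + c)
        ok = np.isfinite(raw)
        denom = (a + b + c)[ok].sum()
        multilocus = float(a[ok].sum() / denom) if ok.any() and denom > 0 else np.nan
    else:
        raise ParameterError(f"unknown FST method {method!r}")

    clipped = np.clip(raw, 0.0, 1.0)
    frame = pd.DataFrame(
        {"fst": clipped, "fst_raw": raw,
         "p_" + pops[0]: p1, "p_" + pops[1]: p2},
        index=matrix.loci,
    )
    frame.attrs["mean_fst"] = float(np.nanmean(clipped)) if ok.any() else np.nan
    frame.attrs["fst_multilocus"] = multilocus
    frame.attrs["method"] = method
    return frame


def _pop_genotype_counts(matrix: GenotypeMatrix, mask: np.ndarray):
    n_aa, n_ab, n_bb, _ = matrix.counts(mask)
    n = n_aa + n_ab + n_bb
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n > 0, (2 * n_aa + n_ab) / (2.0 * n), np.nan)
        h = np.where(n > 0, n_ab / n, np.nan)
    return n, p, h


def private_alleles(matrix: GenotypeMatrix, populations=None) -> pd.DataFrame:
    """Per-locus private-allele flags: an allele is private to a population
    iff observed there and absent from the other population."""
    pops, masks = _pop_masks(matrix, populations)
    p1 = matrix.allele_freq(masks[0])
    p2 = matrix.allele_freq(masks[1])

    def seen(p):  # allele A / allele B observed at all
        return (np.nan_to_num(p) > 0), (np.nan_to_num(1 - p, nan=0.0) > 0)

    a1_, b1_ = seen(p1)
    a2_, b2_ = seen(p2)
    priv1 = (a1_ & ~a2_) | (b1_ & ~b2_)
    priv2 = (a2_ & ~a1_) | (b2_ & ~b1_)
    frame = pd.DataFrame(
        {f"private_{pops[0]}": priv1, f"private_{pops[1]}": priv2},
        index=matrix.loci,
    )
    frame.attrs["totals"] = {pops[0]: int(priv1.sum()), pops[1]: int(priv2.sum())}
    return frame


# ---------------------------------------------------------------------------
# Tajima machinery

@dataclass(frozen=True)
class TajimaConstants:
    n: int
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    if n < 2:
        raise ParameterError("sample size n must be at least 2")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i ** 2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return TajimaConstants(n, a1, a2, b1, b2, c1, c2, e1, e2)


def watterson_theta(S: int, n: int) -> float:
    """Watterson's estimator: S / a1(n)."""
    if S < 0:
        raise ParameterError("S must be non-negative")
    return S / tajima_constants(n).a1


def pairwise_pi(site_minor_counts, n: int) -> float:
    """Mean pairwise differences: sum over sites of 2 k (n-k) / (n (n-1))."""
    if n < 2:
        raise ParameterError("sample size n must be at least 2")
    k = np.asarray(list(site_minor_counts), dtype=float)
    return float((2.0 * k * (n - k) / (n * (n - 1.0))).sum())


def tajimas_d(pi: float, S: int, n: int) -> float:
    """Tajima's D; requires S > 0 and n >= 4 (NaN otherwise)."""
    if S <= 0 or n < 4:
        return np.nan
    c = tajima_constants(n)
    var = c.e1 * S + c.e2 * S * (S - 1.0)
    return (pi - S / c.a1) / np.sqrt(var)


# ---------------------------------------------------------------------------
# windowed scan

@dataclass(frozen=True)
class WindowConfig:
    """Windowed-scan settings mirroring a pooled-scan parameterisation:
    100-bp windows (one per 89-bp tag), sites kept only with minor-allele
    count >= 2 and >= 4 called genotypes; n for the constants is twice the
    called-individual count by default, or the nominal ``pool_n`` when
    ``n_mode="pool"``."""

    window_bp: int = 100
    min_rare_count: int = 2
    min_coverage: int = 4
    pool_n: int = 50
    n_mode: str = "called"  # "called" | "pool"


def windowed_scan(matrix: GenotypeMatrix, population: str | None,
                  config: WindowConfig = WindowConfig(),
                  tag_of_locus=None) -> pd.DataFrame:
    """Per-window S, pi, Watterson's theta and Tajima's D.

    One window per tag (tags are shorter than the window size); by default
    each locus id is its own tag, else ``tag_of_locus`` maps locus -> tag.
    Sites failing the rare-count or coverage thresholds are excluded; a
    window with no retained segregating site is flagged not evaluable.
    """
    mask = (matrix.individual_mask(population=population)
            if population is not None else matrix.analysis_mask())
    if not mask.any():
        raise ParameterError(f"population {population!r} has no individuals")
    n_aa, n_ab, n_bb, _ = matrix.counts(mask)
    called = n_aa + n_ab + n_bb
    count_a = 2 * n_aa + n_ab
    n_alleles = 2 * called
    minor = np.minimum(count_a, n_alleles - count_a)

    site_ok = (called >= config.min_coverage) & (minor >= config.min_rare_count)

    tags = (pd.Index([tag_of_locus(l) for l in matrix.loci])
            if tag_of_locus is not None else matrix.loci)
    frame = pd.DataFrame(
        {"tag": tags, "minor": minor, "n_alleles": n_alleles, "ok": site_ok},
        index=matrix.loci,
    )
    rows = []
    for tag, grp in frame.groupby("tag", sort=True):
        use = grp[grp["ok"]]
        S = len(use)
        if S == 0:
            rows.append({"window": tag, "n": 0, "S": 0, "pi": 0.0,
                         "theta_w": 0.0, "tajima_d": np.nan, "evaluable": False})
            continue
        if config.n_mode == "pool":
            n = 2 * config.pool_n
        else:
            n = int(use["n_alleles"].min())
        pi = pairwise_pi(np.minimum(use["minor"], n - use["minor"]), n)
        theta = watterson_theta(S, n) if n >= 2 else np.nan
        d = tajimas_d(pi, S, n)
        rows.append({"window": tag, "n": n, "S": S, "pi": pi,
                     "theta_w": theta, "tajima_d": d,
                     "evaluable": bool(S > 0 and n >= 4)})
    return pd.DataFrame(rows).set_index("window")
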