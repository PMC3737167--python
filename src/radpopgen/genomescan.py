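"""Genome-scan utilities along a linkage map.

Gaussian kernel smoothing of any per-marker statistic in centimorgan
space, two-locus EM haplotype-frequency inference from unphased
genotypes, Lewontin's D' and chromosome-level LD summaries with a
between-population Welch t-test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import AA, AB, BB, MISSING, GenotypeMatrix, ParameterError


@dataclass(frozen=True)
class SmoothConfig:
    sigma_cm: float = 5.0        # Gaussian bandwidth, centimorgans
    truncation_sigmas: float = 3.0
    grid_step_cm: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma_cm <= 0:
            raise ParameterError("sigma_cm must be positive")
        if self.truncation_sigmas < 1:
            raise ParameterError("truncation must be at least one sigma")


def kernel_smooth(positions_cm, values, config: SmoothConfig = SmoothConfig(),
                  grid=None) -> pd.DataFrame:
    """Gaussian-weighted moving average on one chromosome.

    At each grid point c the smoothed value is
    ``sum_j w_j v_j / sum_j w_j`` with ``w_j = exp(-d_j^2 / (2 sigma^2))``
    over markers within the truncation radius; grid points with no marker
    in range are NaN (gaps).  Returns columns
    (position_cm, value, n_markers).
    """
    pos = np.asarray(positions_cm, dtype=float)
    val = np.asarray(values, dtype=float)
    if pos.shape != val.shape:
        raise ParameterError("positions and values must have the same length")
    if len(pos) == 0:
        return pd.DataFrame(columns=["position_cm", "value", "n_markers"])
    keep = ~np.isnan(val)
    pos, val = pos[keep], val[keep]
    if grid is None:
        step = config.grid_step_cm
        grid = np.arange(np.floor(pos.min() / step) * step,
                         pos.max() + step / 2, step)
    grid = np.asarray(grid, dtype=float)
    radius = config.truncation_sigmas * config.sigma_cm
    d = grid[:, None] - pos[None, :]
    in_range = np.abs(d) <= radius
    w = np.where(in_range, np.exp(-(d ** 2) / (2 * config.sigma_cm ** 2)), 0.0)
    wsum = w.sum(axis=1)
    n_markers = in_range.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = np.where(wsum > 0, (w * val).sum(axis=1) / wsum, np.nan)
    return pd.DataFrame(
        {"position_cm": grid, "value": smoothed, "n_markers": n_markers}
    )


def smooth_map(linkage_map: pd.DataFrame, values: pd.Series,
               config: SmoothConfig = SmoothConfig()) -> pd.DataFrame:
    """Kernel-smooth a per-marker statistic chromosome by chromosome.

    ``linkage_map`` needs columns (marker, chromosome, position_cm);
    ``values`` is indexed by marker.  Unmapped markers are ignored.
    """
    tracks = []
    merged = linkage_map.merge(
        values.rename("value"), left_on="marker", right_index=True, how="inner"
    )
    for chrom, grp in merged.groupby("chromosome", sort=True):
        track = kernel_smooth(grp["position_cm"], grp["value"], config)
        track.insert(0, "chromosome", chrom)
        tracks.append(track)
    if not tracks:
        return pd.DataFrame(columns=["chromosome", "position_cm", "value", "n_markers"])
    return pd.concat(tracks, ignore_index=True)


def call_peaks(track: pd.DataFrame, percentile: float = 95.0) -> pd.DataFrame:
    """Contiguous grid runs above a percentile of the (non-NaN) track."""
    vals = track["value"].to_numpy()
    thr = np.nanpercentile(vals, percentile)
    above = np.nan_to_num(vals, nan=-np.inf) >= thr
    peaks = []
    for chrom, grp in track.assign(_above=above).groupby("chromosome", sort=True):
        run_start = None
        rows = grp.reset_index(drop=True)
        for i, r in rows.iterrows():
            if r["_above"] and run_start is None:
                run_start = r["position_cm"]
            if (not r["_above"] or i == len(rows) - 1) and run_start is not None:
                end = r["position_cm"] if r["_above"] else rows.loc[i - 1, "position_cm"]
                peaks.append({"chromosome": chrom, "start_cm": run_start,
                              "end_cm": end, "threshold": thr})
                run_start = None
    return pd.DataFrame(peaks, columns=["chromosome", "start_cm", "end_cm", "threshold"])


# ---------------------------------------------------------------------------
# linkage disequilibrium

class MonomorphicPairError(ValueError):
    """Either locus is monomorphic among pairwise-complete individuals."""


def genotype_pair_table(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 joint genotype counts over pairwise-complete individuals."""
    ok = (g1 != MISSING) & (g2 != MISSING)
    return np.bincount(g1[ok] * 3 + g2[ok], minlength=9).reshape(3, 3)


def em_haplotype_freqs(table: np.ndarray, tol: float = 1e-8,
                       max_iter: int = 1000) -> np.ndarray:
    """EM haplotype frequencies (AB, Ab, aB, ab) from a 3x3 genotype table.

    Rows index the first locus's genotype (AA, Aa, aa), columns the
    second's.  Only the double heterozygote has ambiguous phase; EM
    iterates its expected phase split until the frequency change drops
    below ``tol``.  The log-likelihood is non-decreasing across
    iterations (standard EM property).
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (3, 3):
        raise ParameterError("expected a 3x3 genotype count table")
    n = table.sum()
    if n < 1:
        raise MonomorphicPairError("no pairwise-complete individuals")
    # marginal allele counts
    pA = (2 * table[0].sum() + table[1].sum()) / (2 * n)
    pB = (2 * table[:, 0].sum() + table[:, 1].sum()) / (2 * n)
    if pA in (0.0, 1.0) or pB in (0.0, 1.0):
        raise MonomorphicPairError("monomorphic locus in pairwise-complete subset")

    # unambiguous haplotype counts; cell (1,1) holds the double hets
    base = np.zeros(4)  # AB, Ab, aB, ab
    base[0] = 2 * table[0, 0] + table[0, 1] + table[1, 0]
    base[1] = 2 * table[0, 2] + table[0, 1] + table[1, 2]
    base[2] = 2 * table[2, 0] + table[1, 0] + table[2, 1]
    base[3] = 2 * table[2, 2] + table[2, 1] + table[1, 2]
    dh = table[1, 1]

    freqs = np.full(4, 0.25)
    for _ in range(max_iter):
        # E: a double het is AB/ab with prob prop. to f_AB f_ab
        coupling = freqs[0] * freqs[3]
        repulsion = freqs[1] * freqs[2]
        denom = coupling + repulsion
        frac = 0.5 if denom == 0 else coupling / denom
        counts = base + dh * np.array([frac, 1 - frac, 1 - frac, frac])
        new = counts / (2 * n)
        if np.abs(new - freqs).max() < tol:
            freqs = new
            break
        freqs = new
    return freqs


def d_coefficient(freqs: np.ndarray) -> float:
    """Raw LD coefficient D = p_AB - p_A p_B."""
    pA = freqs[0] + freqs[1]
    pB = freqs[0] + freqs[2]
    return float(freqs[0] - pA * pB)


def d_prime(freqs: np.ndarray) -> float:
    """Lewontin's D': |D| normalised by its frequency-constrained maximum."""
    pA = freqs[0] + freqs[1]
    pB = freqs[0] + freqs[2]
    D = freqs[0] - pA * pB
    if D > 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    else:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    if d_max <= 0:
        return np.nan
    return float(abs(D) / d_max)


def pair_d_prime(g1: np.ndarray, g2: np.ndarray) -> float:
    """D' for two genotype vectors (int8 codes), NaN when undefined."""
    table = genotype_pair_table(g1, g2)
    try:
        return d_prime(em_haplotype_freqs(table))
    except MonomorphicPairError:
        return np.nan


def chromosome_ld_summary(matrix: GenotypeMatrix, linkage_map: pd.DataFrame,
                          population: str | None = None,
                          max_pairs_per_chromosome: int | None = None,
                          rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Mean D' and its standard error per chromosome.

    All same-chromosome marker pairs are evaluated (optionally a random
    subsample per chromosome for large maps).  Chromosomes with fewer
    than two mapped markers are skipped.  The frame attr ``overall_mean``
    averages the per-pair D' over every chromosome.
    """
    sub = matrix if population is None else matrix.subset_individuals(
        matrix.individual_mask(population=population))
    mapped = linkage_map[linkage_map["marker"].isin(matrix.loci)]
    loc_idx = {l: i for i, l in enumerate(matrix.loci)}
    rows = []
    all_pairs = []
    for chrom, grp in mapped.groupby("chromosome", sort=True):
        markers = list(grp["marker"])
        if len(markers) < 2:
            continue
        pairs = list(itertools.combinations(markers, 2))
        if max_pairs_per_chromosome is not None and len(pairs) > max_pairs_per_chromosome:
            r = rng or np.random.default_rng(0)
            pick = r.choice(len(pairs), size=max_pairs_per_chromosome, replace=False)
            pairs = [pairs[i] for i in pick]
        vals = []
        for m1, m2 in pairs:
            dp = pair_d_prime(sub.calls[loc_idx[m1]], sub.calls[loc_idx[m2]])
            if not np.isnan(dp):
                vals.append(dp)
        if not vals:
            continue
        vals = np.asarray(vals)
        rows.append({
            "chromosome": chrom,
            "n_markers": len(markers),
            "n_pairs": len(vals),
            "mean_d_prime": float(vals.mean()),
            "se_d_prime": float(vals.std(ddof=1) / np.sqrt(len(vals)))
            if len(vals) > 1 else np.nan,
        })
        all_pairs.append(vals)
    frame = pd.DataFrame(
        rows, columns=["chromosome", "n_markers", "n_pairs",
                       "mean_d_prime", "se_d_prime"]
    )
    frame.attrs["overall_mean"] = (
        float(np.concatenate(all_pairs).mean()) if all_pairs else np.nan
    )
    return frame


def plot_track(track: pd.DataFrame, path, statistic: str = "statistic",
               markers: pd.DataFrame | None = None) -> None:
    """Plot a smoothed track (one panel, chromosomes laid end to end with
    alternating shading); optionally overlay per-marker points given a
    frame with columns (chromosome, position_cm, value)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(12, 3.2))
    offset = 0.0
    for k, (chrom, grp) in enumerate(track.groupby("chromosome", sort=True)):
        x = grp["position_cm"] + offset
        if k % 2:
            ax.axvspan(offset, offset + grp["position_cm"].max(),
                       color="0.92", zorder=0)
        ax.plot(x, grp["value"], color="k", lw=1)
        if markers is not None:
            pts = markers[markers["chromosome"] == chrom]
            ax.plot(pts["position_cm"] + offset, pts["value"], ".",
                    ms=2, color="tab:red", alpha=0.6)
        offset += grp["position_cm"].max() + 1.0
    ax.set_xlabel("map position (cM, chromosomes concatenated)")
    ax.set_ylabel(statistic)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def compare_ld_populations(means1, means2) -> tuple[float, float]:
    """Welch two-sample two-tailed t-test on chromosome-mean D' vectors."""
    means1 = np.asarray(means1, dtype=float)
    means2 = np.asarray(means2, dtype=float)
    if len(means1) < 2 or len(means2) < 2:
        raise ParameterError("at least two chromosome means per population")
    if np.array_equal(means1, means2):
        return 0.0, 1.0
    t, p = sps.ttest_ind(means1, means2, equal_var=False)
    return float(t), float(p)
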