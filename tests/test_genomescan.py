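"""Kernel smoothing, EM haplotype inference, D' and LD summaries."""

import numpy as np
import pytest

from radpopgen import genomescan, simdata
from radpopgen.core import AA, AB, BB, MISSING, ParameterError
from radpopgen.genomescan import (
    MonomorphicPairError, SmoothConfig, chromosome_ld_summary,
    compare_ld_populations, d_coefficient, d_prime, em_haplotype_freqs,
    genotype_pair_table, kernel_smooth, pair_d_prime, smooth_map,
)

from conftest import make_matrix
from oracles import haplotype_freqs_by_counting


class TestKernelSmooth:
    def test_single_marker_at_grid_point(self):
        t = kernel_smooth([10.0], [3.5], grid=[10.0])
        assert t["value"].iloc[0] == pytest.approx(3.5)
        assert t["n_markers"].iloc[0] == 1

    def test_constant_values_stay_constant(self):
        t = kernel_smooth(np.linspace(0, 50, 30), np.full(30, 2.2))
        defined = t["value"].dropna()
        np.testing.assert_allclose(defined, 2.2)

    def test_symmetric_markers_average(self):
        cfg = SmoothConfig(sigma_cm=5.0)
        t = kernel_smooth([5.0, 15.0], [0.0, 1.0], cfg, grid=[10.0])
        assert t["value"].iloc[0] == pytest.approx(0.5)

    def test_output_within_value_range(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.uniform(0, 100, 60))
        val = rng.uniform(-1, 4, 60)
        t = kernel_smooth(pos, val)
        defined = t["value"].dropna()
        assert (defined >= val.min() - 1e-12).all()
        assert (defined <= val.max() + 1e-12).all()

    def test_small_sigma_recovers_marker_values(self):
        pos = np.array([0.0, 20.0, 40.0])
        val = np.array([1.0, 5.0, -2.0])
        t = kernel_smooth(pos, val, SmoothConfig(sigma_cm=0.01), grid=pos)
        np.testing.assert_allclose(t["value"], val)

    def test_large_sigma_approaches_unweighted_mean(self):
        pos = np.array([0.0, 10.0, 30.0])
        val = np.array([1.0, 2.0, 6.0])
        t = kernel_smooth(pos, val, SmoothConfig(sigma_cm=1e4), grid=[15.0])
        assert t["value"].iloc[0] == pytest.approx(val.mean(), rel=1e-4)

    def test_gap_far_from_markers_undefined(self):
        t = kernel_smooth([0.0], [1.0], SmoothConfig(sigma_cm=1.0),
                          grid=[0.0, 100.0])
        assert np.isnan(t["value"].iloc[1])
        assert t["n_markers"].iloc[1] == 0

    def test_empty_chromosome(self):
        t = kernel_smooth([], [])
        assert t.empty


class TestEMHaplotypes:
    def test_unambiguous_phase_matches_direct_counting(self):
        # 50 AABB + 50 aabb: no double heterozygotes
        table = np.zeros((3, 3))
        table[0, 0] = 50
        table[2, 2] = 50
        freqs = em_haplotype_freqs(table)
        np.testing.assert_allclose(freqs, [0.5, 0.0, 0.0, 0.5], atol=1e-12)
        want = haplotype_freqs_by_counting([(0, 0)] * 50 + [(2, 2)] * 50)
        np.testing.assert_allclose(freqs, want, atol=1e-12)

    def test_mixed_unambiguous_table_matches_counting(self):
        pairs = ([(0, 0)] * 20 + [(0, 1)] * 10 + [(1, 0)] * 8
                 + [(2, 2)] * 15 + [(1, 2)] * 5 + [(0, 2)] * 3)
        table = np.zeros((3, 3))
        for g1, g2 in pairs:
            table[g1, g2] += 1
        freqs = em_haplotype_freqs(table)
        want = haplotype_freqs_by_counting(pairs)
        np.testing.assert_allclose(freqs, want, atol=1e-9)

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(3)
        table = rng.integers(0, 20, size=(3, 3)).astype(float)
        freqs = em_haplotype_freqs(table)
        assert freqs.sum() == pytest.approx(1.0)
        assert (freqs >= 0).all()

    def test_independent_loci_give_near_zero_D(self):
        # genotype table at exact two-locus equilibrium, p = q = 0.5
        table = np.outer([0.25, 0.5, 0.25], [0.25, 0.5, 0.25]) * 400
        freqs = em_haplotype_freqs(table)
        assert d_coefficient(freqs) == pytest.approx(0.0, abs=1e-9)

    def test_monomorphic_pair_raises(self):
        table = np.zeros((3, 3))
        table[0, 0] = 30
        with pytest.raises(MonomorphicPairError):
            em_haplotype_freqs(table)


class TestDPrime:
    def test_full_coupling(self):
        freqs = np.array([0.5, 0.0, 0.0, 0.5])
        assert d_coefficient(freqs) == pytest.approx(0.25)
        assert d_prime(freqs) == pytest.approx(1.0)

    def test_equilibrium_zero(self):
        freqs = np.array([0.25, 0.25, 0.25, 0.25])
        assert d_prime(freqs) == pytest.approx(0.0, abs=1e-12)

    def test_allele_relabeling_invariance(self):
        freqs = np.array([0.4, 0.2, 0.1, 0.3])
        swapped_first = freqs[[2, 3, 0, 1]]   # relabel locus 1 alleles
        swapped_second = freqs[[1, 0, 3, 2]]  # relabel locus 2 alleles
        assert d_prime(freqs) == pytest.approx(d_prime(swapped_first))
        assert d_prime(freqs) == pytest.approx(d_prime(swapped_second))

    def test_pair_d_prime_from_genotypes(self):
        g1 = np.array([AA] * 50 + [BB] * 50, dtype=np.int8)
        assert pair_d_prime(g1, g1.copy()) == pytest.approx(1.0)


class TestChromosomeLD:
    def _mapped_matrix(self):
        rng = np.random.default_rng(4)
        cfg = simdata.SimConfig(n_loci=60, n_per_pop=40,
                                n_doubled_haploid=0, seed=44)
        ds = simdata.simulate_dataset(cfg)
        from radpopgen.genotyping import call_matrix
        called = call_matrix(ds.read_counts, ds.genotypes.metadata)
        lmap = simdata.generate_linkage_map(ds.truth.loci, cfg, fraction=1.0)
        return called, lmap

    def test_pair_count_per_chromosome(self):
        called, lmap = self._mapped_matrix()
        summary = chromosome_ld_summary(called, lmap, "migrant")
        for r in summary.itertuples():
            assert r.n_pairs <= r.n_markers * (r.n_markers - 1) // 2

    def test_two_marker_chromosome_mean_is_pair_value(self):
        calls = np.array([[AA] * 25 + [BB] * 25,
                          [AA] * 25 + [BB] * 25], dtype=np.int8)
        m = make_matrix(calls)
        import pandas as pd
        lmap = pd.DataFrame({"marker": ["L0", "L1"],
                             "chromosome": ["chr01"] * 2,
                             "position_cm": [1.0, 2.0]})
        summary = chromosome_ld_summary(m, lmap)
        assert len(summary) == 1
        assert summary["mean_d_prime"].iloc[0] == pytest.approx(
            pair_d_prime(calls[0], calls[1]))

    def test_unlinked_panmictic_d_prime_shrinks_with_n(self):
        means = {}
        for n in (15, 120):
            cfg = simdata.SimConfig(n_loci=40, n_per_pop=n, fst_neutral=1e-4,
                                    fst_divergent=0.5, n_doubled_haploid=0,
                                    seed=45)
            ds = simdata.simulate_dataset(cfg)
            from radpopgen.genotyping import call_matrix
            called = call_matrix(ds.read_counts, ds.genotypes.metadata)
            lmap = simdata.generate_linkage_map(
                ds.truth.loci, cfg.replace(n_chromosomes=2), fraction=1.0)
            s = chromosome_ld_summary(called, lmap, "migrant")
            means[n] = s.attrs["overall_mean"]
        assert means[120] < means[15]


class TestComparePopulations:
    def test_identical_vectors(self):
        t, p = compare_ld_populations([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert t == 0.0 and p == 1.0

    def test_large_shift_significant(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0.6, 0.01, size=20)
        t, p = compare_ld_populations(a, a + 0.1)
        assert p < 0.001

    def test_swap_flips_sign(self):
        rng = np.random.default_rng(6)
        a = rng.normal(0.6, 0.02, size=10)
        b = rng.normal(0.5, 0.02, size=10)
        t1, p1 = compare_ld_populations(a, b)
        t2, p2 = compare_ld_populations(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_too_few_chromosomes(self):
        with pytest.raises(ParameterError):
            compare_ld_populations([0.5], [0.6])


def test_smooth_map_tracks_per_chromosome(small_dataset, small_called):
    import pandas as pd

    from radpopgen.stats import pairwise_fst
    fst = pairwise_fst(small_called)["fst"]
    track = smooth_map(small_dataset.linkage_map, fst)
    assert set(track.columns) == {"chromosome", "position_cm", "value",
                                  "n_markers"}
    mapped_chroms = set(small_dataset.linkage_map["chromosome"])
    assert set(track["chromosome"]) <= mapped_chroms
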