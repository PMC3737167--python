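"""Generator behaviour: determinism, frequency laws, doubled haploids,
PSV read signature, depth model, read emission round-trip, linkage map."""

import numpy as np
import pytest
from scipy import stats as sps

from radpopgen import simdata
from radpopgen.core import AB, AA, ParameterError
from radpopgen.simdata import SimConfig


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(fst_neutral=0.0),
        dict(fst_neutral=0.5, fst_divergent=0.4),
        dict(n_loci=100, n_divergent=60, n_psv=50),
        dict(error_rate=0.2),
        dict(n_per_pop=0),
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ParameterError):
            SimConfig(**kw)


class TestPopulationFrequencies:
    def test_deterministic_given_seed(self):
        cfg = SimConfig(n_loci=200, n_divergent=10, n_psv=5, seed=5)
        t1 = simdata.draw_population_frequencies(cfg).table
        t2 = simdata.draw_population_frequencies(cfg).table
        assert t1.equals(t2)

    def test_zero_divergence_limit(self):
        cfg = SimConfig(n_loci=500, fst_neutral=1e-9, fst_divergent=0.5, seed=6)
        t = simdata.draw_population_frequencies(cfg).table
        np.testing.assert_allclose(t["p_pop1"], t["p_anc"], atol=1e-3)
        np.testing.assert_allclose(t["p_pop2"], t["p_anc"], atol=1e-3)

    def test_class_labels_partition(self):
        cfg = SimConfig(n_loci=100, n_divergent=10, n_psv=7, seed=7)
        t = simdata.draw_population_frequencies(cfg).table
        counts = t["locus_class"].value_counts()
        assert counts["divergent"] == 10
        assert counts["psv"] == 7
        assert counts["neutral"] == 83

    def test_balding_nichols_variance_matches_F(self):
        # Var(p_i) = F p (1 - F... p(1-p)F under the island model
        cfg = SimConfig(n_loci=20000, fst_neutral=0.1, fst_divergent=0.5,
                        ancestral_freq=("fixed", 0.5), seed=8)
        t = simdata.draw_population_frequencies(cfg).table
        var = t.loc[t.locus_class == "neutral", "p_pop1"].var()
        assert var == pytest.approx(0.1 * 0.25, rel=0.05)

    def test_invalid_F_raises(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ParameterError):
            simdata._balding_nichols(np.array([0.5]), 1.0, rng)


class TestGenotypes:
    def test_fixed_frequency_gives_all_AA(self):
        cfg = SimConfig(n_loci=50, ancestral_freq=("fixed", 0.9999),
                        fst_neutral=1e-9, fst_divergent=0.5,
                        n_per_pop=20, seed=9)
        ds_truth = simdata.draw_population_frequencies(cfg)
        ds_truth.table["p_pop1"] = 1.0
        ds_truth.table["p_pop2"] = 1.0
        g = simdata.sample_genotypes(ds_truth, cfg)
        analysis = g.analysis_mask()
        assert (g.calls[:, analysis] == AA).all()

    def test_doubled_haploids_never_heterozygous(self, small_dataset):
        g = small_dataset.genotypes
        dh = g.individual_mask(doubled_haploid=True)
        assert dh.sum() == 2
        assert not (g.calls[:, dh] == AB).any()

    def test_heterozygote_fraction_at_half(self):
        cfg = SimConfig(n_loci=200, ancestral_freq=("fixed", 0.5),
                        fst_neutral=1e-9, fst_divergent=0.5,
                        n_per_pop=25, seed=10)
        truth = simdata.draw_population_frequencies(cfg)
        g = simdata.sample_genotypes(truth, cfg)
        analysis = g.analysis_mask()
        frac = (g.calls[:, analysis] == AB).mean()
        n_draws = 200 * 50
        assert frac == pytest.approx(0.5, abs=3 * np.sqrt(0.25 / n_draws))


class TestReadCounts:
    def test_error_free_homozygote_counts(self):
        cfg = SimConfig(n_loci=100, ancestral_freq=("fixed", 0.999),
                        fst_neutral=1e-9, fst_divergent=0.5,
                        error_rate=0.0, n_per_pop=10, seed=11)
        truth = simdata.draw_population_frequencies(cfg)
        g = simdata.sample_genotypes(truth, cfg)
        rc = simdata.simulate_read_counts(g, truth, cfg)
        hom_a = g.calls == AA
        assert (rc.counts_b[hom_a] == 0).all()

    def test_psv_doubled_haploids_show_both_alleles(self, small_dataset,
                                                    small_config):
        rc = small_dataset.read_counts
        psv = small_dataset.truth.class_mask("psv")
        dh = small_dataset.genotypes.individual_mask(doubled_haploid=True)
        a = rc.counts_a[np.ix_(psv, dh)]
        b = rc.counts_b[np.ix_(psv, dh)]
        both = (a > 0) & (b > 0)
        assert both.mean() > 0.99
        # roughly balanced: each copy contributes ~mean_depth
        ratio = a.sum() / (a.sum() + b.sum())
        assert ratio == pytest.approx(0.5, abs=0.05)

    def test_depth_distribution_poisson(self):
        cfg = SimConfig(n_loci=300, n_per_pop=20, mean_depth=30.0,
                        n_doubled_haploid=0, seed=12)
        ds = simdata.simulate_dataset(cfg)
        frac_low = (ds.read_counts.total < 8).mean()
        expected = sps.poisson.cdf(7, 30.0)
        n_cells = ds.read_counts.total.size
        tol = 3 * np.sqrt(expected * (1 - expected) / n_cells) + 1e-6
        assert frac_low == pytest.approx(expected, abs=max(tol, 1e-4))


class TestEmitReads:
    def test_reads_are_89bp_and_round_trip(self, tmp_path):
        from Bio.SeqIO.FastaIO import SimpleFastaParser

        cfg = SimConfig(n_loci=40, n_psv=3, n_per_pop=5, error_rate=0.0,
                        mean_depth=10.0, seed=13)
        ds = simdata.simulate_dataset(cfg)
        path = tmp_path / "reads.fasta"
        n = simdata.emit_reads(ds.genotypes, ds.truth, cfg, path,
                               counts=ds.read_counts)
        seq_counts: dict[str, int] = {}
        with open(path) as fh:
            for rid, seq in SimpleFastaParser(fh):
                assert len(seq) == 89
                assert set(seq) <= set("ACGT")
                seq_counts[seq] = seq_counts.get(seq, 0) + 1
        assert sum(seq_counts.values()) == n
        # stacking recovers the per-allele totals exactly (error-free)
        for r in ds.truth.table.itertuples():
            li = ds.truth.loci.get_loc(r.Index)
            want_a = int(ds.read_counts.counts_a[li].sum())
            sb = simdata.allele_b_sequence(r.seq_a, r.snp_pos, r.alt_base)
            assert seq_counts.get(r.seq_a, 0) == want_a
            assert seq_counts.get(sb, 0) == int(ds.read_counts.counts_b[li].sum())

    def test_fastq_format(self, tmp_path):
        from Bio import SeqIO

        cfg = SimConfig(n_loci=5, n_per_pop=2, mean_depth=5.0, seed=14)
        ds = simdata.simulate_dataset(cfg)
        path = tmp_path / "reads.fastq"
        simdata.emit_reads(ds.genotypes, ds.truth, cfg, path, fmt="fastq")
        recs = list(SeqIO.parse(str(path), "fastq"))
        assert recs and all(len(r.seq) == 89 for r in recs)


class TestLinkageMap:
    def test_full_fraction_maps_everything(self, small_config):
        m = simdata.generate_linkage_map(["a", "b", "c"], small_config,
                                         fraction=1.0)
        assert set(m["marker"]) == {"a", "b", "c"}

    def test_quarter_fraction(self):
        cfg = SimConfig(n_loci=8000, seed=15)
        loci = [f"L{i}" for i in range(8000)]
        m = simdata.generate_linkage_map(loci, cfg, fraction=0.25)
        assert len(m) == 2000
        assert m["position_cm"].between(0, cfg.map_length_cm).all()
        assert m["chromosome"].nunique() <= cfg.n_chromosomes

    def test_map_deterministic(self, small_config):
        loci = [f"L{i}" for i in range(100)]
        m1 = simdata.generate_linkage_map(loci, small_config)
        m2 = simdata.generate_linkage_map(loci, small_config)
        assert m1.equals(m2)


def test_dataset_bit_identical_for_same_seed():
    cfg = SimConfig(n_loci=60, n_divergent=5, n_psv=4, n_per_pop=8, seed=16)
    d1 = simdata.simulate_dataset(cfg)
    d2 = simdata.simulate_dataset(cfg)
    assert d1.truth.table.equals(d2.truth.table)
    assert np.array_equal(d1.genotypes.calls, d2.genotypes.calls)
    assert np.array_equal(d1.read_counts.counts_a, d2.read_counts.counts_a)
    assert d1.linkage_map.equals(d2.linkage_map)


def test_sample_frequencies_recover_truth():
    # frequency recovery at n=500 within 3 binomial SD for most loci
    cfg = SimConfig(n_loci=300, n_per_pop=500, seed=17)
    truth = simdata.draw_population_frequencies(cfg)
    g = simdata.sample_genotypes(truth, cfg)
    pop1 = g.individual_mask(population="migrant")
    freq = g.allele_freq(pop1)
    p = truth.table["p_pop1"].to_numpy()
    sd = np.sqrt(p * (1 - p) / (2 * 500))
    within = np.abs(freq - p) <= 3 * sd + 1e-9
    # ~0.3% of loci are expected outside a 3-SD band by chance
    assert within.mean() >= 0.98
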