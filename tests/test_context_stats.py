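"""Context annotation, buffering, occupancy, enrichment and overlap tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asbscan import context_stats as cs
from asbscan import synthetic_data as sd


@pytest.fixture(scope="module")
def genes():
    return [
        cs.GeneModel("gA", "chr1", "+", 10_000, 9_999, 15_000,
                     exons=[(9_999, 10_500), (14_000, 15_000)]),
        cs.GeneModel("gB", "chr1", "-", 30_000, 25_000, 30_000,
                     exons=[(25_000, 25_400), (29_500, 30_000)]),
    ]


class TestAnnotateContext:
    @pytest.mark.parametrize("pos,expected", [
        (9_500, cs.PROMOTER),      # within 2 kb upstream of + TSS
        (10_400, cs.PROMOTER),     # within 500 bp downstream
        (14_500, cs.EXON),
        (12_000, cs.INTRON),
        (100_000, cs.INTERGENIC),
        (31_500, cs.PROMOTER),     # upstream of the - strand TSS at 30,000
        (25_200, cs.EXON),
    ])
    def test_labels(self, genes, pos, expected):
        assert cs.annotate_context("chr1", pos, genes) == expected

    def test_promoter_takes_precedence_over_exon(self):
        gene_exon = cs.GeneModel("gC", "chr1", "+", 1_000, 999, 3_000,
                                 exons=[(1_999, 2_500)])
        gene_promo = cs.GeneModel("gD", "chr1", "+", 2_500, 2_499, 5_000)
        assert cs.annotate_context("chr1", 2_100, [gene_exon, gene_promo]) \
            == cs.PROMOTER

    def test_unknown_contig_is_intergenic(self, genes, caplog):
        with caplog.at_level("WARNING", logger="asbscan"):
            assert cs.annotate_context("chr9", 100, genes) == cs.INTERGENIC

    def test_every_site_gets_exactly_one_label(self, genes, rng):
        labels = {cs.annotate_context("chr1", int(p), genes)
                  for p in rng.integers(1, 40_000, 200)}
        assert labels <= {cs.PROMOTER, cs.EXON, cs.INTRON, cs.INTERGENIC}


class TestBuffering:
    def test_planted_promoter_attenuation_detected(self):
        table = sd.simulate_asb_table(n_sites=500, seed=5, promoter_attenuation=0.5)
        res = cs.buffering_tests(table)
        assert res["mw_p_magnitude"] < 0.01
        assert res["anova_p"] < 0.01
        assert res["mw_p_frequency"] < 0.05

    def test_all_ties_give_p_one(self):
        table = pd.DataFrame({
            "tf": "JUN", "log2fc": 0.5, "p_binom": 0.5, "passes_fc": False,
            "n_ref": 20, "n_alt": 14,
            "context": [cs.PROMOTER] * 10 + [cs.INTERGENIC] * 10,
        })
        res = cs.buffering_tests(table)
        assert res["mw_p_magnitude"] == pytest.approx(1.0)

    def test_single_context_errors(self):
        table = sd.simulate_asb_table(n_sites=50, seed=1)
        table["context"] = cs.PROMOTER
        with pytest.raises(ValueError):
            cs.buffering_tests(table)

    def test_null_anova_p_not_small_on_average(self):
        """Without a planted context effect the ANOVA p shows no signal."""
        ps = [cs.buffering_tests(sd.simulate_asb_table(n_sites=300, seed=s))["anova_p"]
              for s in range(25)]
        ks = stats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01


class TestOccupancy:
    def test_planted_negative_effect_detected(self):
        table, peaks = sd.simulate_occupancy_data(n_sites=300, seed=2,
                                                  occupancy_effect=0.35)
        res = cs.occupancy_correlation(table, peaks)
        assert res["r"] < 0 and res["p"] < 0.05
        assert res["hot_median"] <= res["rest_median"]

    def test_constant_occupancy_is_na(self):
        table, _ = sd.simulate_occupancy_data(n_sites=50, seed=3, occupancy_effect=0)
        peaks = {"TF0": [("chr1", 0, 10_000_000)]}   # covers everything
        res = cs.occupancy_correlation(table, peaks)
        assert math.isnan(res["r"])

    def test_empty_peaks_error(self):
        table, _ = sd.simulate_occupancy_data(n_sites=20, seed=3)
        with pytest.raises(ValueError):
            cs.occupancy_correlation(table, {})


@pytest.fixture(scope="module")
def models():
    return [cs.GeneModel(f"g{i}", "chr1", "+", 1 + i * 200_000,
                         i * 200_000, i * 200_000 + 2_000)
            for i in range(300)]


class TestGeneSetEnrichment:
    def test_sites_planted_near_targets_are_maximally_enriched(self, models):
        targets = [f"g{i}" for i in range(3)]
        expressed = [f"g{i}" for i in range(300)]
        sites = pd.DataFrame({"contig": "chr1",
                              "pos": [i * 200_000 + 500 for i in range(3)]})
        res = cs.empirical_geneset_enrichment(sites, targets, expressed, models,
                                              n_draws=1000, seed=0)
        assert res["p"] == pytest.approx(1 / 1001)

    def test_zero_observed_gives_p_one(self, models):
        sites = pd.DataFrame({"contig": ["chr2"], "pos": [5]})
        res = cs.empirical_geneset_enrichment(sites, ["g0"],
                                              [f"g{i}" for i in range(300)],
                                              models, n_draws=200, seed=0)
        assert res["p"] == 1.0

    def test_null_targets_rarely_significant(self, models):
        """Random expressed targets should not look enriched."""
        rng = np.random.default_rng(1)
        expressed = [f"g{i}" for i in range(300)]
        sites = pd.DataFrame({"contig": "chr1",
                              "pos": rng.integers(1, 60_000_000, 60)})
        hits = 0
        for s in range(20):
            targets = list(np.random.default_rng(s).choice(expressed, 4, replace=False))
            res = cs.empirical_geneset_enrichment(sites, targets, expressed, models,
                                                  n_draws=200, seed=s)
            hits += res["p"] < 0.05
        assert hits <= 2   # ~90% of seeds non-significant

    def test_unexpressed_target_rejected(self, models):
        with pytest.raises(ValueError):
            cs.empirical_geneset_enrichment(pd.DataFrame({"contig": [], "pos": []}),
                                            ["gX"], ["g0"], models)


class TestOverlapFisher:
    def test_enumerated_two_by_two(self):
        _, p = cs.overlap_fisher(table=[[2, 0], [0, 2]], sided="greater")
        assert p == pytest.approx(1 / 6)

    def test_zero_overlap_upper_tail_is_one(self):
        _, p = cs.overlap_fisher(table=[[0, 10], [10, 100]], sided="greater")
        assert p == pytest.approx(1.0)

    def test_matches_hypergeometric_tail_summation(self, rng):
        """Sampled tables with N <= 200 agree with exact rational tail sums."""
        from fractions import Fraction
        from math import comb

        for _ in range(150):
            N = int(rng.integers(4, 201))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(max(0, K + n - N), min(K, n) + 1))
            table = [[k, K - k], [n - k, N - K - n + k]]
            _, p = cs.overlap_fisher(table=table, sided="greater")
            tail = sum(Fraction(comb(K, j) * comb(N - K, n - j), comb(N, n))
                       for j in range(k, min(K, n) + 1))
            assert p == pytest.approx(float(tail), rel=1e-9, abs=1e-300)

    def test_indicator_vectors(self):
        a = [1, 1, 1, 0, 0, 0]
        b = [1, 1, 0, 0, 0, 1]
        odds, p = cs.overlap_fisher(a, b, sided="two")
        assert 0 < p <= 1

    def test_empty_table_errors(self):
        with pytest.raises(ValueError):
            cs.overlap_fisher(table=[[0, 0], [0, 0]])


class TestSNVClassEnrichment:
    @staticmethod
    def _snvs(rng, n, lo=0, hi=1_000_000):
        return pd.DataFrame({"contig": "chr1",
                             "pos": rng.integers(lo, hi, n) + 1})

    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(4)
        skin = self._snvs(rng, 60, 0, 100_000)          # clustered where peaks are
        other = self._snvs(rng, 120, 0, 1_000_000)      # mostly outside peaks
        reps = []
        for r in range(5):
            prng = np.random.default_rng(100 + r)
            reps.append([("chr1", int(p), int(p) + 400)
                         for p in prng.integers(0, 100_000, 80)])
        p = cs.snv_class_binding_enrichment(reps, skin, other, downsample_to=60, seed=0)
        assert p is not None and p < 0.05

    def test_equal_class_distributions_show_no_effect(self):
        """Both SNV classes drawn from the same positions distribution give a
        symmetric test: p averages near 0.5 over seeds."""
        rng = np.random.default_rng(5)
        reps = [[("chr1", int(p), int(p) + 300)
                 for p in np.random.default_rng(r).integers(0, 200_000, 50)]
                for r in range(4)]
        ps = []
        for s in range(12):
            srng = np.random.default_rng(50 + s)
            class_snvs = self._snvs(srng, 100, 0, 200_000)
            other_snvs = self._snvs(srng, 200, 0, 200_000)
            p = cs.snv_class_binding_enrichment(reps, class_snvs, other_snvs,
                                                downsample_to=100, seed=s)
            if p is not None:
                ps.append(p)
        assert 0.25 < np.mean(ps) < 0.75

    def test_degenerate_inputs_return_none(self):
        snvs = pd.DataFrame({"contig": ["chr1"], "pos": [10]})
        assert cs.snv_class_binding_enrichment([[]], snvs, snvs) is None  # <2 reps
        assert cs.snv_class_binding_enrichment([[], []], snvs, snvs) is None  # 0 peaks


class TestAlleleFreqCorrelation:
    def test_perfect_dependence(self):
        rng = np.random.default_rng(6)
        n = 80
        depth = rng.integers(50, 200, n)
        frac = rng.uniform(0.55, 0.95, n)
        n_ref = (depth * frac).astype(int)
        table = pd.DataFrame({"tf": "JUN", "rsid": [f"rs{i}" for i in range(n)],
                              "n_ref": n_ref, "n_alt": depth - n_ref})
        bound_frac = np.maximum(n_ref, depth - n_ref) / depth
        # alt frequency chosen so the more-bound (ref) allele's freq == its read share
        freqs = pd.DataFrame({"rsid": table["rsid"], "freq": 1 - bound_frac})
        res = cs.allele_freq_binding_correlation(table, freqs)
        assert res["r"] == pytest.approx(1.0, abs=1e-9)
        assert res["anova_p"] < 1e-10

    def test_constant_frequency_is_na(self):
        table = pd.DataFrame({"tf": "JUN", "rsid": ["rs1", "rs2"],
                              "n_ref": [30, 40], "n_alt": [10, 20]})
        freqs = pd.DataFrame({"rsid": ["rs1", "rs2"], "freq": [0.3, 0.3]})
        res = cs.allele_freq_binding_correlation(table, freqs)
        assert math.isnan(res["r"])

    def test_no_joinable_rsids_errors(self):
        table = pd.DataFrame({"tf": ["JUN"], "rsid": ["rs1"],
                              "n_ref": [30], "n_alt": [10]})
        freqs = pd.DataFrame({"rsid": ["rs9"], "freq": [0.5]})
        with pytest.raises(ValueError):
            cs.allele_freq_binding_correlation(table, freqs)
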