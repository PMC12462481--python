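"""Screen pseudo-P, FDR simulation, meta-analysis and pseudotime tests."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from asbscan import screen_stats as ss
from asbscan import synthetic_data as sd


class TestFisherPseudoP:
    @pytest.mark.parametrize("p1,p2,expected", [
        (1.0, 1.0, 1.0),
        (0.1, 0.1, 0.05605),
        (0.5, 0.5, 0.59657),
    ])
    def test_worked_examples(self, p1, p2, expected):
        assert ss.fisher_combine_pseudo_p(p1, p2) == pytest.approx(expected, abs=5e-6)

    def test_matches_chi2_survival_everywhere(self):
        """Closed form equals the df-4 chi-square survival to 1e-12."""
        grid = np.linspace(0.001, 1.0, 50)
        for p1 in grid:
            for p2 in grid[::7]:
                x = -2 * (math.log(p1) + math.log(p2))
                assert ss.fisher_combine_pseudo_p(p1, p2) == \
                    pytest.approx(float(stats.chi2.sf(x, 4)), abs=1e-12)

    def test_zero_is_clipped_not_fatal(self):
        assert 0 < ss.fisher_combine_pseudo_p(0.0, 0.5) < 1e-100

    def test_null_rate_matches_uniform(self):
        """With independent uniform inputs the pseudo-P is itself uniform, so
        the fraction below alpha matches alpha within MC error."""
        rng = np.random.default_rng(8)
        n = 20_000
        psi = [ss.fisher_combine_pseudo_p(a, b)
               for a, b in zip(rng.random(n), rng.random(n))]
        for alpha in (0.001, 0.01, 0.05):
            frac = np.mean(np.asarray(psi) < alpha)
            se = math.sqrt(alpha * (1 - alpha) / n)
            assert abs(frac - alpha) < 3 * se + 1e-9


class TestStouffer:
    def test_single_study_identity(self):
        assert ss.stouffer_combine([0.037], [5.0]) == pytest.approx(0.037, rel=1e-9)

    def test_two_equal_studies_worked_example(self):
        assert ss.stouffer_combine([0.05, 0.05], [1, 1]) == \
            pytest.approx(0.0100, abs=1e-4)

    def test_zero_weight_drops_study(self):
        assert ss.stouffer_combine([0.02, 0.9], [3.0, 0.0]) == \
            pytest.approx(0.02, rel=1e-9)

    def test_combination_strengthens_consistent_evidence(self):
        for p in (0.01, 0.1, 0.3):
            assert ss.stouffer_combine([p, p], [1, 1]) < p

    def test_two_sided_doubling(self):
        assert ss.two_sided_from_directions(0.03, 0.97) == pytest.approx(0.06)
        assert ss.two_sided_from_directions(0.9, 0.8) == 1.0


class TestHedgesG:
    def test_worked_example(self):
        assert ss.hedges_g(1, 1, 20, 0, 1, 20) == pytest.approx(1 - 3 / 151, rel=1e-9)

    def test_identical_groups_zero(self):
        assert ss.hedges_g(2.0, 1.0, 10, 2.0, 1.0, 10) == 0.0

    def test_antisymmetry(self):
        g1 = ss.hedges_g(3.0, 1.2, 15, 1.0, 0.8, 12)
        g2 = ss.hedges_g(1.0, 0.8, 12, 3.0, 1.2, 15)
        assert g1 == pytest.approx(-g2)

    def test_degenerate_zero_spread(self):
        assert ss.hedges_g(1.0, 0.0, 5, 1.0, 0.0, 5) == 0.0
        with pytest.raises(ValueError):
            ss.hedges_g(1.0, 0.0, 5, 2.0, 0.0, 5)

    def test_combine_effects_weighted(self):
        vals = [[1.0, 2.0, 3.0], [3.0, 2.0, 1.0]]
        comb = ss.combine_effects(vals, [1.0, 1.0])
        assert np.allclose(comb, 0.0)
        comb = ss.combine_effects(vals, [1.0, 0.0])
        assert comb[2] > comb[0]


class TestScreenFDR:
    def test_estimate_tracks_generative_truth(self):
        """The simulation estimate lands within 0.05 of the realized FDR
        computed from the generator's planted truth."""
        cfg = sd.ScreenCellConfig(seed=3, n_genes=4000, unexpressed_fraction=0.4,
                                  n_true_hits=150)
        screen, _, truth = sd.simulate_screen_and_cells(cfg)
        res = ss.pseudo_p_table(screen, cutoff=0.1)
        merged = res.merge(truth.genes, on="gene")
        realized_fdr = float((merged["hit"] & ~merged["is_true_screen_hit"]).sum()
                             / merged["hit"].sum())
        est = ss.screen_fdr_simulation(res, cutoff=0.1,
                                       true_positive_range=(150, 150),
                                       n_sims=200, seed=0)
        assert abs(est["fdr_min"] - realized_fdr) < 0.05

    def test_random_hits_look_fully_false(self):
        """Hits drawn blind to expression give an FDR estimate near 1."""
        rng = np.random.default_rng(9)
        n = 2000
        df = pd.DataFrame({"gene": [f"g{i}" for i in range(n)],
                           "expressed": rng.random(n) > 0.4,
                           "hit": False})
        df.loc[rng.choice(n, 100, replace=False), "hit"] = True
        est = ss.screen_fdr_simulation(df, true_positive_range=(100, 100),
                                       n_sims=100, seed=1)
        assert est["fdr_min"] > 0.7

    def test_clean_hits_give_near_zero_fdr(self):
        n = 2000
        expressed = np.ones(n, dtype=bool)
        expressed[1000:] = False
        hit = np.zeros(n, dtype=bool)
        hit[:100] = True                     # all hits expressed
        df = pd.DataFrame({"gene": [f"g{i}" for i in range(n)],
                           "expressed": expressed, "hit": hit})
        est = ss.screen_fdr_simulation(df, true_positive_range=(100, 100),
                                       n_sims=100, seed=2)
        assert est["fdr_min"] < 0.05


class TestPseudotimeShift:
    def test_single_extreme_cell_exact_rank_p(self):
        """One target cell holding the max pseudotime of n cells has exact
        one-sided Mann-Whitney p = 1/n."""
        n = 25
        cells = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(n)],
            "target": ["KO"] + ["control"] * (n - 1),
            "pseudotime": np.concatenate([[1.0], np.linspace(0, 0.9, n - 1)]),
            "dataset": "d1",
        })
        res = ss.pseudotime_shift_test(cells, "KO")
        assert res["per_dataset"]["d1"]["p_greater"] == pytest.approx(1 / n, rel=1e-9)

    def test_planted_shift_detected_and_null_calibrated(self):
        cfg = sd.ScreenCellConfig(seed=4, n_targets=8, cells_per_target=120)
        _, cells, truth = sd.simulate_screen_and_cells(cfg)
        shifts = truth.cells["pseudotime_shift"]
        shifted = [t for t, s in shifts.items() if s > 0]
        nulls = [t for t, s in shifts.items() if s == 0 and t != "control"]
        res = ss.pseudotime_shift_test(cells, shifted[0])
        assert res["p_greater"] < 1e-4
        null_ps = [ss.pseudotime_shift_test(cells, t)["p_two_sided"] for t in nulls]
        assert min(null_ps) > 0.001

    def test_all_tied_pseudotimes_give_p_one(self):
        cells = pd.DataFrame({"cell_id": list("abcd"), "target": ["KO", "KO", "c", "c"],
                              "pseudotime": [0.5] * 4, "dataset": "d1"})
        res = ss.pseudotime_shift_test(cells, "KO")
        assert res["p_two_sided"] == 1.0

    def test_absent_target_errors(self):
        cells = pd.DataFrame({"cell_id": ["a"], "target": ["c"],
                              "pseudotime": [0.1], "dataset": "d1"})
        with pytest.raises(ValueError):
            ss.pseudotime_shift_test(cells, "KO")


class TestWindowEnrichment:
    @staticmethod
    def _null_cells(seed, n_all=800, n_target=60):
        rng = np.random.default_rng(seed)
        pt_all = sd._mixture_pseudotime(rng, n_all, 0.0)
        pt_t = sd._mixture_pseudotime(rng, n_target, 0.0)
        return pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(n_all + n_target)],
            "target": ["other"] * n_all + ["KO"] * n_target,
            "pseudotime": np.concatenate([pt_all, pt_t]),
            "dataset": "d1",
        })

    def test_shifted_target_separates_from_null(self):
        """A strongly shifted target reaches the clip ceiling while null
        targets usually stay below it; the shifted signal dominates the
        typical null background."""
        null_maxes = []
        for seed in range(12):
            res = ss.pseudotime_window_enrichment(self._null_cells(seed), "KO")
            null_maxes.append(float(res["neglog10p"].max()))
        rng = np.random.default_rng(99)
        pt_all = sd._mixture_pseudotime(rng, 800, 0.0)
        pt_t = rng.beta(8, 1.5, size=60)
        cells = pd.DataFrame({
            "cell_id": np.arange(860),
            "target": ["other"] * 800 + ["KO"] * 60,
            "pseudotime": np.concatenate([pt_all, pt_t]),
            "dataset": "d1",
        })
        shifted = ss.pseudotime_window_enrichment(cells, "KO")
        assert shifted["neglog10p"].max() == pytest.approx(4.0)
        assert np.median(null_maxes) < 4.0

    def test_low_end_shift_localizes_to_early_windows(self):
        rng = np.random.default_rng(10)
        pt_all = sd._mixture_pseudotime(rng, 900, 0.0)
        pt_t = rng.beta(1.5, 8, size=80)          # shifted toward pseudotime 0
        cells = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(980)],
            "target": ["other"] * 900 + ["KO"] * 80,
            "pseudotime": np.concatenate([pt_all, pt_t]),
            "dataset": "d1",
        })
        res = ss.pseudotime_window_enrichment(cells, "KO")
        assert res["best_window"] < 5
        assert res["neglog10p"].max() == pytest.approx(4.0)   # clipped

    def test_cell_floor_skips_dataset(self):
        cells = self._null_cells(0, n_all=100, n_target=5)
        with pytest.raises(ValueError):
            ss.pseudotime_window_enrichment(cells, "KO", min_cells=20)


class TestResidualMarkerTest:
    def test_planted_expression_shift_ranks_first(self):
        cfg = sd.ScreenCellConfig(seed=6, n_targets=9, cells_per_target=100,
                                  marker_effect=1.0)
        _, cells, truth = sd.simulate_screen_and_cells(cfg)
        effects = truth.cells["marker_effect"]
        res = ss.residual_marker_test(cells, "marker")
        res = res.merge(pd.DataFrame({"target": list(effects),
                                      "effect": list(effects.values())}), on="target")
        top = res.sort_values("p").iloc[0]
        assert top["effect"] > 0
        assert top["q"] < 0.2
        # every planted-effect target beats every null target
        planted = res[res["effect"] > 0]["p"].max()
        nulls = res[res["effect"] == 0]["p"].min()
        assert planted < nulls

    def test_constant_marker_gives_all_ones(self):
        cells = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(40)],
            "target": ["KO"] * 20 + ["control"] * 20,
            "pseudotime": np.linspace(0, 1, 40),
            "marker": 1.0, "dataset": "d1",
        })
        res = ss.residual_marker_test(cells, "marker")
        assert (res["p"] == 1.0).all()

    def test_null_targets_are_calibrated(self):
        """Type-I error of the residual test stays near nominal under the null."""
        rej = 0
        n_tests = 0
        for seed in range(8):
            rng = np.random.default_rng(seed)
            n = 600
            pt = rng.random(n)
            marker = np.sin(3 * pt) + rng.normal(0, 0.4, n)
            targets = rng.choice([f"t{i}" for i in range(25)], size=n)
            cells = pd.DataFrame({"cell_id": np.arange(n), "target": targets,
                                  "pseudotime": pt, "marker": marker,
                                  "dataset": "d1"})
            res = ss.residual_marker_test(cells, "marker", control_label="none")
            rej += int((res["p"] < 0.05).sum())
            n_tests += len(res)
        assert 0.01 <= rej / n_tests <= 0.10
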