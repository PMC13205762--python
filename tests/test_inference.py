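import numpy as np
import pandas as pd
import pytest

import starscale as ss
from starscale.inference import _blocks


def star_surface(z=0.139, w=0.366, u=-0.03, b=5.0, noise=0.0, seed=None,
                 response="richness"):
    return ss.simulate_star_surface(z, w, u, b, noise, [1, 4, 16, 64, 256],
                                    range(1, 18), seed=seed, response=response)


class TestBlocks:
    def test_remainder_block_kept_intact(self):
        blocks = _blocks(17, 3)
        assert [len(b) for b in blocks] == [3, 3, 3, 3, 3, 2]
        assert np.concatenate(blocks).tolist() == list(range(17))

    def test_single_block_rejected(self):
        with pytest.raises(ValueError, match="blocks"):
            _blocks(5, 5)


class TestBlockPermutationTest:
    def test_strong_surface_min_p(self):
        res = ss.block_permutation_test(star_surface(noise=0.02, seed=1),
                                        n_rand=199, seed=2)
        assert res["r_squared"].p_value == pytest.approx(1 / 200)
        assert res["w"].p_value <= 0.05

    def test_p_formula_bounds_and_null_length(self):
        res = ss.block_permutation_test(star_surface(noise=0.5, seed=3),
                                        n_rand=99, seed=4)
        for r in res.values():
            assert 1 / 100 <= r.p_value <= 1.0
            assert len(r.null) + r.n_discarded == 99

    def test_block_size_equal_series_rejected(self):
        with pytest.raises(ValueError, match="blocks"):
            ss.block_permutation_test(star_surface(noise=0.1, seed=0),
                                      n_rand=9, block_size=17, seed=1)

    def test_type_one_error_under_structureless_null(self):
        """i.i.d. surfaces: rejection rate at alpha=0.05 within [0.02, 0.09]."""
        rejections = 0
        n_datasets = 300
        for i in range(n_datasets):
            surf = ss.simulate_star_surface(0, 0, 0, 3.0, 0.3, [1, 4, 16, 64, 256],
                                            range(1, 18), seed=10_000 + i)
            res = ss.block_permutation_test(surf, n_rand=199, seed=i)
            rejections += res["r_squared"].p_value <= 0.05
        assert 0.02 <= rejections / n_datasets <= 0.09

    def test_accepts_community_matrix(self, small_matrix, small_design):
        res = ss.block_permutation_test(
            small_matrix, design=small_design, n_rand=49, block_size=2, seed=0,
            site="site1", treatment="fallow",
        )
        assert res["r_squared"].p_value <= 0.10  # real structure present


class TestStarPtarDifference:
    def test_identical_responses_give_p_one(self):
        surf = star_surface(noise=0.02, seed=5)
        surf["pd"] = surf["richness"]
        res = ss.star_ptar_difference_test(surf, "w", n_rand=99, seed=6)
        assert res.observed == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0

    def test_detects_true_exponent_gap(self):
        """w_s=0.366 vs w_p=0.331, noise 0.02: detected in >= 80% of 50 reps."""
        hits = 0
        for rep in range(50):
            s = star_surface(noise=0.02, seed=2000 + rep)
            p = star_surface(z=0.124, w=0.331, b=4.8, noise=0.02,
                             seed=3000 + rep, response="pd")
            surf = s.assign(pd=p["pd"].to_numpy())
            res = ss.star_ptar_difference_test(surf, "w", n_rand=199, seed=rep)
            hits += res.p_value < 0.05
        assert hits / 50 >= 0.8

    def test_zero_randomizations_rejected(self):
        surf = star_surface(noise=0.02, seed=1)
        surf["pd"] = surf["richness"]
        with pytest.raises(ValueError):
            ss.star_ptar_difference_test(surf, "w", n_rand=0)

    def test_missing_pd_rejected(self):
        with pytest.raises(ValueError, match="phylogenetic"):
            ss.star_ptar_difference_test(star_surface(noise=0.02, seed=1), "w",
                                         n_rand=9)


class TestEnumerateWindows:
    @pytest.mark.parametrize("size, expected", [(5, 13), (6, 12), (7, 11), (17, 1)])
    def test_window_counts_over_17_months(self, size, expected):
        wins = ss.enumerate_windows(17, {size})
        assert len(wins) == expected
        assert [s for s, _ in wins] == [size] * expected

    @pytest.mark.parametrize("K", [5, 11, 20])
    def test_counts_match_exhaustive_listing(self, K):
        for s in range(2, K + 1):
            wins = ss.enumerate_windows(K, {s})
            explicit = [(s, y) for y in range(1, K + 1) if y + s - 1 <= K]
            assert wins == explicit

    def test_oversized_window_warns_and_skips(self):
        with pytest.warns(UserWarning, match="exceeds"):
            assert ss.enumerate_windows(10, {12}) == []

    def test_size_below_two_rejected(self):
        with pytest.raises(ValueError):
            ss.enumerate_windows(10, {1})


class TestWindowFamily:
    def test_85_fits_per_plot_per_response(self, small_design):
        params = ss.SimulationParams(pool_size=60, depth_mean=400, seed=3)
        design = ss.make_design(1, 1, 9, 17, 3)
        m = ss.simulate_communities(design, params)
        fam = ss.fit_window_family(m, design, sizes=range(5, 15))
        assert len(fam) == 85  # 13+12+...+4
        counts = fam.groupby("window_size").size()
        assert counts.loc[5] == 13 and counts.loc[14] == 4

    def test_whole_series_window_equals_full_fit(self, small_matrix, small_design):
        fam = ss.fit_window_family(small_matrix, small_design, sizes={6})
        surf = ss.build_accumulation_surface(small_matrix, small_design,
                                             site="site1", treatment="fallow")
        full = ss.fit_star(surf)
        row = fam.query("site == 'site1' and treatment == 'fallow'").iloc[0]
        assert row["w"] == pytest.approx(full.w_, abs=1e-9)
        assert row["z"] == pytest.approx(full.z_, abs=1e-9)

    def test_stationary_turnover_identical_exponents_in_every_window(self):
        # each month carries its own disjoint set of 4 taxa at every point,
        # so any window of length T accumulates exactly 4T taxa regardless
        # of its start: every window fit must agree exactly
        design = ss.make_design(1, 1, 4, 8, 2)
        meta = design.sample_index()
        taxa = [f"m{m}k{k}" for m in range(1, 9) for k in range(4)]
        counts = pd.DataFrame(0, index=meta.index, columns=taxa)
        for sample, row in meta.iterrows():
            for k in range(4):
                counts.loc[sample, f"m{int(row['time'])}k{k}"] = 1
        m = ss.CommunityMatrix(counts, meta)
        fam = ss.fit_window_family(m, design, sizes={5})
        assert len(fam) == 4
        assert fam["w"].std() == pytest.approx(0.0, abs=1e-9)
        assert fam["w"].iloc[0] == pytest.approx(1.0, abs=1e-9)


class TestLmmEffectSize:
    @staticmethod
    def family(shift, sd=0.1, n_per=40, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for trt, mean in (("fallow", 0.4), ("cropping", 0.4 + shift)):
            for i in range(n_per):
                rows.append(
                    dict(treatment=trt, window_size=5 + i % 10, ystart=1 + i % 4,
                         site="site1", plot=f"site1.{trt}",
                         w=mean + sd * rng.standard_normal())
                )
        return pd.DataFrame(rows)

    def test_identical_groups_beta_near_zero(self):
        fam = self.family(shift=0.0, sd=0.0)
        es = ss.lmm_effect_size(fam, value="w", reference="fallow")
        assert abs(es.estimate) < 1e-8

    def test_injected_shift_recovered(self):
        fam = self.family(shift=-0.6, sd=0.1, seed=1)
        es = ss.lmm_effect_size(fam, value="w", reference="fallow")
        assert -0.7 < es.estimate < -0.5
        assert es.p_value < 0.05

    def test_sign_recovery_rate_on_strong_shifts(self):
        hits = 0
        for rep in range(100):
            fam = self.family(shift=-0.3, sd=0.1, n_per=20, seed=rep)
            es = ss.lmm_effect_size(fam, value="w", reference="fallow")
            hits += es.estimate < 0
        assert hits >= 95

    def test_single_level_rejected(self):
        fam = self.family(shift=0.0)
        with pytest.raises(ValueError, match="single level"):
            ss.lmm_effect_size(fam[fam["treatment"] == "fallow"], value="w")

    def test_ar1_request_noted(self):
        es = ss.lmm_effect_size(self.family(-0.2, seed=3), value="w",
                                reference="fallow", ar1_on_ystart=True)
        assert "AR(1)" in es.note


class TestSimpleEffectSizes:
    def test_lnrr_values_and_antisymmetry(self):
        assert ss.ln_response_ratio([2.0, 2.0], [2.0, 2.0]).estimate == 0.0
        es = ss.ln_response_ratio([2.0, 2.0, 2.0], [1.0, 1.0, 1.0])
        assert es.estimate == pytest.approx(np.log(2))
        a, b = [1.2, 1.5, 2.0], [0.7, 0.9, 1.1]
        assert ss.ln_response_ratio(a, b).estimate == pytest.approx(
            -ss.ln_response_ratio(b, a).estimate
        )

    def test_lnrr_variance_formula(self):
        a, b = np.array([2.0, 3.0, 4.0]), np.array([1.0, 1.5, 2.5])
        es = ss.ln_response_ratio(a, b)
        want = a.var(ddof=1) / (3 * a.mean() ** 2) + b.var(ddof=1) / (3 * b.mean() ** 2)
        assert es.se**2 == pytest.approx(want)

    def test_lnrr_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            ss.ln_response_ratio([1.0, 2.0], [0.0, 0.0])

    def test_cohens_d_values_and_antisymmetry(self):
        assert ss.cohens_d([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]).estimate == 0.0
        es = ss.cohens_d([0.0, 1.0, 2.0], [-1.0, 0.0, 1.0])
        assert es.estimate == pytest.approx(1.0)
        a, b = [0.3, 0.9, 1.1], [0.5, 0.2, 0.8]
        assert ss.cohens_d(a, b).estimate == pytest.approx(-ss.cohens_d(b, a).estimate)

    def test_cohens_d_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            ss.cohens_d([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            ss.cohens_d([1.0, 1.0], [1.0, 1.0])


class TestSpearmanFdr:
    def test_monotone_pairs(self):
        rates = pd.DataFrame({"w": [1.0, 2, 3, 4, 5]})
        het = pd.DataFrame({"up": [2.0, 4, 5, 7, 9], "down": [9.0, 7, 5, 4, 2]})
        out = ss.spearman_fdr(rates, het).set_index("property")
        assert out.loc["up", "rho"] == pytest.approx(1.0)
        assert out.loc["down", "rho"] == pytest.approx(-1.0)

    def test_bh_adjustment_step_up_by_hand(self):
        # raw p (0.01, 0.04, 0.03) -> BH adjusted (0.03, 0.04, 0.04)
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([0.01, 0.04, 0.03], method="fdr_bh")[1]
        assert np.allclose(adj, [0.03, 0.04, 0.04])
        rng = np.random.default_rng(0)
        rates = pd.DataFrame({"a": rng.normal(size=8), "b": rng.normal(size=8)})
        het = pd.DataFrame({"x": rng.normal(size=8), "y": rng.normal(size=8)},
                           index=rates.index)
        out = ss.spearman_fdr(rates, het)
        manual = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        assert np.allclose(out["p_adjusted"].to_numpy(), manual)

    def test_constant_vector_flagged(self):
        rates = pd.DataFrame({"w": [1.0, 1, 1, 1, 1]})
        het = pd.DataFrame({"x": [1.0, 2, 3, 4, 5]})
        out = ss.spearman_fdr(rates, het)
        assert out["undefined"].iloc[0]
        assert np.isnan(out["rho"].iloc[0])

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            ss.spearman_fdr(pd.DataFrame({"w": [1.0, 2]}),
                            pd.DataFrame({"x": [1.0, 2]}))
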