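import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode
from skbio.diversity.alpha import faith_pd as skbio_faith_pd

import starscale as ss
from starscale.accumulation import (
    CommunityMatrix,
    complete_nested_curve,
    island_curve,
    pool_counts_by_scale,
    standardize_depth,
)

from conftest import brute_force_surface, random_toy_matrix


class TestFaithPD:
    @pytest.mark.parametrize(
        "taxa, expected",
        [(["A", "B", "C"], 10.0), (["A", "B"], 6.0), (["A"], 4.0),
         (["B"], 5.0), (["C"], 4.0), ([], 0.0)],
    )
    def test_toy_tree_path_sums(self, toy_tree, taxa, expected):
        assert ss.faith_pd(taxa, toy_tree) == pytest.approx(expected)

    def test_unknown_tip_rejected(self, toy_tree):
        with pytest.raises(ValueError, match="unknown"):
            ss.faith_pd(["A", "Z"], toy_tree)

    def test_monotone_under_inclusion_and_matches_skbio(self):
        tree = ss.simulate_tree(30, seed=5)
        tips = [f"t{i + 1}" for i in range(30)]
        rng = np.random.default_rng(0)
        prev = 0.0
        chosen: list = []
        for size in (1, 5, 12, 30):
            extra = [t for t in tips if t not in chosen]
            chosen = chosen + list(rng.choice(extra, size - len(chosen), replace=False))
            val = ss.faith_pd(chosen, tree)
            assert val >= prev
            prev = val
            counts = [1 if t in chosen else 0 for t in tips]
            assert val == pytest.approx(skbio_faith_pd(counts, taxa=tips, tree=tree))
        total = sum(n.length for n in tree.traverse(include_self=False))
        assert ss.faith_pd(tips, tree) == pytest.approx(total)

    def test_root_exclusive_option_drops_path_above_mrca(self, toy_tree):
        assert ss.faith_pd(["A", "B"], toy_tree, include_root=False) == pytest.approx(3.0)
        assert ss.faith_pd(["A", "C"], toy_tree, include_root=False) == pytest.approx(8.0)


class TestNestedSurface:
    def test_single_cell_counts_positive_taxa(self):
        design = ss.make_design(1, 1, 1, 1, 1)
        meta = design.sample_index()
        m = CommunityMatrix(
            pd.DataFrame([[0, 3, 1]], index=meta.index, columns=["a", "b", "c"]),
            meta,
        )
        surf = ss.build_accumulation_surface(m, design)
        assert len(surf) == 1
        assert surf["richness"].iloc[0] == 2

    def test_matches_exhaustive_union_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n_points = int(rng.integers(1, 4))
            m, design = random_toy_matrix(
                rng, n_taxa=int(rng.integers(2, 7)), n_points=n_points,
                n_times=int(rng.integers(1, 4)),
                n_levels=int(rng.integers(1, n_points + 1)),
            )
            surf = ss.build_accumulation_surface(m, design)
            oracle = brute_force_surface(m, design)
            merged = surf.merge(oracle, on=["area_level", "time_months"],
                                suffixes=("", "_oracle"))
            assert (merged["richness"] == merged["richness_oracle"]).all()

    def test_monotone_along_both_axes_with_pd(self, small_matrix, small_design):
        tree = ss.simulate_tree(80, seed=11)
        surf = ss.build_accumulation_surface(
            small_matrix, small_design, tree=tree, site="site1", treatment="fallow"
        )
        for col in ("richness", "pd"):
            grid = surf.pivot_table(index="area_level", columns="time_months",
                                    values=col).to_numpy()
            assert (np.diff(grid, axis=0) >= -1e-9).all()
            assert (np.diff(grid, axis=1) >= -1e-9).all()

    def test_missing_cell_policy(self, small_matrix, small_design):
        clipped = CommunityMatrix(
            small_matrix.counts.iloc[:-1], small_matrix.meta.iloc[:-1]
        )
        with pytest.raises(ValueError, match="missing"):
            ss.build_accumulation_surface(clipped, small_design,
                                          site="site1", treatment="cropping")
        with pytest.warns(UserWarning, match="skipping"):
            ss.build_accumulation_surface(clipped, small_design, site="site1",
                                          treatment="cropping", on_missing="skip")

    def test_unknown_temporal_method_rejected(self, small_matrix, small_design):
        with pytest.raises(ValueError, match="temporal_method"):
            ss.build_accumulation_surface(small_matrix, small_design,
                                          temporal_method="bogus",
                                          site="site1", treatment="fallow")


class TestCompleteNested:
    def test_toy_window_means_by_hand(self):
        # K=3 with per-month taxon sets {a},{b},{a}: T=2 windows give
        # |{a,b}| and |{b,a}| -> mean 2; T=1 gives mean per-month richness 1.
        design = ss.make_design(1, 1, 1, 3, 1)
        meta = design.sample_index()
        m = CommunityMatrix(
            pd.DataFrame([[1, 0], [0, 1], [1, 0]], index=meta.index,
                         columns=["a", "b"]),
            meta,
        )
        curve = complete_nested_curve(m, design)
        vals = curve.set_index("time_months")["richness"]
        assert vals.loc[1.0] == pytest.approx(1.0)
        assert vals.loc[2.0] == pytest.approx(2.0)
        assert vals.loc[3.0] == pytest.approx(2.0)

    def test_terminal_window_equals_nested_terminal(self, small_matrix, small_design):
        nested = ss.build_accumulation_surface(small_matrix, small_design,
                                               site="site1", treatment="fallow")
        complete = complete_nested_curve(small_matrix, small_design,
                                         site="site1", treatment="fallow")
        K = max(small_design.time_points)
        for lvl in (1, 2, 3):
            a = nested.query("area_level == @lvl and time_months == @K")["richness"]
            b = complete.query("area_level == @lvl and time_months == @K")["richness"]
            assert float(a.iloc[0]) == pytest.approx(float(b.iloc[0]))

    def test_single_timepoint_rejected(self):
        design = ss.make_design(1, 1, 2, 1, 1)
        meta = design.sample_index()
        m = CommunityMatrix(
            pd.DataFrame([[1], [1]], index=meta.index, columns=["a"]), meta
        )
        with pytest.raises(ValueError):
            complete_nested_curve(m, design)


class TestIslandCurve:
    def test_points_are_per_survey_richness(self, toy_tree):
        surveys = [
            (5, pd.DataFrame({"A": [1, 0], "B": [0, 2], "C": [0, 0]})),
            (2, pd.DataFrame({"A": [3], "B": [0], "C": [0]})),
            (9, pd.DataFrame({"A": [1], "B": [1], "C": [1]})),
        ]
        curve = island_curve(surveys, tree=toy_tree)
        assert list(curve["time_months"]) == [5.0, 2.0, 9.0]
        assert list(curve["richness"]) == [2.0, 1.0, 3.0]
        assert curve["pd"].iloc[2] == pytest.approx(10.0)

    def test_identical_surveys_same_richness_different_duration(self):
        counts = pd.DataFrame({"A": [1], "B": [2]})
        curve = island_curve([(3, counts), (7, counts)])
        assert curve["richness"].nunique() == 1
        assert curve["time_months"].nunique() == 2

    def test_empty_survey_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            island_curve([(1, pd.DataFrame({"A": [0]}))])


class TestStandardizeDepth:
    def test_hypergeometric_closed_form_toy(self):
        pooled = pd.DataFrame([[5, 3, 2]], index=["s"], columns=list("abc"))
        res = standardize_depth(pooled, 5, n_reps=1000, seed=7)
        expected = 3 - (1 + 21 + 56) / 252
        assert res["richness_expected"].iloc[0] == pytest.approx(expected)
        # Monte-Carlo mean within 3 SE of the closed form
        se = 0.5 / np.sqrt(1000)
        assert abs(res["richness_rarefied"].iloc[0] - expected) < 3 * max(se, 0.02)

    def test_full_depth_keeps_richness(self):
        pooled = pd.DataFrame([[4, 1, 0, 7]], index=["s"], columns=list("abcd"))
        res = standardize_depth(pooled, 12, n_reps=5, seed=0)
        assert res["richness_rarefied"].iloc[0] == res["richness_observed"].iloc[0] == 3

    def test_subsample_never_exceeds_observed_richness(self):
        rng = np.random.default_rng(3)
        pooled = pd.DataFrame(rng.integers(0, 30, size=(4, 12)))
        pooled.columns = [f"t{i}" for i in range(12)]
        target = int(pooled.sum(axis=1).min())
        res = standardize_depth(pooled, target, n_reps=20, seed=1)
        assert (res["richness_rarefied"] <= res["richness_observed"] + 1e-9).all()

    def test_target_above_pool_rejected(self):
        pooled = pd.DataFrame([[2, 2]], index=["s"], columns=["a", "b"])
        with pytest.raises(ValueError, match="target_depth"):
            standardize_depth(pooled, 10)


def test_pool_counts_by_scale_nested_totals(small_matrix, small_design):
    pooled = pool_counts_by_scale(small_matrix, small_design, axis="time",
                                  site="site1", treatment="fallow")
    totals = pooled.sum(axis=1).to_numpy()
    assert (np.diff(totals) > 0).all()  # nested pools grow
    sub = small_matrix.plot("site1", "fallow")
    assert totals[-1] == sub.counts.to_numpy().sum()
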