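"""Landscape-edit scenarios, re-costing of fixed pathways, two-way ANOVA and
Holm-corrected paired tests against reference-library oracles."""

import numpy as np
import pandas as pd
import pytest
import shapely

import corridorscape as cs
from corridorscape import scenarios as scen


class TestApplyScenario:
    def test_tunnel_increases_distance_near_removed_segment(
            self, small_landscape):
        _, stack, features = small_landscape
        road = features.roads[0].geometry
        mid = road.length / 2
        spec = scen.ScenarioSpec("t", [scen.Tunnel(0, mid - 500, mid + 500)])
        st2, ft2 = scen.apply_scenario(stack, features, spec)
        d0, d1 = stack["dist_road"].values, st2["dist_road"].values
        assert (d1 >= d0 - 1e-9).all()
        assert (d1 > d0 + 1e-9).any()
        # cells whose nearest road point survives are unchanged
        assert np.isclose(d1, d0).any()
        # untouched layers bit-identical
        np.testing.assert_array_equal(st2["elevation"].values,
                                      stack["elevation"].values)

    def test_remove_all_large_residences_gives_cap(self, small_landscape):
        _, stack, features = small_landscape
        spec = scen.ScenarioSpec("r", [scen.RemoveResidences("large")])
        st2, ft2 = scen.apply_scenario(stack, features, spec)
        assert not ft2.residence_geometries("large")
        cap = stack.grid.diagonal
        np.testing.assert_allclose(st2["dist_large_residence"].values, cap)
        # small residences untouched
        np.testing.assert_array_equal(st2["dist_small_residence"].values,
                                      stack["dist_small_residence"].values)

    def test_restoration_masks_correctly(self, small_landscape):
        _, stack, features = small_landscape
        region = shapely.box(1000, 1000, 2500, 2500)
        spec = scen.ScenarioSpec("f", [scen.RestoreForest(region)])
        st2, _ = scen.apply_scenario(stack, features, spec)
        xs, ys = stack.grid.cell_centers()
        inside = shapely.contains(
            region, shapely.points(xs.ravel(), ys.ravel())
        ).reshape(stack.grid.shape)
        assert (st2["forest_age"].values[inside] == 1.0).all()
        assert (st2["bamboo"].values[inside] == 1.0).all()
        np.testing.assert_array_equal(st2["forest_age"].values[~inside],
                                      stack["forest_age"].values[~inside])

    def test_empty_selection_warns_noop(self, small_landscape):
        _, stack, features = small_landscape
        spec = scen.ScenarioSpec(
            "r", [scen.RemoveResidences("large", shapely.box(-10, -10, -5, -5))])
        with pytest.warns(UserWarning, match="no residences matched"):
            st2, ft2 = scen.apply_scenario(stack, features, spec)
        assert len(ft2.residences) == len(features.residences)

    def test_original_inputs_untouched(self, small_landscape):
        _, stack, features = small_landscape
        before = stack["forest_age"].values.copy()
        spec = scen.ScenarioSpec(
            "f", [scen.RestoreForest(shapely.box(0, 0, 5000, 4000))])
        scen.apply_scenario(stack, features, spec)
        np.testing.assert_array_equal(stack["forest_age"].values, before)


class TestScenarioCosts:
    def test_baseline_column_matches_original_indices(self, valley_case,
                                                      valley_matrix):
        orig = [p.cost_index for p in valley_case["paths"].paths
                if p.flag != "infeasible"]
        np.testing.assert_allclose(valley_matrix["baseline"].to_numpy(), orig,
                                   rtol=1e-12)

    def test_identity_scenario_identical_column(self, valley_case):
        m = scen.scenario_costs(
            valley_case["stack"], valley_case["features"],
            [scen.ScenarioSpec("noop", [])], valley_case["avg"],
            valley_case["paths"])
        np.testing.assert_array_equal(m["noop"], m["baseline"])

    def test_cost_lowering_edit_lowers_every_path(self, valley_case,
                                                  valley_matrix):
        # restoration touches the valley band every path must cross
        assert (valley_matrix["restoration"] < valley_matrix["baseline"]).all()

    def test_qualitative_ordering(self, valley_matrix):
        means = valley_matrix.mean()
        assert means["tunnel"] < means["restoration"] < means["baseline"]
        assert means["relocation"] == pytest.approx(means["baseline"])


class TestTwoWayAnova:
    def test_constant_matrix_gives_zero_F(self):
        M = pd.DataFrame(np.full((6, 3), 7.0))
        tab = scen.two_way_anova(M).set_index("factor")
        assert tab.loc["scenario", "F"] == 0.0
        assert tab.loc["pathway", "F"] == 0.0

    def test_degrees_of_freedom_layout(self):
        M = pd.DataFrame(np.random.default_rng(0).random((25, 4)))
        tab = scen.two_way_anova(M).set_index("factor")
        assert tab.loc["scenario", "df"] == 3
        assert tab.loc["pathway", "df"] == 24
        assert tab.loc["residual", "df"] == 72

    def test_sum_of_squares_conservation(self):
        rng = np.random.default_rng(1)
        M = pd.DataFrame(rng.random((10, 4)))
        tab = scen.two_way_anova(M).set_index("factor")
        total = ((M.to_numpy() - M.to_numpy().mean()) ** 2).sum()
        assert tab["SS"].sum() == pytest.approx(total, rel=1e-10)

    def test_matches_statsmodels_oracle(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(42)
        M = pd.DataFrame(rng.normal(10, 2, (25, 4)),
                         columns=list("abcd"))
        long = M.reset_index().melt(id_vars="index", var_name="scenario",
                                    value_name="cost")
        fit = ols("cost ~ C(scenario) + C(index)", data=long).fit()
        oracle = sm.stats.anova_lm(fit, typ=2)
        tab = scen.two_way_anova(M).set_index("factor")
        assert tab.loc["scenario", "F"] == pytest.approx(
            oracle.loc["C(scenario)", "F"], rel=1e-8)
        assert tab.loc["scenario", "p"] == pytest.approx(
            oracle.loc["C(scenario)", "PR(>F)"], rel=1e-8)
        assert tab.loc["pathway", "F"] == pytest.approx(
            oracle.loc["C(index)", "F"], rel=1e-8)

    def test_incomplete_matrix_rejected(self):
        M = pd.DataFrame(np.random.default_rng(0).random((5, 3)))
        M.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            scen.two_way_anova(M)


class TestHolm:
    def test_hand_computed_case(self):
        np.testing.assert_allclose(
            scen.holm_adjust([0.01, 0.03, 0.04]), [0.03, 0.06, 0.06],
            atol=1e-12)

    def test_single_comparison_identity(self):
        np.testing.assert_allclose(scen.holm_adjust([0.037]), [0.037])

    def test_never_below_raw_and_monotone(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.random(rng.integers(2, 8))
            adj = scen.holm_adjust(p)
            assert (adj >= p - 1e-15).all()
            order = np.argsort(p)
            assert (np.diff(adj[order]) >= -1e-15).all()
            assert (adj <= 1.0).all()

    def test_matches_statsmodels_multipletests(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.random(6)
        _, oracle, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(scen.holm_adjust(p), oracle, atol=1e-12)


class TestPairedTests:
    def test_t_matches_scipy_reference(self):
        rng = np.random.default_rng(11)
        M = pd.DataFrame(rng.normal(size=(25, 4)), columns=list("wxyz"))
        res = scen.holm_paired_tests(M, [("w", "x"), ("y", "z")])
        from scipy.stats import ttest_rel
        t, p = ttest_rel(M["w"], M["x"])
        assert res.loc[0, "t"] == pytest.approx(t, rel=1e-12)
        assert res.loc[0, "p_raw"] == pytest.approx(p, rel=1e-12)

    def test_identical_columns_reported_undefined(self):
        M = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        res = scen.holm_paired_tests(M, [("a", "b")])
        assert np.isnan(res.loc[0, "t"])
        assert res.loc[0, "p_holm"] == 1.0
        assert not res.loc[0, "significant"]

    def test_scenario_pattern_on_valley_fixture(self, valley_matrix):
        cmp = scen.compare_scenarios(
            valley_matrix,
            [("restoration", "baseline"), ("relocation", "baseline"),
             ("tunnel", "baseline"), ("tunnel", "restoration")])
        res = cmp.pairwise.set_index(["a", "b"])
        assert res.loc[("restoration", "baseline"), "significant"]
        assert res.loc[("tunnel", "baseline"), "significant"]
        assert not res.loc[("relocation", "baseline"), "significant"]
        assert res.loc[("tunnel", "restoration"), "significant"]
        assert res.loc[("tunnel", "restoration"), "mean_diff"] < 0
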