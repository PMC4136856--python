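"""The statistical core: detection histories, the zero-inflated binomial
likelihood against closed forms and an independent oracle, the MLE against a
grid search, AIC bookkeeping, model averaging, and prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from corridorscape import occupancy as occ


def _oracle_nll(psi, p, y):
    """Independent per-site closed-form NLL: scalar loops, no vectorization
    shared with the implementation."""
    total = 0.0
    for i in range(y.shape[0]):
        cond = 1.0
        all_zero = True
        for t in range(y.shape[1]):
            if np.isnan(y[i, t]):
                continue
            pit = p[i, t] if np.ndim(p) == 2 else p
            if y[i, t] == 1:
                cond *= pit
                all_zero = False
            else:
                cond *= 1 - pit
        L = psi[i] * cond + (1 - psi[i]) * (1.0 if all_zero else 0.0)
        total -= np.log(L)
    return total


def _nll(psi_logit, p_logit, y):
    n = y.shape[0]
    table = pd.DataFrame(index=range(n))
    X = np.ones((n, 1))
    D = [np.ones_like(y)]
    return occ.occupancy_negloglik(np.array([psi_logit, p_logit]), X, D, y)


class TestBuildDetectionHistory:
    def _deps(self, rows):
        return pd.DataFrame(rows)

    def test_38_day_deployment_gives_7_occasions(self):
        deps = self._deps([{"site_id": "a", "n_days": 38}])
        dets = pd.DataFrame({"site_id": [], "day": []})
        hist, excluded = occ.build_detection_history(deps, dets)
        assert hist.n_occasions == 7      # 35 days used, 3 dropped
        assert not excluded

    def test_detection_day_maps_to_occasion(self):
        deps = self._deps([{"site_id": "a", "n_days": 20}])
        dets = pd.DataFrame({"site_id": ["a"], "day": [12]})
        hist, _ = occ.build_detection_history(deps, dets)
        np.testing.assert_array_equal(hist.y[0], [0, 0, 1, 0])

    def test_short_deployment_excluded_with_warning(self):
        deps = self._deps([{"site_id": "a", "n_days": 4},
                           {"site_id": "b", "n_days": 10}])
        dets = pd.DataFrame({"site_id": [], "day": []})
        with pytest.warns(UserWarning, match="excluded"):
            hist, excluded = occ.build_detection_history(deps, dets)
        assert excluded == ["a"]
        assert hist.site_ids == ["b"]

    def test_detection_outside_window_raises(self):
        deps = self._deps([{"site_id": "a", "n_days": 10}])
        dets = pd.DataFrame({"site_id": ["a"], "day": [10]})
        with pytest.raises(ValueError, match="outside deployment window"):
            occ.build_detection_history(deps, dets)

    def test_occasion_covariates_inherited(self):
        deps = self._deps([{"site_id": "a", "n_days": 10, "lure": 1,
                            "temperature": 2, "camera_view": 0}])
        dets = pd.DataFrame({"site_id": [], "day": []})
        hist, _ = occ.build_detection_history(deps, dets)
        assert (hist.occasion_covariates["lure"] == 1).all()
        assert (hist.occasion_covariates["temperature"] == 2).all()


class TestNegLogLik:
    def test_closed_form_no_detection(self):
        # psi=0.5, p=0.5, y=(0,0): L = 0.5*0.25 + 0.5 = 0.625
        y = np.array([[0.0, 0.0]])
        assert _nll(0.0, 0.0, y) == pytest.approx(-np.log(0.625), abs=1e-10)

    def test_closed_form_one_detection(self):
        # psi=0.8, p=0.5, y=(1,0): L = 0.8*0.25 = 0.2, NLL = 1.6094
        y = np.array([[1.0, 0.0]])
        nll = _nll(float(logit(0.8)), 0.0, y)
        assert nll == pytest.approx(-np.log(0.2), abs=1e-10)
        assert nll == pytest.approx(1.6094, abs=1e-4)

    def test_matches_independent_oracle_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            n, T = 25, rng.integers(2, 7)
            y = rng.integers(0, 2, (n, T)).astype(float)
            y[rng.random((n, T)) < 0.1] = np.nan
            y[np.all(np.isnan(y), axis=1), 0] = 0.0
            a, b = rng.normal(0, 1.5, 2)
            X = np.column_stack([np.ones(n), rng.standard_normal(n)])
            beta = rng.normal(0, 1, 2)
            psi = expit(X @ beta)
            p = expit(a + b * 0 + np.zeros_like(y))
            ours = occ.occupancy_negloglik(
                np.concatenate([beta, [a]]), X, [np.ones_like(y)], y)
            assert ours == pytest.approx(_oracle_nll(psi, expit(a), y),
                                         abs=1e-10)

    def test_site_order_invariance(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, (30, 5)).astype(float)
        X = np.column_stack([np.ones(30), rng.standard_normal(30)])
        params = np.array([0.3, -0.7, 0.1])
        perm = rng.permutation(30)
        a = occ.occupancy_negloglik(params, X, [np.ones_like(y)], y)
        b = occ.occupancy_negloglik(params, X[perm], [np.ones_like(y)], y[perm])
        assert a == pytest.approx(b, abs=1e-10)

    def test_occasion_permutation_invariance(self):
        rng = np.random.default_rng(4)
        y = rng.integers(0, 2, (20, 6)).astype(float)
        X = np.ones((20, 1))
        params = np.array([0.2, -0.4])
        perm = rng.permutation(6)
        a = occ.occupancy_negloglik(params, X, [np.ones_like(y)], y)
        b = occ.occupancy_negloglik(params, X, [np.ones_like(y)], y[:, perm])
        assert a == pytest.approx(b, abs=1e-10)

    def test_nonfinite_params_rejected(self):
        y = np.zeros((2, 2))
        with pytest.raises(ValueError):
            occ.occupancy_negloglik(np.array([np.nan, 0.0]), np.ones((2, 1)),
                                    [np.ones_like(y)], y)


class TestFitOccupancy:
    def test_all_detected_hits_boundary(self):
        y = np.ones((40, 5))
        hist = occ.DetectionHistory(y)
        fit = occ.fit_occupancy(occ.ModelSpec(), hist,
                                pd.DataFrame(index=range(40)), n_starts=2)
        assert fit.boundary
        assert expit(fit.beta[0]) > 0.999
        assert expit(fit.alpha[0]) > 0.999

    def test_intercept_only_matches_grid_search(self):
        rng = np.random.default_rng(21)
        n, T = 200, 5
        z = rng.random(n) < 0.55
        y = ((rng.random((n, T)) < 0.35) * z[:, None]).astype(float)
        hist = occ.DetectionHistory(y)
        fit = occ.fit_occupancy(occ.ModelSpec(), hist,
                                pd.DataFrame(index=range(n)), n_starts=2)
        X, D = np.ones((n, 1)), [np.ones_like(y)]
        # dense coarse-to-fine 2-D grid search oracle
        best = (np.inf, None)
        grid = np.arange(-4, 4, 0.05)
        for a in grid:
            for b in grid:
                v = occ.occupancy_negloglik(np.array([a, b]), X, D, y)
                if v < best[0]:
                    best = (v, (a, b))
        a0, b0 = best[1]
        for a in np.arange(a0 - 0.06, a0 + 0.06, 0.002):
            for b in np.arange(b0 - 0.06, b0 + 0.06, 0.002):
                v = occ.occupancy_negloglik(np.array([a, b]), X, D, y)
                best = min(best, (v, (a, b)))
        assert -fit.loglik == pytest.approx(best[0], abs=1e-4)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(6)
        n, T = 30, 4
        y = rng.integers(0, 2, (n, T)).astype(float)
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        lure = rng.integers(0, 2, (n, T)).astype(float)
        D = [np.ones_like(y), lure]
        params = rng.normal(0, 0.8, 4)
        f0, g = occ.occupancy_negloglik_grad(params, X, D, y)
        eps = 1e-6
        for k in range(4):
            dp = params.copy(); dp[k] += eps
            num = (occ.occupancy_negloglik(dp, X, D, y) - f0) / eps
            assert g[k] == pytest.approx(num, rel=1e-4, abs=1e-4)


class TestModelSetBookkeeping:
    def _fake_fit(self, aic_target, terms):
        # loglik chosen so AIC = aic_target with K = 1 + len(terms) + 1
        spec = occ.ModelSpec([(t, "raw") for t in terms], [])
        k = 2 + len(terms)
        f = occ.FitResult(spec, np.zeros(1 + len(terms)), np.zeros(1),
                          ["(intercept)"] + list(terms), ["(intercept)"],
                          loglik=-(aic_target - 2 * k) / 2, converged=True)
        assert f.aic == pytest.approx(aic_target)
        return f

    def test_two_model_weights(self):
        ms = occ.ModelSet([self._fake_fit(100.0, ["a"]),
                           self._fake_fit(102.0, ["b"])])
        np.testing.assert_allclose(ms.weights, [0.7311, 0.2689], atol=5e-4)
        assert ms.delta[0] == 0.0

    def test_cumulative_weight_is_one(self):
        ms = occ.ModelSet([self._fake_fit(100.0 + i, [f"c{i}"])
                           for i in range(5)])
        assert ms.cumulative[-1] == pytest.approx(1.0)
        assert (ms.weights > 0).all()

    def test_weights_shift_invariant(self):
        a = occ.ModelSet([self._fake_fit(100.0, ["a"]),
                          self._fake_fit(103.0, ["b"])])
        b = occ.ModelSet([self._fake_fit(600.0, ["a"]),
                          self._fake_fit(603.0, ["b"])])
        np.testing.assert_allclose(a.weights, b.weights, atol=1e-12)

    def test_single_model_average_is_identity(self):
        f = self._fake_fit(100.0, ["a"])
        f.beta = np.array([0.5, -1.2])
        avg = occ.model_average(occ.ModelSet([f, self._fake_fit(110.0, ["b"])]))
        assert avg.coefficients["a"] == pytest.approx(-1.2)
        assert avg.coefficients["(intercept)"] == pytest.approx(0.5)
        assert avg.importance["a"] == pytest.approx(1.0)

    def test_zero_substitution_halves_coefficient(self):
        f1 = self._fake_fit(100.0, ["a"])
        f1.beta = np.array([0.0, 1.0])
        f2 = self._fake_fit(100.0, [])
        avg = occ.model_average(occ.ModelSet([f1, f2]))
        # equal AIC -> equal weights; "a" present in one of two models
        assert avg.coefficients["a"] == pytest.approx(0.5)
        assert avg.importance["a"] == pytest.approx(0.5)

    def test_covariate_in_every_top_model_has_importance_one(self):
        fits = [self._fake_fit(100.0, ["elev"]),
                self._fake_fit(101.0, ["elev", "slope"]),
                self._fake_fit(109.0, ["slope"])]  # outside the top set
        avg = occ.model_average(occ.ModelSet(fits))
        assert avg.importance["elev"] == pytest.approx(1.0)


class TestSelectionSimulations:
    def _simulate_lure_effect(self, rng, n=250, T=8):
        x = rng.standard_normal(n)
        z = rng.random(n) < expit(0.3 + 0.9 * x)
        lure = rng.integers(0, 2, (n, T)).astype(float)
        temp = rng.integers(0, 3, (n, T)).astype(float)
        view = rng.integers(0, 2, (n, T)).astype(float)
        p = expit(-0.4 + 1.5 * lure)   # strong lure, no temp/view effect
        y = (rng.random((n, T)) < z[:, None] * p).astype(float)
        hist = occ.DetectionHistory(
            y, {"lure": lure, "temperature": temp, "camera_view": view})
        return pd.DataFrame({"x": x}), hist

    def test_strong_lure_effect_selected(self):
        # the true lure effect must always be retained; null covariates may
        # slip in at AIC's well-known background rate, so they are only
        # bounded, not forbidden
        rng = np.random.default_rng(31)
        lure_wins, spurious = 0, 0
        n_reps = 12
        for _ in range(n_reps):
            table, hist = self._simulate_lure_effect(rng)
            det, _ = occ.select_detection_model(
                hist, table, [("x", "raw")], n_starts=1)
            lure_wins += "lure" in det
            spurious += len(set(det) - {"lure"})
        assert lure_wins >= 0.8 * n_reps
        assert spurious <= n_reps  # on average at most one extra term

    def test_empty_pool_returns_empty(self):
        rng = np.random.default_rng(32)
        table, hist = self._simulate_lure_effect(rng, n=60, T=4)
        det, mset = occ.select_detection_model(hist, table, [("x", "raw")],
                                               det_pool=[], n_starts=1)
        assert det == []
        assert len(mset.fits) == 1


class TestPrediction:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(77)
        n, T = 300, 8
        x1, x2 = rng.standard_normal(n), rng.standard_normal(n)
        psi = expit(0.2 - 1.0 * x1 + 0.7 * x2)
        z = rng.random(n) < psi
        y = (rng.random((n, T)) < z[:, None] * 0.5).astype(float)
        table = pd.DataFrame({"x1": x1, "x2": x2})
        hist = occ.DetectionHistory(y)
        mset = occ.all_subsets_selection(hist, table, [],
                                         [("x1", "raw"), ("x2", "raw")],
                                         n_starts=1)
        return table, occ.model_average(mset)

    def test_prediction_consistent_with_table_rows(self, fitted):
        table, avg = fitted
        psi = occ.predict_at_table(avg, table)
        assert psi.shape == (len(table),)
        assert ((psi >= 0) & (psi <= 1)).all()
        v, curve = occ.partial_response(avg, table, "x1",
                                        values=np.array([table["x1"].mean()]))
        ref = occ.predict_at_table(avg, pd.DataFrame(
            {"x1": [table["x1"].mean()], "x2": [table["x2"].mean()]}))
        assert curve[0] == pytest.approx(ref[0], abs=1e-12)

    def test_negative_coefficient_monotone_decreasing(self, fitted):
        table, avg = fitted
        _, curve = occ.partial_response(avg, table, "x1", n=50)
        assert (np.diff(curve) < 0).all()

    def test_quadratic_partial_response_unimodal(self):
        avg = occ.AveragedModel(
            coefficients={"(intercept)": 1.0, "x": 0.0, "x^2": -1.5},
            det_coefficients={}, importance={"x": 1.0},
            terms=[("x", "quadratic")], standardization={"x": (0.0, 1.0)})
        table = pd.DataFrame({"x": np.linspace(-3, 3, 10)})
        _, curve = occ.partial_response(avg, table, "x", n=41)
        peak = np.argmax(curve)
        assert 0 < peak < 40
        assert (np.diff(curve[:peak + 1]) > 0).all()
        assert (np.diff(curve[peak:]) < 0).all()

    def test_zero_coefficients_give_half(self, small_landscape):
        _, stack, _ = small_landscape
        avg = occ.AveragedModel(
            coefficients={"(intercept)": 0.0, "elevation": 0.0},
            det_coefficients={}, importance={"elevation": 1.0},
            terms=[("elevation", "raw")],
            standardization={"elevation": (1500.0, 300.0)})
        psi = occ.predict_suitability(avg, stack)
        np.testing.assert_allclose(psi.values, 0.5)

    def test_missing_layer_raises(self, small_landscape):
        _, stack, _ = small_landscape
        avg = occ.AveragedModel(
            coefficients={"(intercept)": 0.0, "ghost": 1.0},
            det_coefficients={}, importance={}, terms=[("ghost", "raw")],
            standardization={})
        with pytest.raises(ValueError, match="lacks layer"):
            occ.predict_suitability(avg, stack)
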