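"""Tests of the product-limit estimator, adapters and curve-set construction."""

import numpy as np
import pytest

import ipcwbrier as ib
from ipcwbrier.estimators import StepCurves, breslow_baseline, cross_validated_criterion


class TestReverseKaplanMeier:
    def test_hand_worked_single_censoring(self):
        # censoring event at t=2 with two subjects at risk: G drops to 1/2
        G = ib.reverse_kaplan_meier(np.array([1.0, 2.0, 3.0]), np.array([1, 0, 1]))
        assert G(1.9) == 1.0
        assert G(2.0) == 0.5
        assert G(5.0) == 0.5
        assert G.left(2.0) == 1.0

    def test_no_censoring_events_gives_constant_one(self):
        G = ib.reverse_kaplan_meier(np.array([1.0, 2.0, 3.0]), np.ones(3))
        assert np.all(G(np.linspace(0, 10, 20)) == 1.0)

    def test_all_censored_reaches_zero(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        G = ib.reverse_kaplan_meier(times, np.zeros(4))
        assert G(4.0) == 0.0
        # one minus the empirical censoring CDF at every point
        for t in [0.5, 1.5, 2.5, 3.5]:
            assert G(t) == (times > t).mean()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ib.kaplan_meier(np.array([]), np.array([]))

    def test_role_swap_symmetry(self):
        rng = np.random.default_rng(14)
        times = rng.exponential(size=50)
        status = rng.integers(0, 2, size=50)
        # KM of the censoring process == reverse KM of the event process
        a = ib.kaplan_meier(times, status == 0)
        b = ib.reverse_kaplan_meier(times, status)
        grid = np.linspace(0.01, 3, 50)
        np.testing.assert_array_equal(a(grid), b(grid))

    def test_agrees_with_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(15)
        times = rng.exponential(size=200)
        status = rng.integers(0, 2, size=200)
        ours = ib.kaplan_meier(times, status == 1)
        kmf = KaplanMeierFitter().fit(times, status)
        grid = np.linspace(0.01, times.max() * 1.1, 50)
        theirs = kmf.survival_function_at_times(grid).to_numpy()
        np.testing.assert_allclose(ours(grid), theirs, atol=1e-10)


class TestStepCurves:
    def test_right_continuity_and_left_limits(self):
        sc = StepCurves(np.array([1.0, 2.0]), np.array([[0.8, 0.4]]))
        np.testing.assert_array_equal(sc.eval(np.array([0.5, 1.0, 1.5, 2.0, 3.0]))[0], [1.0, 0.8, 0.8, 0.4, 0.4])
        # left limit at a jump is the preceding step value, not the new one
        assert sc.eval_left(np.array([2.0]))[0] == 0.8
        assert sc.eval_left(np.array([1.0]))[0] == 1.0


class TestTimeGrid:
    def test_regular_grid_properties(self):
        g = ib.TimeGrid.regular(10.0, 100)
        assert g.k == 100
        assert g.points[0] > 0
        assert np.allclose(np.diff(g.points), g.points[0])

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            ib.TimeGrid(np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            ib.TimeGrid(np.array([1.0, 2.0, 4.0]))


class TestAdapters:
    def test_km_censoring_curves_identical_across_individuals(self, small_cohort):
        data = ib.SurvivalData.from_cohort(small_cohort)
        grid = ib.TimeGrid.regular(3.0, 50)
        G = ib.fit_censoring_model(ib.get_adapter("km"), data, data, grid)
        assert G.role == "censoring"
        assert np.all(G.values == G.values[0])
        marginal = ib.reverse_kaplan_meier(data.time, data.status)
        np.testing.assert_allclose(G.values[0], marginal(grid.points))

    def test_cox_recovers_ph_coefficients(self, event_params, spec10):
        # large Weibull cohort: Cox partial likelihood estimates beta = -gamma/sigma
        cohort = ib.generate_cohort(
            event_params, ib.WeibullAFTParams.marginal_exponential(1e-9), spec10, 4000, seed=16
        )
        data = ib.SurvivalData.from_cohort(cohort)
        from lifelines import CoxPHFitter
        import pandas as pd

        df = pd.DataFrame(data.Z, columns=[f"z{j}" for j in range(10)])
        df["time"], df["event"] = data.time, data.status
        beta_hat = CoxPHFitter().fit(df, "time", "event").params_.to_numpy()
        np.testing.assert_allclose(beta_hat, event_params.ph_coefs, atol=0.15)

    def test_cox_separates_censoring_groups_correctly(self, spec10):
        # two covariate groups with different censoring scales: predicted G
        # curves must separate in the true order
        rng = np.random.default_rng(17)
        n = 2000
        z = np.where(rng.uniform(size=n) < 0.5, 1.0, -1.0)[:, None]
        cens_params = ib.WeibullAFTParams(mu=0.0, sigma=0.58, gamma=np.array([0.8]), role="censoring")
        event_params = ib.WeibullAFTParams(mu=0.5, sigma=0.58, gamma=np.array([0.1]))
        T = ib.sample_aft_times(event_params, z, seed=18)
        C = ib.sample_aft_times(cens_params, z, seed=19)
        data = ib.SurvivalData(np.minimum(T, C), (T <= C).astype(int), z)
        grid = ib.TimeGrid.regular(2.0, 50)
        G = ib.fit_censoring_model(ib.get_adapter("cox"), data, data, grid)
        hi = G.values[data.Z[:, 0] > 0].mean(axis=0)  # gamma>0: longer censoring times
        lo = G.values[data.Z[:, 0] < 0].mean(axis=0)
        true_hi = ib.true_survival(cens_params, np.array([1.0]), grid.points)
        assert np.all(hi[10:40] > lo[10:40])
        assert np.max(np.abs(hi - true_hi)) < 0.1

    def test_km_matches_covariate_free_cox(self, small_cohort):
        # constant-hazard data with no informative covariates: Cox with a
        # zero coefficient reduces to the product-limit estimate
        rng = np.random.default_rng(20)
        n = 20
        times = rng.exponential(size=n)
        status = rng.integers(0, 2, size=n)
        data = ib.SurvivalData(times, status, np.zeros((n, 1)))
        grid = ib.TimeGrid.regular(2.0, 25)
        from ipcwbrier.estimators import breslow_baseline, PHPredictor

        jumps, h0 = breslow_baseline(times, status == 1, np.zeros(n))
        cox_like = PHPredictor(jumps, h0, lambda Z: np.zeros(Z.shape[0]))
        km = ib.kaplan_meier(times, status == 1)
        # Breslow exp(-H) and the product-limit agree asymptotically; on 20
        # observations they track closely while the risk set is still large
        cox_vals = cox_like.step_curves(data.Z).eval(grid.points)[0]
        km_vals = km(grid.points)
        head = km_vals >= 0.4
        np.testing.assert_allclose(cox_vals[head], km_vals[head], atol=0.05)

    @pytest.mark.parametrize("name", ["coxnet", "rsf", "xgb"])
    def test_ml_adapters_emit_valid_curve_sets(self, name, small_cohort):
        data = ib.SurvivalData.from_cohort(small_cohort)
        grid = ib.TimeGrid.regular(3.0, 40)
        G = ib.fit_censoring_model(ib.get_adapter(name), data, data, grid, seed=21)
        assert G.values.shape == (data.n, 40)
        assert np.all((G.values >= 0) & (G.values <= 1))
        assert np.all(np.diff(G.values, axis=1) <= 1e-12)
        assert G.left_limits is not None
        # left limit is at least the curve value at the first grid point >= T*
        pos = np.searchsorted(grid.points, data.time)
        inside = np.flatnonzero(pos < grid.k)
        assert np.all(G.left_limits[inside] >= G.values[inside, pos[inside]] - 1e-12)

    def test_unknown_adapter_name(self):
        with pytest.raises(KeyError):
            ib.get_adapter("nope")

    def test_degenerate_split_falls_back_to_constant_one(self, spec10, event_params):
        cohort = ib.generate_cohort(event_params, ib.WeibullAFTParams.marginal_exponential(1e-9), spec10, 30, seed=22)
        data = ib.SurvivalData.from_cohort(cohort)  # no censoring events at all
        grid = ib.TimeGrid.regular(2.0, 20)
        with pytest.warns(RuntimeWarning, match="no censoring events"):
            G = ib.fit_censoring_model(ib.get_adapter("cox"), data, data, grid)
        assert np.all(G.values == 1.0)


class TestBreslow:
    def test_no_covariates_matches_nelson_aalen(self):
        times = np.array([1.0, 2.0, 3.0, 4.0])
        events = np.array([True, True, False, True])
        jumps, h0 = breslow_baseline(times, events, np.zeros(4))
        np.testing.assert_allclose(jumps, [1.0, 2.0, 4.0])
        np.testing.assert_allclose(h0, np.cumsum([1 / 4, 1 / 3, 1 / 1]))


class TestTuning:
    def test_cox_returned_unchanged(self, small_cohort):
        data = ib.SurvivalData.from_cohort(small_cohort)
        adapter = ib.get_adapter("cox")
        assert ib.tune(adapter, data, budget=5, seed=23) is adapter

    def test_budget_one_returns_default_configuration(self, small_cohort):
        data = ib.SurvivalData.from_cohort(small_cohort)
        adapter = ib.get_adapter("xgb")
        tuned = ib.tune(adapter, data, budget=1, seed=24)
        assert tuned.params == adapter.params

    def test_tuned_criterion_never_worse_than_default(self, small_cohort):
        data = ib.SurvivalData.from_cohort(small_cohort)
        adapter = ib.get_adapter("xgb")
        tuned = ib.tune(adapter, data, budget=4, seed=25)
        c_tuned = cross_validated_criterion(tuned, data, seed=25)
        c_default = cross_validated_criterion(adapter, data, seed=25)
        assert c_tuned <= c_default + 1e-12

    def test_invalid_budget(self, small_cohort):
        data = ib.SurvivalData.from_cohort(small_cohort)
        with pytest.raises(ValueError):
            ib.tune(ib.get_adapter("rsf"), data, budget=0)
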