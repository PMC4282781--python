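"""Cox engine: partial likelihood, Breslow baseline, Schoenfeld residuals."""

import numpy as np
import pandas as pd
import pytest

from coxsens import (
    CoxFitError,
    SurvivalDataset,
    breslow_cumhaz,
    fit_cox,
    schoenfeld_residuals,
)


def breslow_partial_loglik(beta, time, event, z):
    """Independent brute-force Breslow partial log-likelihood (1 covariate)."""
    ll = 0.0
    for t in sorted(set(time[event == 1])):
        risk = time >= t
        d = int(((time == t) & (event == 1)).sum())
        ll += float(beta * z[(time == t) & (event == 1)].sum())
        ll -= d * np.log(np.exp(beta * z[risk]).sum())
    return ll


class TestFitCox:
    def test_exchangeable_groups_give_zero_coefficient(self):
        # two groups with event/censoring patterns exactly exchanged
        ds = SurvivalDataset(
            time=[1, 2, 3, 1, 2, 3],
            event=[1, 0, 1, 1, 0, 1],
            covariates=np.array([0, 0, 0, 1, 1, 1.0])[:, None],
            covariate_names=["g"],
            tau=4,
        )
        fit = fit_cox(ds)
        assert abs(fit.beta[0]) < 1e-8

    def test_matches_brute_force_grid_search(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.array([1, 1, 0, 1])
        z = np.array([1.0, 0.0, 1.0, 0.0])
        ds = SurvivalDataset(time, event, z[:, None], ["z"], tau=5)
        fit = fit_cox(ds)
        grid = np.arange(-5, 5, 1e-4)
        lls = [breslow_partial_loglik(b, time, event, z) for b in grid]
        b_star = grid[int(np.argmax(lls))]
        assert abs(fit.beta[0] - b_star) < 1e-4

    def test_matches_lifelines_on_untied_data(self, sim5):
        lifelines = pytest.importorskip("lifelines")
        fit = fit_cox(sim5)
        df = pd.DataFrame(sim5.covariates, columns=sim5.covariate_names)
        df["t"], df["e"] = sim5.time, sim5.event
        cph = lifelines.CoxPHFitter().fit(df, "t", "e")
        np.testing.assert_allclose(fit.beta, cph.params_.values, atol=1e-5)
        np.testing.assert_allclose(fit.se, cph.standard_errors_.values, atol=1e-5)

    def test_no_events_raises(self):
        ds = SurvivalDataset([1.0, 2.0], [0, 0], np.array([[0.0], [1.0]]), ["z"], tau=3)
        with pytest.raises(CoxFitError):
            fit_cox(ds)

    def test_collinear_covariates_raise(self):
        z = np.array([1, 0, 1, 0, 1, 0.0])
        ds = SurvivalDataset(
            time=[1, 2, 3, 4, 5, 6.0],
            event=[1, 1, 0, 1, 0, 1],
            covariates=np.column_stack([z, 2 * z]),
            covariate_names=["z", "z2"],
            tau=7,
        )
        with pytest.raises(CoxFitError):
            fit_cox(ds)

    def test_stratified_fit_recovers_shared_coefficient(self, rng):
        # two strata with very different baselines, common log hazard ratio 0.8
        n = 4000
        z = rng.integers(0, 2, n).astype(float)
        strat = np.where(rng.random(n) < 0.5, "a", "b")
        lam = np.where(strat == "a", 0.5, 3.0) * np.exp(0.8 * z)
        T = rng.exponential(1 / lam)
        C = rng.exponential(2.0, n)
        tau = 10.0
        Y = np.minimum(np.minimum(T, C), tau)
        d = ((T < C) & (T < tau)).astype(int)
        ds = SurvivalDataset(Y, d, z[:, None], ["z"], tau=tau, stratum=strat)
        fit = fit_cox(ds)
        assert abs(fit.beta[0] - 0.8) < 3 * fit.se[0]
        assert set(fit.baseline) == {"a", "b"}


class TestBreslowBaseline:
    def test_single_subject_single_jump(self):
        ds = SurvivalDataset([2.0], [1], np.empty((1, 0)), [], tau=3)
        H = breslow_cumhaz(ds, np.empty(0))
        np.testing.assert_allclose(H.times, [2.0])
        np.testing.assert_allclose(H.values, [1.0])

    def test_matches_nelson_aalen_at_beta_zero(self):
        # events at 1, 2; censored at 3: H(1)=1/3, H(2)=1/3+1/2=5/6
        ds = SurvivalDataset([1.0, 2.0, 3.0], [1, 1, 0], np.empty((3, 0)), [], tau=3)
        H = breslow_cumhaz(ds, np.empty(0))
        np.testing.assert_allclose(H.values, [1 / 3, 5 / 6])
        assert H.at(0.5) == 0.0
        assert H.at(1.0) == pytest.approx(1 / 3)   # right-continuous at jumps
        assert H.at(2.7) == pytest.approx(5 / 6)

    def test_linear_predictor_shift_rescales_jumps(self, rng):
        time = rng.exponential(1, 20)
        event = rng.integers(0, 2, 20)
        event[0] = 1
        z = rng.normal(size=20)
        tau = float(time.max())
        ds = SurvivalDataset(time, event, z[:, None], ["z"], tau=tau)
        shifted = SurvivalDataset(time, event, (z + 2.0)[:, None], ["z"], tau=tau)
        H = breslow_cumhaz(ds, np.array([0.7]))
        Hs = breslow_cumhaz(shifted, np.array([0.7]))
        np.testing.assert_allclose(Hs.values, H.values * np.exp(-2.0 * 0.7))

    def test_stratum_without_events_is_empty(self):
        ds = SurvivalDataset(
            [1.0, 2.0], [1, 0], np.empty((2, 0)), [], tau=3,
            stratum=["a", "b"],
        )
        assert breslow_cumhaz(ds, np.empty(0), "b").n_jumps == 0


class TestSchoenfeld:
    def test_single_event_uniform_weights(self):
        ds = SurvivalDataset(
            [1.0, 2.0], [1, 0], np.array([[1.0], [0.0]]), ["z"], tau=3
        )
        # at beta = 0 the risk-set mean is the plain average of {0, 1}
        from coxsens.cox import CoxFit
        fake = CoxFit(np.array([0.0]), np.eye(1), {}, 1, 0.0, ["z"])
        res = schoenfeld_residuals(fake, ds)
        assert res.loc[0, "z"] == pytest.approx(1.0 - 0.5)

    def test_residual_sums_vanish_at_fitted_beta(self, sim5):
        fit = fit_cox(sim5)
        res = schoenfeld_residuals(fit, sim5)
        sums = res[fit.covariate_names].sum()
        assert np.all(np.abs(sums.values) < 1e-6)

    def test_matches_brute_force_on_fixture(self):
        time = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        event = np.array([1, 1, 1, 0, 1])
        z = np.array([0.0, 1.0, 1.0, 0.0, 1.0])
        ds = SurvivalDataset(time, event, z[:, None], ["z"], tau=6)
        fit = fit_cox(ds)
        res = schoenfeld_residuals(fit, ds)
        b = fit.beta[0]
        expected = []
        for t in time[event == 1]:
            risk = time >= t
            w = np.exp(b * z[risk])
            expected.append(z[time == t][0] - (z[risk] * w).sum() / w.sum())
        np.testing.assert_allclose(res["z"].values, expected, atol=1e-10)
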