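"""NB regression and the NB-CAR sampler: oracles, collapse, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import gammaln

from cyanorisk.geo_synth import (SyntheticScenario, make_county_grid,
                                 make_covariates, simulate_mortality)
from cyanorisk.mortality import smr_table
from cyanorisk.nbcar import (ModelData, NegativeBinomialCAR, ess_rhat,
                             convergence_diagnostics, nb_glm_fit, nb_loglik,
                             risk_ratios)


def _sim_model(seed=0, nx=10, ny=10, **scen_kwargs):
    cm = make_county_grid(nx, ny)
    scen = SyntheticScenario(grid_nx=nx, grid_ny=ny, seed=seed, **scen_kwargs)
    rng = np.random.default_rng(seed)
    cov = make_covariates(cm, scen, rng=rng)
    sim = simulate_mortality(cm, cov, scen, rng=rng)
    smr = smr_table(sim.table)
    df = smr.merge(cov, on="county_id")
    model = NegativeBinomialCAR.from_dataframe(
        df, cm, covariates=["coverage_pct", "education", "race"])
    return model, scen, sim


class TestNBGLM:
    def test_null_effect_recovered_within_3se(self):
        model, _, _ = _sim_model(seed=1, nx=14, ny=14, true_beta=(0.0, 0.0, 0.0),
                                 sigma_e=0.0, sigma_phi=0.0)
        res = model.fit_glm()
        for k in range(3):
            assert abs(res.beta[k]) < 3 * res.bse[k + 1]

    def test_counts_equal_expected_gives_zero_intercept(self):
        cm = make_county_grid(8, 8)
        rng = np.random.default_rng(3)
        E = rng.uniform(40, 160, size=64)
        y = np.round(E)
        data = ModelData(y=y, X=np.empty((64, 0)), offset=np.log(E),
                         neighbors=cm.neighbors)
        res = nb_glm_fit(data)
        assert abs(res.alpha) < 0.02

    def test_mle_matches_independent_optimizer(self):
        """Oracle: scipy minimization of a separately written NB likelihood."""
        model, _, _ = _sim_model(seed=4, nx=20, ny=20, sigma_e=0.0,
                                 sigma_phi=0.0)
        res = model.fit_glm()
        d = model.data
        Xd = np.column_stack([np.ones(d.n), d.X])

        def negll(theta):
            eta = d.offset + Xd @ theta[:-1]
            mu = np.exp(eta)
            r = np.exp(theta[-1])
            return -np.sum(gammaln(d.y + r) - gammaln(r) - gammaln(d.y + 1)
                           + r * np.log(r / (r + mu))
                           + d.y * np.log(mu / (r + mu)))

        x0 = np.concatenate([[res.alpha], res.beta, [np.log(res.r)]]) * 0.0
        opt = minimize(negll, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12,
                                "maxiter": 20000, "maxfev": 40000})
        assert opt.x[0] == pytest.approx(res.alpha, abs=1e-4)
        assert np.allclose(opt.x[1:-1], res.beta, atol=1e-4)
        assert np.exp(opt.x[-1]) == pytest.approx(res.r, rel=1e-3)

    def test_rank_deficient_design_rejected(self):
        cm = make_county_grid(3, 3)
        X = np.column_stack([np.ones(9), np.ones(9)])
        data = ModelData(y=np.arange(9.0) + 1, X=X, offset=np.zeros(9),
                         neighbors=cm.neighbors)
        with pytest.raises(ValueError):
            nb_glm_fit(data)


class TestLikelihood:
    def test_offset_shift_absorbed_by_intercept(self, rng):
        """Adding c to the offset and subtracting c from alpha leaves the
        NB likelihood unchanged."""
        y = rng.poisson(10, size=50).astype(float)
        off = rng.normal(2, 0.3, size=50)
        alpha, c, r = 0.4, 1.7, 8.0
        ll1 = nb_loglik(y, np.exp(off + alpha), r).sum()
        ll2 = nb_loglik(y, np.exp((off + c) + (alpha - c)), r).sum()
        assert ll1 == pytest.approx(ll2, rel=1e-12)

    def test_nb_loglik_matches_scipy(self, rng):
        from scipy import stats

        y = rng.poisson(5, size=20).astype(float)
        mu, r = 6.0, 3.0
        ours = nb_loglik(y, np.full_like(y, mu), r)
        ref = stats.nbinom.logpmf(y, r, r / (r + mu))
        assert np.allclose(ours, ref, rtol=1e-10)


class TestMCMC:
    def test_same_seed_identical_draws(self):
        model, _, _ = _sim_model(seed=6, nx=5, ny=5)
        a = model.fit(n_burn=100, n_iter=150, seed=9)
        b = model.fit(n_burn=100, n_iter=150, seed=9)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.phi, b.phi)
        assert np.array_equal(a.r, b.r)

    def test_phi_sum_to_zero_every_draw(self):
        model, _, _ = _sim_model(seed=7, nx=5, ny=5)
        post = model.fit(n_burn=150, n_iter=200, seed=2)
        assert np.max(np.abs(post.phi.mean(axis=1))) < 1e-10

    def test_collapse_to_glm_with_degenerate_random_effects(self):
        """sigma_e, sigma_phi ~ 0 must reproduce the NB GLM estimates."""
        model, _, _ = _sim_model(seed=8, nx=12, ny=12, sigma_e=0.0,
                                 sigma_phi=0.0)
        glm = model.fit_glm()
        post = model.fit(n_burn=1500, n_iter=3000, seed=3,
                         fix_sigmas=(1e-6, 1e-6))
        # with scales pinned at 1e-6 the random effects are numerically nil
        assert np.all(np.abs(post.e) < 1e-4)
        assert np.all(np.abs(post.phi) < 1e-4)
        summ = post.summary()
        assert summ.loc["alpha", "mean"] == pytest.approx(
            glm.alpha, abs=4 * summ.loc["alpha", "sd"] + 0.01)
        for k, name in enumerate(post.covariate_names):
            row = summ.loc[f"beta[{name}]"]
            assert row["mean"] == pytest.approx(
                glm.beta[k], abs=4 * row["sd"] + 0.005)

    def test_acceptance_rates_in_working_range(self):
        model, _, _ = _sim_model(seed=9, nx=8, ny=8)
        post = model.fit(n_burn=600, n_iter=600, seed=4)
        for key in ("alpha", "r", "e", "phi"):
            rate = np.mean(post.acceptance[key])
            assert 0.05 < rate < 0.9

    def test_suppressed_counties_excluded(self):
        cm = make_county_grid(4, 4)
        df = pd.DataFrame({
            "county_id": cm.ids,
            "observed": [3.0] * 4 + [50.0] * 12,
            "expected": [30.0] * 16,
            "suppressed": [True] * 4 + [False] * 12,
            "coverage_pct": np.linspace(0, 20, 16),
        })
        model = NegativeBinomialCAR.from_dataframe(df, cm,
                                                   covariates=["coverage_pct"])
        assert model.data.n == 12
        # re-induced adjacency must stay within retained counties
        assert all(max(nb, default=0) < 12 for nb in model.data.neighbors)


class TestRiskRatios:
    def _post_with_beta(self, draws):
        model, _, _ = _sim_model(seed=10, nx=3, ny=3)
        post = model.fit(n_burn=10, n_iter=draws.shape[0], seed=1)
        post.beta = draws
        return post

    def test_zero_draws_give_unit_rr(self):
        draws = np.zeros((200, 3))
        post = self._post_with_beta(draws)
        rr = risk_ratios(post)
        assert np.allclose(rr["rr"], 1.0)
        assert np.allclose(rr["rr_2.5"], 1.0)
        assert np.allclose(rr["rr_97.5"], 1.0)

    def test_constant_draws_closed_form(self):
        draws = np.full((200, 3), 0.003)
        post = self._post_with_beta(draws)
        rr = risk_ratios(post, {"coverage_pct": 1.0})
        assert rr.loc["coverage_pct", "rr"] == pytest.approx(np.exp(0.003),
                                                             rel=1e-12)

    def test_delta_doubling_doubles_log_rr(self):
        rng = np.random.default_rng(0)
        # 401 draws put the 2.5/97.5 percentiles exactly on order statistics,
        # so the quantile commutes with the monotone exp transform
        draws = rng.normal(0.01, 0.002, size=(401, 3))
        post = self._post_with_beta(draws)
        rr1 = risk_ratios(post, {"coverage_pct": 1.0})
        rr2 = risk_ratios(post, {"coverage_pct": 2.0})
        assert np.log(rr2.loc["coverage_pct", "rr_97.5"]) == pytest.approx(
            2 * np.log(rr1.loc["coverage_pct", "rr_97.5"]), rel=1e-9)


class TestDiagnostics:
    def test_iid_chain_rhat_near_one(self):
        rng = np.random.default_rng(1)
        ess, rhat = ess_rhat(rng.standard_normal(4000))
        assert rhat == pytest.approx(1.0, abs=0.02)
        assert ess > 2000

    def test_shifted_half_chains_flagged(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.standard_normal(1000),
                            rng.standard_normal(1000) + 3.0])
        _, rhat = ess_rhat(x)
        assert rhat > 1.05

    def test_ar1_ess_closed_form(self):
        rho, n = 0.5, 40000
        rng = np.random.default_rng(3)
        x = np.empty(n)
        x[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * np.sqrt(1 - rho ** 2)
        for t in range(1, n):
            x[t] = rho * x[t - 1] + eps[t]
        ess, _ = ess_rhat(x)
        expected = n * (1 - rho) / (1 + rho)
        assert ess == pytest.approx(expected, rel=0.2)

    def test_too_few_draws_rejected(self):
        model, _, _ = _sim_model(seed=11, nx=3, ny=3)
        post = model.fit(n_burn=20, n_iter=50, seed=1)
        with pytest.raises(ValueError):
            convergence_diagnostics(post)
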