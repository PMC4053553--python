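"""DIC, variance decomposition, exceedance surfaces and diagnostics,
checked against hand arithmetic and brute-force counting on synthetic
draw containers."""

import numpy as np
import pytest

from pphmap.results import (ModelFit, autocorrelation, dic, exceedance, rhat,
                            variance_explained)
from pphmap.sampler import PosteriorDraws

from conftest import two_area_data


def fake_draws(alpha, log_delta, phi, epsilon, prec_phi=None, prec_eps=None,
               deviance=None, n_chains=1, conditions=None):
    """Build a PosteriorDraws with identical chains from given arrays of
    shape (T, ...)."""
    alpha = np.asarray(alpha, float)
    t, j = alpha.shape
    phi = np.asarray(phi, float)
    chain = {
        "alpha": alpha,
        "log_delta": np.asarray(log_delta, float),
        "phi": phi,
        "epsilon": np.asarray(epsilon, float),
        "prec_phi": np.ones(t) if prec_phi is None else np.asarray(prec_phi, float),
        "prec_eps": np.ones((t, j)) if prec_eps is None else np.asarray(prec_eps, float),
        "deviance": np.zeros(t) if deviance is None else np.asarray(deviance, float),
    }
    meta = {"conditions": conditions or [f"c{k}" for k in range(j)]}
    return PosteriorDraws(chains=[{k: v.copy() for k, v in chain.items()}
                                  for _ in range(n_chains)], meta=meta)


class TestDIC:
    def test_arithmetic_on_definition(self):
        fit = ModelFit(dbar=11.0, d_at_mean=10.5)
        assert fit.pd == pytest.approx(0.5)
        assert fit.dic == pytest.approx(11.5)
        assert fit.dic == pytest.approx(fit.dbar + fit.pd)

    def test_degenerate_posterior_has_zero_pd(self):
        data = two_area_data(observed=(6, 6))
        d = fake_draws(alpha=np.zeros((5, 1)), log_delta=np.zeros((5, 1)),
                       phi=np.zeros((5, 2)), epsilon=np.zeros((5, 2, 1)))
        # all draws identical -> deviance constant == plug-in deviance
        from pphmap.sampler import SCMParams, poisson_log_lik
        dev = -2 * poisson_log_lik(data, SCMParams(
            alpha=np.zeros(1), log_delta=np.zeros(1), phi=np.zeros(2),
            epsilon=np.zeros((2, 1)), prec_phi=1.0, prec_eps=np.ones(1)))
        for c in d.chains:
            c["deviance"][:] = dev
        fit = dic(d, data)
        assert fit.pd == pytest.approx(0.0, abs=1e-9)
        assert fit.dic == pytest.approx(fit.dbar)

    def test_consistency_on_real_fit(self, small_data):
        from pphmap.model import fit_scm
        res = fit_scm(small_data, n_chains=2, iterations=1200, burn_in=400,
                      thin=4, seed=0)
        fit = res.dic()
        assert fit.dic == pytest.approx(fit.dbar + fit.pd, abs=1e-12)
        # Dbar really is the mean of the stored per-draw deviances
        assert fit.dbar == pytest.approx(res.draws.pooled("deviance").mean())

    def test_empty_draws_rejected(self):
        data = two_area_data()
        d = fake_draws(alpha=np.zeros((0, 1)), log_delta=np.zeros((0, 1)),
                       phi=np.zeros((0, 2)), epsilon=np.zeros((0, 2, 1)))
        with pytest.raises(ValueError):
            dic(d, data)


class TestVarianceExplained:
    def test_no_specific_noise_gives_100(self):
        rng = np.random.default_rng(0)
        phi = rng.normal(size=(8, 10))
        d = fake_draws(alpha=np.zeros((8, 2)), log_delta=np.zeros((8, 2)),
                       phi=phi, epsilon=np.zeros((8, 10, 2)))
        dec = variance_explained(d)
        assert np.allclose(dec.table["pct_shared"], 100.0)
        assert np.allclose(dec.table["pct_shared_lo"], 100.0)

    def test_zero_loading_gives_0(self):
        rng = np.random.default_rng(1)
        d = fake_draws(alpha=np.zeros((8, 2)),
                       log_delta=np.full((8, 2), -np.inf),
                       phi=rng.normal(size=(8, 10)),
                       epsilon=rng.normal(size=(8, 10, 2)))
        dec = variance_explained(d)
        assert np.allclose(dec.table["pct_shared"], 0.0)

    def test_per_draw_formula_and_area_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        t, n, j = 6, 12, 3
        phi = rng.normal(size=(t, n))
        ld = rng.normal(size=(t, j)) * 0.1
        eps = rng.normal(size=(t, n, j))
        d = fake_draws(alpha=np.zeros((t, j)), log_delta=ld, phi=phi, epsilon=eps)
        dec = variance_explained(d)
        # independent loop oracle
        fr = np.empty((t, j))
        for tt in range(t):
            for jj in range(j):
                vs = np.var(np.exp(ld[tt, jj]) * phi[tt])
                ve = np.var(eps[tt, :, jj])
                fr[tt, jj] = vs / (vs + ve)
        np.testing.assert_allclose(dec.table["pct_shared"], 100 * fr.mean(0),
                                   rtol=1e-12)
        assert ((dec.table["pct_shared"] >= 0) & (dec.table["pct_shared"] <= 100)).all()
        perm = rng.permutation(n)
        d2 = fake_draws(alpha=np.zeros((t, j)), log_delta=ld,
                        phi=phi[:, perm], epsilon=eps[:, perm, :])
        np.testing.assert_allclose(variance_explained(d2).table["pct_shared"],
                                   dec.table["pct_shared"], rtol=1e-12)


class TestVarianceExplainedRecovery:
    def test_balanced_half_shared_design_recovered(self):
        """Data generated with a true shared fraction of one half for
        every condition: the posterior mean lands within +-15 points for
        at least 5 of 6 conditions."""
        import pphmap as pm

        cfg = pm.GeneratorConfig(seed=17, delta=(1.0,) * 6, sigma_shared=0.25,
                                 sigma_specific=(0.25,) * 6)
        table, graph, truth = pm.generate(cfg)
        data = pm.assemble(table, graph)
        res = pm.fit_scm(data, n_chains=3, iterations=5000, burn_in=1000,
                         thin=5, seed=17)
        err = np.abs(res.variance_explained().table["pct_shared"].to_numpy()
                     - 100 * truth.shared_fraction)
        assert np.sum(err <= 15.0) >= 5


class TestExceedance:
    def test_all_positive_field_is_high(self):
        phi = np.abs(np.random.default_rng(0).normal(size=(10, 4))) + 0.01
        d = fake_draws(alpha=np.zeros((10, 1)), log_delta=np.zeros((10, 1)),
                       phi=phi, epsilon=np.zeros((10, 4, 1)))
        surf = exceedance(d, "shared")
        assert np.allclose(surf.prob["shared"], 1.0)
        assert (surf.category["shared"] == "high").all()

    def test_symmetric_draws_indeterminate(self):
        phi = np.concatenate([np.full((5, 2), 0.3), np.full((5, 2), -0.3)])
        d = fake_draws(alpha=np.zeros((10, 1)), log_delta=np.zeros((10, 1)),
                       phi=phi, epsilon=np.zeros((10, 2, 1)))
        surf = exceedance(d, "shared")
        assert np.allclose(surf.prob["shared"], 0.5)
        assert (surf.category["shared"] == "indeterminate").all()

    def test_counting_oracle_seven_of_ten(self):
        phi = np.where(np.arange(10)[:, None] < 7, 0.2, -0.2) * np.ones((10, 3))
        d = fake_draws(alpha=np.zeros((10, 1)), log_delta=np.zeros((10, 1)),
                       phi=phi, epsilon=np.zeros((10, 3, 1)))
        surf = exceedance(d, "shared")
        assert np.allclose(surf.prob["shared"], 0.7)

    def test_terms_match_brute_force_counting(self):
        rng = np.random.default_rng(4)
        t, n, j = 9, 6, 2
        phi = rng.normal(size=(t, n))
        ld = 0.1 * rng.normal(size=(t, j))
        al = 0.05 * rng.normal(size=(t, j))
        eps = rng.normal(size=(t, n, j))
        d = fake_draws(alpha=al, log_delta=ld, phi=phi, epsilon=eps)
        rr = exceedance(d, "condition_rr").prob.to_numpy()
        sp = exceedance(d, "specific").prob.to_numpy()
        for i in range(n):
            for jj in range(j):
                full = al[:, jj] + np.exp(ld[:, jj]) * phi[:, i] + eps[:, i, jj]
                assert rr[i, jj] == np.mean(np.exp(full) > 1.0)
                assert sp[i, jj] == np.mean(np.exp(eps[:, i, jj]) > 1.0)

    def test_unknown_term_rejected(self):
        d = fake_draws(alpha=np.zeros((4, 1)), log_delta=np.zeros((4, 1)),
                       phi=np.zeros((4, 2)), epsilon=np.zeros((4, 2, 1)))
        with pytest.raises(ValueError):
            exceedance(d, "nope")


class TestRhat:
    @staticmethod
    def _chains(mu_by_chain, sd=1.0, t=4000, seed=0):
        rng = np.random.default_rng(seed)
        chains = []
        for m in mu_by_chain:
            a = rng.normal(m, sd, size=(t, 1))
            chains.append({"alpha": a, "log_delta": a.copy(),
                           "phi": a.copy(), "epsilon": a[:, :, None].copy(),
                           "prec_phi": a[:, 0].copy(), "prec_eps": a.copy(),
                           "deviance": a[:, 0].copy()})
        return PosteriorDraws(chains=chains, meta={})

    def test_well_mixed_chains_near_one(self):
        d = self._chains([0.0, 0.0, 0.0], seed=1)
        assert 0.99 <= rhat(d, "prec_phi") <= 1.02

    def test_offset_chain_flagged(self):
        d = self._chains([0.0, 10.0], sd=1.0, t=500, seed=2)
        assert rhat(d, "prec_phi") > 1.5

    def test_constant_parameter_reported_as_one(self, caplog):
        d = self._chains([0.0, 0.0], sd=1.0, t=100, seed=3)
        for c in d.chains:
            c["prec_phi"][:] = 2.5
        with caplog.at_level("WARNING"):
            assert rhat(d, "prec_phi") == 1.0
        assert any("zero" in r.message for r in caplog.records)

    def test_single_chain_rejected(self):
        d = self._chains([0.0], t=100)
        with pytest.raises(ValueError):
            rhat(d, "prec_phi")


class TestAutocorrelation:
    def test_lag_zero_is_one_and_white_noise_small(self):
        d = TestRhat._chains([0.0], sd=1.0, t=2000, seed=5)
        d.chains.append(d.chains[0])
        acf = autocorrelation(d, "prec_phi", max_lag=50)
        assert acf[0] == pytest.approx(1.0)
        assert np.mean(np.abs(acf[1:]) < 3 / np.sqrt(2000)) >= 0.9

    def test_ar1_coefficient_recovered(self):
        rng = np.random.default_rng(6)
        t = 10_000
        x = np.empty(t)
        x[0] = 0.0
        for i in range(1, t):
            x[i] = 0.9 * x[i - 1] + rng.normal()
        chain = {"alpha": x[:, None], "prec_phi": x, "deviance": x,
                 "log_delta": x[:, None], "phi": x[:, None],
                 "epsilon": x[:, None, None], "prec_eps": x[:, None]}
        d = PosteriorDraws(chains=[chain], meta={})
        acf = autocorrelation(d, "prec_phi", max_lag=5)
        assert acf[1] == pytest.approx(0.9, abs=0.05)

    def test_too_few_draws_rejected(self):
        d = TestRhat._chains([0.0], t=20)
        with pytest.raises(ValueError):
            autocorrelation(d, "prec_phi", max_lag=50)


class TestRhatCrossCheck:
    def test_matches_arviz_split_rhat(self):
        """Independent cross-check of the split-R-hat computation."""
        import arviz as az

        rng = np.random.default_rng(9)
        x = rng.normal(size=(4, 600)) + np.array([0.0, 0.1, -0.1, 0.2])[:, None]
        chains = [{"alpha": c[:, None], "log_delta": c[:, None],
                   "phi": c[:, None], "epsilon": c[:, None, None],
                   "prec_phi": c, "prec_eps": c[:, None], "deviance": c}
                  for c in x]
        d = PosteriorDraws(chains=chains, meta={})
        ours = rhat(d, "prec_phi")
        ref = float(az.rhat(az.convert_to_dataset(x), method="split")["x"])
        assert ours == pytest.approx(ref, abs=0.01)
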