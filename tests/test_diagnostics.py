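import numpy as np
import pandas as pd
import pytest

import nichemod as nm
from nichemod.diagnostics import (compute_dic, convergence_report,
                                  dic_from_deviance, inclusion_probabilities,
                                  variance_explained)
from nichemod.inference import McmcOptions, PosteriorDraws


def _fake_draws(sigma2_draws, y, x, prior="spike_slab", extra=None):
    """Minimal PosteriorDraws carrying only what a diagnostic needs."""
    draws = {"sigma2": np.asarray(sigma2_draws)[None, ...],
             "deviance": np.zeros((1, np.asarray(sigma2_draws).shape[0]))}
    if extra:
        draws.update(extra)
    return PosteriorDraws(draws=draws,
                          options=McmcOptions(n_iter=10, seed=0, prior=prior),
                          inits=None, acceptance={}, data={"y": y, "x": x},
                          fingerprint="", mode="single")


class TestDic:
    def test_degenerate_constant_chain(self):
        rep = dic_from_deviance(np.full((1, 5), 100.0), 100.0)
        assert rep.p_d_classic == 0 and rep.p_d_var == 0
        assert rep.dic_classic == 100 and rep.dic_var == 100

    def test_hand_computed_two_draw_chain(self):
        # Dbar=100; sample variance (n-1 denominator) of {98,102} is 8
        rep = dic_from_deviance(np.array([[98.0, 102.0]]), 99.0)
        assert rep.d_bar == 100.0
        assert rep.p_d_classic == 1.0 and rep.dic_classic == 101.0
        assert rep.p_d_var == 4.0 and rep.dic_var == 104.0
        assert not rep.flag_negative_pd

    def test_negative_pd_is_flagged_not_truncated(self):
        rep = dic_from_deviance(np.array([[100.0, 102.0]]), 105.0)
        assert rep.p_d_classic == -4.0
        assert rep.flag_negative_pd
        assert rep.dic_classic == 105.0 + 2 * (-4.0)

    def test_single_draw_and_nonfinite_are_errors(self):
        with pytest.raises(ValueError):
            dic_from_deviance(np.array([[100.0]]), 99.0)
        with pytest.raises(ValueError):
            dic_from_deviance(np.array([[np.nan, 1.0]]), 99.0)

    def test_identities_hold_on_real_fit(self, small_fit):
        rep = compute_dic(small_fit)
        assert abs(rep.dic_classic - (rep.d_bar + rep.p_d_classic)) < 1e-10
        assert abs(rep.dic_classic - (rep.d_hat + 2 * rep.p_d_classic)) < 1e-10
        assert abs(rep.dic_var - (rep.d_bar + rep.p_d_var)) < 1e-10
        assert rep.p_d_var >= 0

    def test_conjugate_normal_means_effective_parameters(self):
        # y_i ~ N(theta_i, 1), theta_i ~ N(0, tau^2) with weak shrinkage:
        # the effective parameter count approaches the number of means
        rng = np.random.default_rng(6)
        p, tau2 = 60, 100.0
        shrink = tau2 / (1.0 + tau2)
        y = rng.standard_normal(p) * np.sqrt(1 + tau2)
        post_mean = shrink * y
        post_sd = np.sqrt(shrink)
        n_draws = 4000
        theta = post_mean + post_sd * rng.standard_normal((n_draws, p))
        dev = np.sum((y - theta) ** 2, axis=1)
        d_hat = float(np.sum((y - post_mean) ** 2))
        rep = dic_from_deviance(dev[None, :], d_hat)
        true_pd = p * shrink
        assert abs(rep.p_d_var - true_pd) / true_pd < 0.2
        assert abs(rep.p_d_classic - true_pd) / true_pd < 0.2


class TestVarianceExplained:
    def test_halved_variance_is_fifty_percent(self, rng):
        y = (rng.uniform(size=(4, 3)) < 0.5).astype(float)
        x = rng.standard_normal(4)
        with_tr = _fake_draws(np.tile([1.0, 1.0, 1.0], (6, 1)), y, x)
        without = _fake_draws(np.tile([2.0, 1.0, 1.0], (6, 1)), y, x)
        ve = variance_explained(with_tr, without)
        assert np.isclose(ve.fraction_pct["opt"], 50.0)
        assert np.isclose(ve.fraction_pct["tol"], 0.0)

    def test_antisymmetry_relation(self, rng):
        y = (rng.uniform(size=(4, 3)) < 0.5).astype(float)
        x = rng.standard_normal(4)
        s_a = rng.uniform(0.5, 3.0, size=(8, 3))
        s_b = rng.uniform(0.5, 3.0, size=(8, 3))
        da, db = _fake_draws(s_a, y, x), _fake_draws(s_b, y, x)
        f_ab = variance_explained(da, db)
        f_ba = variance_explained(db, da)
        for t in ("opt", "tol", "a"):
            ratio = f_ab.sigma2_with[t] / f_ab.sigma2_without[t]
            assert np.isclose(f_ab.fraction_pct[t],
                              -f_ba.fraction_pct[t] * ratio)

    def test_mismatched_data_rejected(self, rng):
        y1 = (rng.uniform(size=(4, 3)) < 0.5).astype(float)
        y2 = 1.0 - y1
        x = rng.standard_normal(4)
        with pytest.raises(ValueError, match="fingerprint"):
            variance_explained(_fake_draws(np.ones((5, 3)), y1, x),
                               _fake_draws(np.ones((5, 3)), y2, x))

    def test_published_component_arithmetic(self):
        # a variance drop from 2.31 to 1.14 is a 50.6% reduction, consistent
        # with a printed 50.45 once the components are rounded to 2 decimals
        pct = 100.0 * (2.31 - 1.14) / 2.31
        assert abs(pct - 50.45) < 1.0


class TestConvergence:
    def test_identical_iid_chains_have_unit_rhat(self, rng):
        draws = {"mu": rng.standard_normal((2, 2000, 3)),
                 "deviance": rng.standard_normal((2, 2000))}
        d = PosteriorDraws(draws=draws, options=McmcOptions(n_iter=10, seed=0),
                           inits=None, acceptance={}, data={}, fingerprint="",
                           mode="single")
        rep = convergence_report(d, parameters=("mu",))
        assert np.all(np.abs(rep["rhat"] - 1.0) < 0.05)
        assert not rep["flagged"].any()

    def test_separated_chains_flagged(self, rng):
        chains = np.stack([rng.standard_normal(500),
                           10.0 + rng.standard_normal(500)])
        d = PosteriorDraws(draws={"deviance": chains},
                           options=McmcOptions(n_iter=10, seed=0),
                           inits=None, acceptance={}, data={},
                           fingerprint="", mode="single")
        rep = convergence_report(d, parameters=("deviance",))
        assert rep["rhat"].iloc[0] > 1.1 and rep["flagged"].iloc[0]

    def test_ar1_ess_close_to_analytic(self, rng):
        rho, n = 0.5, 40000
        e = rng.standard_normal((2, n))
        z = np.zeros((2, n))
        for i in range(1, n):
            z[:, i] = rho * z[:, i - 1] + np.sqrt(1 - rho ** 2) * e[:, i]
        d = PosteriorDraws(draws={"deviance": z},
                           options=McmcOptions(n_iter=10, seed=0),
                           inits=None, acceptance={}, data={},
                           fingerprint="", mode="single")
        rep = convergence_report(d, parameters=("deviance",))
        expected = 2 * n * (1 - rho) / (1 + rho)
        assert abs(rep["ess"].iloc[0] - expected) / expected < 0.2

    def test_single_chain_omits_rhat(self, rng):
        d = PosteriorDraws(draws={"deviance": rng.standard_normal((1, 400))},
                           options=McmcOptions(n_iter=10, seed=0, n_chains=1),
                           inits=None, acceptance={}, data={},
                           fingerprint="", mode="single")
        rep = convergence_report(d, parameters=("deviance",))
        assert np.isnan(rep["rhat"].iloc[0])
        assert rep.attrs["notice"].startswith("single chain")


class TestInclusionProbabilities:
    def test_posterior_mean_of_indicators(self, rng):
        y = (rng.uniform(size=(4, 3)) < 0.5).astype(float)
        gamma = np.array([1, 1, 0, 1], dtype=float)[None, :, None, None]
        gamma = np.broadcast_to(gamma, (1, 4, 3, 1)).copy()
        d = _fake_draws(np.ones((4, 3)), y, rng.standard_normal(4),
                        extra={"gamma": gamma})
        rep = inclusion_probabilities(d)
        assert np.allclose(rep["probability"], 0.75)

    def test_all_zero_draws(self, rng):
        y = (rng.uniform(size=(4, 3)) < 0.5).astype(float)
        d = _fake_draws(np.ones((4, 3)), y, rng.standard_normal(4),
                        extra={"gamma": np.zeros((1, 4, 3, 2))})
        rep = inclusion_probabilities(d)
        assert np.all(rep["probability"] == 0.0)

    def test_normal_prior_fit_has_no_indicators(self, rng):
        y = (rng.uniform(size=(4, 3)) < 0.5).astype(float)
        d = _fake_draws(np.ones((4, 3)), y, rng.standard_normal(4),
                        prior="normal")
        with pytest.raises(ValueError, match="no indicators"):
            inclusion_probabilities(d)
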