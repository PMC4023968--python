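import numpy as np
import pytest
from scipy import stats

import nichemod as nm
from nichemod.inference import McmcOptions, ModelState, fit, \
    fit_without_traits, log_joint
from nichemod.model import bernoulli_loglik, laplace_logpdf, response_logit


def _random_state(rng, n, m, K):
    return ModelState(
        opt=rng.standard_normal(m), tolp=0.2 * rng.standard_normal(m),
        a=rng.standard_normal(m), eps=0.3 * rng.standard_normal(n),
        mu=rng.standard_normal(3), beta=rng.standard_normal((3, K)),
        gamma=np.ones((3, K), dtype=int),
        sigma2=np.array([0.5, 0.4, 0.8]), sigma2_site=0.25, lam=1.3)


class TestLogJoint:
    def test_single_cell_at_optimum_gives_log_half(self):
        # a=0 at x=opt with no site effect puts p at exactly 1/2
        lg = response_logit(np.array([1.7]), np.array([1.7]),
                            np.array([1.0]), np.array([0.0]), 0.0)
        assert np.isclose(bernoulli_loglik(np.array([[1.0]]), lg)[0, 0],
                          np.log(0.5))

    def test_slab_density_at_zero(self):
        assert np.isclose(laplace_logpdf(0.0, 1.0), np.log(0.5))

    def test_matches_term_by_term_hand_computation(self, rng):
        n, m, K = 7, 4, 2
        y = (rng.uniform(size=(n, m)) < 0.5).astype(float)
        x = rng.standard_normal(n)
        Z = rng.standard_normal((m, K))
        st = _random_state(rng, n, m, K)
        opts = McmcOptions(n_iter=10, seed=0)
        got = log_joint(st, {"y": y, "x": x, "Z": Z}, opts)

        # independent term-by-term recomputation
        tol = np.exp(st.tolp)
        lg = (st.a[None, :] - (x[:, None] - st.opt[None, :]) ** 2
              / (2 * tol[None, :] ** 2) + st.eps[:, None])
        want = float(np.sum(y * lg - np.log1p(np.exp(lg))))
        for t, th in enumerate((st.opt, st.tolp, st.a)):
            mean = st.mu[t] + Z @ st.beta[t]
            want += float(np.sum(stats.norm.logpdf(
                th, mean, np.sqrt(st.sigma2[t]))))
        want += float(np.sum(stats.norm.logpdf(
            st.eps, 0, np.sqrt(st.sigma2_site))))
        want += -3 * np.log(2 * opts.intercept_bound)
        for s2 in (*st.sigma2, st.sigma2_site):
            want += -np.log(opts.sd_bound) - np.log(2 * np.sqrt(s2))
        want += 3 * K * np.log(0.5)
        want += float(np.sum(np.log(st.lam / 2) - st.lam * np.abs(st.beta)))
        want += float(stats.gamma.logpdf(st.lam, 1.0, scale=1.0))
        assert np.isclose(got, want, rtol=1e-12)

    def test_out_of_support_states_rejected(self, rng):
        n, m, K = 5, 3, 1
        y = (rng.uniform(size=(n, m)) < 0.5).astype(float)
        data = {"y": y, "x": rng.standard_normal(n),
                "Z": rng.standard_normal((m, K))}
        opts = McmcOptions(n_iter=10, seed=0, tol_scale="identity")
        st = _random_state(rng, n, m, K)
        st.tolp = np.abs(st.tolp) + 0.5  # identity scale: tolp is tol
        assert np.isfinite(log_joint(st, data, opts))
        bad = st.copy()
        bad.tolp = bad.tolp.copy()
        bad.tolp[0] = -0.1
        assert log_joint(bad, data, opts) == -np.inf
        bad2 = st.copy()
        bad2.mu = bad2.mu.copy()
        bad2.mu[0] = 1e6  # outside the uniform intercept bound
        assert log_joint(bad2, data, opts) == -np.inf


class TestSamplerContracts:
    def test_same_seed_gives_bit_identical_draws(self, small_community):
        occ, env, tr, _ = small_community
        x = env.values[:, 0]
        inits = nm.initial_values(occ, x, tr)
        opts = McmcOptions(n_iter=300, n_chains=2, seed=17)
        d1 = fit(occ, x, tr, opts, inits)
        d2 = fit(occ, x, tr, opts, inits)
        for k in d1.draws:
            assert np.array_equal(d1.draws[k], d2.draws[k]), k

    def test_excluded_slopes_are_exact_zeros(self, small_fit):
        beta = small_fit.stacked("beta")
        gamma = small_fit.stacked("gamma")
        off = gamma == 0
        assert off.any()  # the spike is actually visited
        assert np.all(beta[off] == 0.0)

    def test_deviance_trace_matches_recomputation(self, small_fit):
        y = small_fit.data["y"]
        x = small_fit.data["x"]
        for idx in (0, small_fit.n_kept // 2, small_fit.n_kept - 1):
            lg = response_logit(x, small_fit.draws["opt"][0, idx],
                                small_fit.draws["tol"][0, idx],
                                small_fit.draws["a"][0, idx],
                                small_fit.draws["eps"][0, idx])
            dev = -2.0 * bernoulli_loglik(y, lg).sum()
            assert np.isclose(dev, small_fit.draws["deviance"][0, idx],
                              rtol=1e-8)

    def test_gradient_shift_shifts_optima(self, small_community):
        occ, env, tr, _ = small_community
        x = env.values[:, 0]
        inits = nm.initial_values(occ, x, tr)
        opts = McmcOptions(n_iter=300, n_chains=1, seed=23)
        base = fit(occ, x, tr, opts, inits)
        c = 3.0
        shifted_inits = nm.InitBundle(
            opt=inits.opt + c, tol=inits.tol, a=inits.a, eps=inits.eps,
            mu=np.array([inits.mu[0] + c, inits.mu[1], inits.mu[2]]),
            beta=inits.beta, sigma2=inits.sigma2,
            sigma2_site=inits.sigma2_site)
        moved = fit(occ, x + c, tr, opts, shifted_inits)
        assert np.allclose(moved.draws["opt"], base.draws["opt"] + c,
                           atol=1e-8)

    def test_without_traits_equals_zero_column_fit(self, small_community):
        occ, env, tr, _ = small_community
        x = env.values[:, 0]
        opts = McmcOptions(n_iter=200, n_chains=1, seed=31)
        inits = nm.initial_values(occ, x, None)
        d0 = fit_without_traits(occ, x, opts, inits)
        zero_tr = nm.TraitTable(np.zeros((occ.n_species, 0)), ())
        d1 = fit(occ, x, zero_tr, opts, inits)
        for k in d0.draws:
            assert np.array_equal(d0.draws[k], d1.draws[k]), k
        assert np.all(np.isfinite(d0.draws["deviance"]))

    def test_draw_count_respects_thinning(self, small_community):
        occ, env, tr, _ = small_community
        x = env.values[:, 0]
        inits = nm.initial_values(occ, x, tr)
        opts = McmcOptions(n_iter=200, burn_in=100, thin=5, n_chains=1,
                           seed=3)
        d = fit(occ, x, tr, opts, inits)
        assert d.n_kept == 20

    def test_niche_means_agree_with_and_without_null_traits(self):
        # when traits carry no signal the trait model should not distort
        # the niche parameter posteriors
        cfg = nm.SyntheticConfig(n=120, m=12, k_continuous=2, k_binary=0,
                                 seed=77)
        occ, env, tr, _ = nm.simulate_community(cfg)
        x = env.values[:, 0]
        inits = nm.initial_values(occ, x, tr)
        opts = McmcOptions(n_iter=800, n_chains=1, seed=5)
        d_tr = fit(occ, x, tr, opts, inits)
        d_no = fit_without_traits(occ, x, McmcOptions(n_iter=800, n_chains=1,
                                                      seed=5))
        m1 = d_tr.stacked("opt").mean(axis=0)
        m2 = d_no.stacked("opt").mean(axis=0)
        assert np.corrcoef(m1, m2)[0, 1] > 0.95

    def test_invalid_options_rejected(self):
        with pytest.raises(ValueError):
            McmcOptions(n_iter=100, burn_in=100)
        with pytest.raises(ValueError):
            McmcOptions(prior="horseshoe")
        with pytest.raises(ValueError):
            McmcOptions(n_chains=0)
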