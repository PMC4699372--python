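import numpy as np
import pytest
from scipy.optimize import minimize

import screenmle as sm
from screenmle.data import DesignMatrix, FitConfig, ScreenValidationError, SgRNALibrary
from screenmle.mle import (
    _penalized_mixture_loglik,
    build_extended_design,
    e_step,
    fit_all,
    fit_gene,
    initial_efficiency,
    m_step_irls,
    nb_loglik,
)
from screenmle.normalize import SizeFactors


def tight_cfg(**kw):
    defaults = dict(convergence_tol=1e-8, irls_tol=1e-10, max_em_iters=500, max_irls_iters=200)
    defaults.update(kw)
    return FitConfig(**defaults)


def maximize_numerically(x, design, sf, alpha, prior, lam, starts):
    """Independent oracle: generic maximizer of the penalized mixture NB log-likelihood."""

    def neg(b):
        return -_penalized_mixture_loglik(x, b, design, sf, alpha, prior, lam)

    best = None
    for b0 in starts:
        res = minimize(neg, b0, method="Nelder-Mead",
                       options=dict(maxiter=20000, xatol=1e-10, fatol=1e-12))
        if best is None or res.fun < best.fun:
            best = res
    return best.x


class TestExtendedDesign:
    def test_two_guide_two_sample_layout(self):
        design = DesignMatrix(("s1", "s2"), ("c",), np.array([[0], [1]]))
        dp = build_extended_design(design, 2)
        # rows in (q11, q21, q12, q22) order
        np.testing.assert_array_equal(
            dp, [[1, 0, 0], [0, 1, 0], [1, 0, 1], [0, 1, 1]]
        )

    def test_baseline_only_design(self):
        design = DesignMatrix(("s1", "s2", "s3"), (), np.zeros((3, 0)))
        dp = build_extended_design(design, 1)
        np.testing.assert_array_equal(dp, np.ones((3, 1)))

    def test_row_sums(self, screen_design):
        dp = build_extended_design(screen_design, 3)
        active = np.repeat(screen_design.entries.sum(axis=1), 3)
        np.testing.assert_array_equal(dp.sum(axis=1), 1 + active)


class TestNbLoglik:
    def test_poisson_limit_closed_form(self):
        assert nb_loglik(2, 2.0, 0.0) == pytest.approx(np.log(2) - 2, abs=1e-12)

    def test_poisson_zero_class(self):
        for m in (0.5, 3.0, 10.0):
            assert nb_loglik(0, m, 0.0) == pytest.approx(-m, abs=1e-12)

    @pytest.mark.parametrize("mu,alpha", [(3.0, 0.0), (3.0, 0.5), (20.0, 0.1), (0.7, 2.0)])
    def test_normalization(self, mu, alpha):
        xs = np.arange(0, 3000)
        total = np.exp(nb_loglik(xs, mu, alpha)).sum()
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_nb_matches_scipy(self):
        from scipy.stats import nbinom

        mu, alpha = 12.0, 0.3
        r = 1 / alpha
        p = r / (r + mu)
        xs = np.arange(0, 50)
        np.testing.assert_allclose(nb_loglik(xs, mu, alpha), nbinom.logpmf(xs, r, p), atol=1e-10)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError):
            nb_loglik(1, 0.0, 0.1)


class TestInitialEfficiency:
    def test_ssc_midpoint(self):
        lib = SgRNALibrary(("a",), ("g",), ("ACGT",), efficiency_scores=(0.0,))
        assert initial_efficiency(lib)[0] == pytest.approx(0.5)

    def test_ssc_limits(self):
        lib = SgRNALibrary(("a", "b"), ("g", "g"), ("ACGT", "TTTT"),
                           efficiency_scores=(1.9999, -1.9999))
        e = initial_efficiency(lib)
        assert e[0] == pytest.approx(1.0, abs=1e-4) and e[1] == pytest.approx(0.0, abs=1e-4)

    def test_no_scores_all_one(self, tiny_library):
        np.testing.assert_array_equal(initial_efficiency(tiny_library), 1.0)

    def test_out_of_range_ssc_rejected(self):
        lib = SgRNALibrary(("a",), ("g",), ("ACGT",), efficiency_scores=(2.5,))
        with pytest.raises(ScreenValidationError):
            initial_efficiency(lib)

    def test_probability_scale_passthrough(self):
        lib = SgRNALibrary(("a",), ("g",), ("ACGT",), efficiency_scores=(0.7,),
                           score_scale="probability")
        assert initial_efficiency(lib)[0] == pytest.approx(0.7)


class TestEStep:
    def setup_method(self):
        self.design = DesignMatrix(("s1", "s2"), ("c",), np.array([[0], [1]]))
        self.sf = np.ones(2)

    def test_equal_likelihoods_return_prior(self):
        # beta_cond = 0 makes both component models identical
        x = np.array([[10.0, 10.0]])
        beta = np.array([np.log(10.0), 0.0])
        e = e_step(x, beta, self.design, self.sf, np.array([0.1]), np.array([0.5]))
        assert e[0] == pytest.approx(0.5)

    def test_degenerate_prior_pinned(self):
        x = np.array([[10.0, 500.0]])
        beta = np.array([np.log(10.0), 2.0])
        for p in (0.0, 1.0):
            e = e_step(x, beta, self.design, self.sf, np.array([0.1]), np.array([p]))
            assert e[0] == p

    def test_flat_counts_with_strong_condition_beta_favor_inefficient(self):
        x = np.array([[50.0, 50.0]])
        beta = np.array([np.log(50.0), 2.0])
        e = e_step(x, beta, self.design, self.sf, np.array([0.1]), np.array([0.5]))
        assert e[0] < 0.5


class TestMStep:
    def test_saturated_poisson_closed_form(self):
        # one guide, two samples, x = (10, 40): beta -> (ln 10, ln 4)
        design = DesignMatrix(("s1", "s2"), ("c",), np.array([[0], [1]]))
        x = np.array([[10.0, 40.0]])
        cfg = tight_cfg(ridge_lambda=1e-9)
        dp = build_extended_design(design, 1)
        beta = m_step_irls(x, np.array([np.log(10.0), 0.0]), design, dp,
                           np.ones(2), np.zeros(1), np.ones(1), cfg)
        np.testing.assert_allclose(beta, [np.log(10), np.log(4)], atol=1e-6)

    def test_no_signal_gives_zero_condition_beta(self):
        design = DesignMatrix(("s1", "s2", "s3"), ("c",), np.array([[0], [1], [1]]))
        x = np.full((2, 3), 25.0)
        cfg = tight_cfg(ridge_lambda=1e-9)
        dp = build_extended_design(design, 2)
        beta = m_step_irls(x, np.r_[np.log([25.0, 25.0]), 0.0], design, dp,
                           np.ones(3), np.zeros(2), np.ones(2), cfg)
        assert abs(beta[-1]) < 1e-6

    def test_matches_generic_optimizer_small_instance(self):
        rng = np.random.default_rng(10)
        design = DesignMatrix(("s1", "s2", "s3"), ("c",), np.array([[0], [1], [1]]))
        x = rng.poisson([[30], [80]] * np.exp(rng.normal(0, 0.3, (2, 3)))).astype(float)
        sf = np.array([1.0, 0.9, 1.1])
        alpha = np.array([0.05, 0.05])
        cfg = tight_cfg()
        fit, state = fit_gene(x, design, sf, alpha, np.ones(2), cfg)
        oracle = maximize_numerically(
            x, design, sf, alpha, np.ones(2), cfg.ridge_lambda,
            [state.beta, np.r_[np.log(x.mean(1) + 1), 0.0]],
        )
        assert np.max(np.abs(oracle - state.beta)) < 1e-3


class TestFitGene:
    def test_parameter_recovery(self, screen_design):
        cm, lib, truth = sm.simulate_counts(
            1, 4, screen_design, effect_spec=np.full((1, 2), 1.0),
            alpha_true=0.05, rng_seed=21,
        )
        fit, _ = fit_gene(
            cm.counts.astype(float), screen_design, np.ones(5),
            np.full(4, 0.05), np.ones(4), FitConfig(),
        )
        assert np.all(np.abs(fit.beta_conditions - 1.0) < 0.3)

    def test_mixture_separates_inefficient_guides(self, screen_design):
        rng = np.random.default_rng(22)
        beta0 = np.log(rng.uniform(100, 1000, 4))
        efficient = np.array([True, True, False, False])
        cond = screen_design.entries @ np.array([1.5, 1.5])
        h = beta0[:, None] + np.where(efficient[:, None], cond[None, :], 0.0)
        x = rng.poisson(np.exp(h)).astype(float)
        fit, _ = fit_gene(x, screen_design, np.ones(5), np.full(4, 0.05),
                          np.full(4, 0.5), FitConfig())
        post = fit.efficiency_posterior
        assert post[:2].mean() > post[2:].mean()

    def test_single_guide_prior_one_is_m_step_fixed_point(self):
        design = DesignMatrix(("s1", "s2"), ("c",), np.array([[0], [1]]))
        x = np.array([[12.0, 48.0]])
        cfg = tight_cfg()
        fit, state = fit_gene(x, design, np.ones(2), np.zeros(1), np.ones(1), cfg)
        dp = build_extended_design(design, 1)
        beta = m_step_irls(x, state.beta, design, dp, np.ones(2), np.zeros(1),
                           np.ones(1), cfg)
        np.testing.assert_allclose(beta, state.beta, atol=1e-8)

    def test_all_zero_gene_not_estimable(self, screen_design):
        fit, _ = fit_gene(np.zeros((2, 5)), screen_design, np.ones(5),
                          np.full(2, 0.1), np.ones(2), FitConfig())
        assert not fit.estimable
        np.testing.assert_array_equal(fit.beta_conditions, 0.0)

    def test_em_objective_monotone(self, screen_design):
        rng = np.random.default_rng(23)
        for trial in range(10):
            x = rng.poisson(rng.uniform(20, 500, (3, 1)) *
                            np.exp(rng.normal(0, 0.8, (3, 5)))).astype(float)
            prior = rng.choice([1.0, 0.5, 0.8], 3)
            _, state = fit_gene(x, screen_design, np.ones(5), np.full(3, 0.1),
                                prior, FitConfig())
            diffs = np.diff(state.loglik_history)
            assert np.all(diffs >= -1e-8)

    def test_poisson_glm_identity_saturated(self):
        # e = 1, alpha = 0, lambda -> 0, one guide per sample block:
        # fitted rates equal the per-sample counts
        design = DesignMatrix(("s1", "s2", "s3"), ("c1", "c2"),
                              np.array([[0, 0], [1, 0], [0, 1]]))
        x = np.array([[20.0, 60.0, 5.0]])
        fit, state = fit_gene(x, design, np.ones(3), np.zeros(1), np.ones(1),
                              tight_cfg(ridge_lambda=1e-10))
        mu = np.exp(build_extended_design(design, 1) @ state.beta)
        np.testing.assert_allclose(mu, x.ravel(), rtol=1e-5)

    def test_ridge_shrinkage_monotone_in_lambda(self):
        design = DesignMatrix(("s1", "s2"), ("c",), np.array([[0], [1]]))
        x = np.array([[10.0, 80.0]])
        betas = []
        for lam in (0.01, 0.1, 1.0, 10.0):
            fit, _ = fit_gene(x, design, np.ones(2), np.zeros(1), np.ones(1),
                              tight_cfg(ridge_lambda=lam))
            betas.append(abs(fit.beta_conditions[0]))
        assert betas == sorted(betas, reverse=True)


class TestFitAll:
    def test_gene_order_permutation_invariance(self, screen_design):
        cm, lib, _ = sm.simulate_counts(6, 3, screen_design, alpha_true=0.1, rng_seed=30)
        sf = SizeFactors(cm.sample_ids, np.ones(5))
        alpha = np.full(18, 0.1)
        fits = fit_all(cm, lib, screen_design, sf, alpha, FitConfig(), compute_se=False)
        # permute gene blocks
        order = [4, 0, 5, 2, 1, 3]
        rows = np.concatenate([np.arange(g * 3, g * 3 + 3) for g in order])
        cm2 = sm.CountMatrix(
            tuple(cm.sgrna_ids[i] for i in rows), cm.sample_ids, cm.counts[rows]
        )
        lib2 = SgRNALibrary(
            tuple(lib.sgrna_ids[i] for i in rows),
            tuple(lib.gene_ids[i] for i in rows),
            tuple(lib.spacers[i] for i in rows),
        )
        fits2 = fit_all(cm2, lib2, screen_design, sf, alpha[rows], FitConfig(),
                        compute_se=False)
        by_gene = {f.gene_id: f for f in fits2}
        for f in fits:
            np.testing.assert_allclose(
                f.beta_conditions, by_gene[f.gene_id].beta_conditions, atol=1e-12
            )

    def test_empty_gene_set(self, screen_design):
        lib = SgRNALibrary((), (), ())
        cm = sm.CountMatrix((), screen_design.sample_ids, np.zeros((0, 5), dtype=int))
        sf = SizeFactors(cm.sample_ids, np.ones(5))
        assert fit_all(cm, lib, screen_design, sf, np.zeros(0), FitConfig()) == []

    def test_sample_mismatch_rejected_before_fitting(self, screen_design, tiny_library):
        cm = sm.CountMatrix(tiny_library.sgrna_ids, ("x", "y"), np.ones((3, 2), dtype=int))
        sf = SizeFactors(("x", "y"), np.ones(2))
        with pytest.raises(ScreenValidationError, match="sample ids"):
            fit_all(cm, tiny_library, screen_design, sf, np.full(3, 0.1), FitConfig())
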