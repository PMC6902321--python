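"""Single-step Bayesian regression: imputation, Gibbs sampler, summaries."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import gsvcbias as g
from gsvcbias.config import SsbrChainConfig
from gsvcbias.relationships import a_inverse
from gsvcbias.ssbr import (
    SsbrPriors,
    build_ssbr_model,
    gebv,
    impute_markers,
    marker_genetic_variance,
    monte_carlo_error,
    run_gibbs,
)

from test_relationships import Ped, random_pedigree


class TestImputation:
    def test_offspring_of_two_genotyped_parents_gets_parent_mean(self):
        trio = Ped([-1, -1, 0], [-1, -1, 1])
        M2 = np.array([[1.0, -0.5], [0.0, 0.5]])
        M1, J1, ng, P11 = impute_markers(M2, a_inverse(trio), np.array([0, 1]))
        assert ng.tolist() == [2]
        assert M1 == pytest.approx(M2.mean(axis=0)[None, :])
        assert J1 == pytest.approx(np.ones(1))  # fully covered by genotyped parents

    def test_unrelated_non_genotyped_animal_imputes_to_zero(self):
        ped = Ped([-1, -1, -1], [-1, -1, -1])
        M2 = np.array([[1.0], [-1.0]])
        M1, J1, ng, _ = impute_markers(M2, a_inverse(ped), np.array([0, 1]))
        assert M1 == pytest.approx(np.zeros((1,1)))
        assert J1 == pytest.approx(np.zeros(1))

    def test_all_genotyped_gives_empty_m1(self):
        ped = Ped([-1, -1], [-1, -1])
        M1, J1, ng, P11 = impute_markers(np.eye(2), a_inverse(ped), np.array([0, 1]))
        assert M1.shape[0] == 0 and ng.size == 0

    def test_precision_basis_is_inverse_of_conditional_covariance(self):
        ped = random_pedigree(50, 10, seed=1)
        from gsvcbias.relationships import a_partitions

        geno = np.arange(30, 50)
        A11, A12, A21, A22, A22i = a_partitions(ped, geno)
        cond = A11 - A12 @ A22i @ A21
        _, _, ng, P11 = impute_markers(np.zeros((20, 1)), a_inverse(ped), geno)
        assert np.linalg.inv(P11.toarray()) == pytest.approx(cond, abs=1e-8)


class TestMonteCarloError:
    def test_iid_unit_normal_matches_closed_form(self):
        rng = np.random.default_rng(2)
        chain = rng.standard_normal(10_000)
        assert monte_carlo_error(chain, 100) == pytest.approx(0.01, rel=0.2)

    def test_constant_chain_has_zero_error(self):
        assert monte_carlo_error(np.full(1000, 2.5), 50) == 0.0

    def test_error_halves_when_chain_quadruples(self):
        rng = np.random.default_rng(3)
        chain = rng.standard_normal(40_000)
        short = monte_carlo_error(chain[:10_000], 100)
        long = monte_carlo_error(chain, 100)
        assert long == pytest.approx(short / 2, rel=0.35)

    def test_oversized_batch_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_error(np.zeros(10), 10)


def _animal_model_data(n=300, seed=4, sg=3.59, se=5.05):
    rng = np.random.default_rng(seed)
    ped = random_pedigree(n, 40, seed=seed)
    A = g.a_matrix_tabular(ped)
    L = np.linalg.cholesky(A + 1e-10 * np.eye(n))
    u = L @ rng.standard_normal(n) * np.sqrt(sg)
    y = 3.0 + u + rng.standard_normal(n) * np.sqrt(se)
    ph = pd.DataFrame(
        dict(animal=np.arange(n), value=y, herd=0, year=rng.integers(0, 3, n), season=0)
    )
    return ped, ph


class TestGibbs:
    def test_seeded_chains_bit_reproducible(self):
        ped, ph = _animal_model_data(n=80, seed=5)
        ainv = a_inverse(ped)
        model = build_ssbr_model(ped, ph, np.zeros(0, np.int64), np.zeros((0, 0)),
                                 np.zeros(0), ainv)
        cc = SsbrChainConfig(n_iter=300, burn_in=100)
        a = run_gibbs(model, SsbrPriors(), cc, 42)
        b = run_gibbs(model, SsbrPriors(), cc, 42)
        assert np.array_equal(a.var_eps, b.var_eps)
        assert np.array_equal(a.var_e, b.var_e)

    def test_without_markers_agrees_with_reml(self):
        # posterior mean of the polygenic variance vs AI-REML on the same data
        ped, ph = _animal_model_data(n=400, seed=6)
        ainv = a_inverse(ped)
        model = build_ssbr_model(ped, ph, np.zeros(0, np.int64), np.zeros((0, 0)),
                                 np.zeros(0), ainv)
        post = run_gibbs(model, SsbrPriors(), SsbrChainConfig(n_iter=12_000, burn_in=4_000), 7)
        from gsvcbias.reml import MixedModelSpec, fit_reml, hys_design

        X, _ = hys_design(list(zip(ph["herd"], ph["year"], ph["season"])))
        est = fit_reml(MixedModelSpec(
            y=ph["value"].to_numpy(float), X=X,
            rec_animal=np.arange(400), n_animals=400, k_inverse=ainv))
        mce = monte_carlo_error(post.kept("eps"), 200)
        # MCMC error plus the weak-prior pull: allow 2 MCE + 5% of the estimate
        assert abs(post.posterior_mean("eps") - est.genetic_variance) < 2 * mce + 0.05 * est.genetic_variance

    def test_constant_response_collapses_residual_to_prior(self):
        ped = random_pedigree(40, 10, seed=8)
        ph = pd.DataFrame(dict(animal=np.arange(40), value=np.full(40, 7.0),
                               herd=0, year=0, season=0))
        model = build_ssbr_model(ped, ph, np.zeros(0, np.int64), np.zeros((0, 0)),
                                 np.zeros(0), a_inverse(ped))
        priors = SsbrPriors()
        post = run_gibbs(model, priors, SsbrChainConfig(n_iter=4000, burn_in=2000), 9)
        prior_mean_e = priors.df * priors.scale_e / (priors.df - 2)
        assert post.posterior_mean("e") < prior_mean_e  # no residual signal left

    def test_duplicated_markers_leave_genetic_variance_invariant(self):
        # doubling the marker panel with copies halves sigma_alpha^2 but not
        # sigma_alpha^2 * sum 2pq
        rng = np.random.default_rng(10)
        n, m = 250, 60
        ped = Ped(np.full(n, -1), np.full(n, -1))
        ainv = sp.eye(n, format="csc")
        p = rng.uniform(0.1, 0.9, m)
        geno = rng.binomial(2, p[None, :].repeat(n, 0))
        alpha = rng.standard_normal(m) * np.sqrt(3.0 / np.sum(2 * p * (1 - p)))
        y = (geno - 2 * p) @ alpha + rng.standard_normal(n) * np.sqrt(5.0)
        ph = pd.DataFrame(dict(animal=np.arange(n), value=y, herd=0, year=0, season=0))
        cc = SsbrChainConfig(n_iter=6000, burn_in=2000)
        m_single = build_ssbr_model(ped, ph, np.arange(n), geno, p, ainv)
        m_double = build_ssbr_model(ped, ph, np.arange(n), np.hstack([geno, geno]),
                                    np.concatenate([p, p]), ainv)
        v1, _ = marker_genetic_variance(run_gibbs(m_single, SsbrPriors(), cc, 11),
                                        m_single.centering_freqs)
        v2, _ = marker_genetic_variance(run_gibbs(m_double, SsbrPriors(), cc, 11),
                                        m_double.centering_freqs)
        assert v2 == pytest.approx(v1, rel=0.25)

    def test_fixed_frequencies_give_zero_marker_variance(self):
        chain = g.PosteriorChain(var_alpha=np.ones(10), var_eps=np.ones(10),
                                 var_e=np.ones(10), burn_in=0, seed=0)
        mean, sd = marker_genetic_variance(chain, np.array([0.0, 1.0]))
        assert mean == 0.0 and sd == 0.0


class TestGebv:
    def test_zero_effects_give_zero_gebv(self):
        ped, ph = _animal_model_data(n=30, seed=12)
        ainv = a_inverse(ped)
        geno = np.arange(20, 30)
        rng = np.random.default_rng(13)
        g2 = rng.integers(0, 3, (10, 5))
        model = build_ssbr_model(ped, ph, geno, g2, np.full(5, 0.5), ainv)
        chain = g.PosteriorChain(var_alpha=np.ones(2), var_eps=np.ones(2),
                                 var_e=np.ones(2), burn_in=0, seed=0,
                                 alpha_mean=np.zeros(5),
                                 eps_mean=np.zeros(model.non_genotyped.size))
        assert not gebv(model, chain).any()

    def test_genotyped_gebv_ignores_imputation_residual(self):
        ped, ph = _animal_model_data(n=30, seed=14)
        ainv = a_inverse(ped)
        geno = np.arange(20, 30)
        rng = np.random.default_rng(15)
        g2 = rng.integers(0, 3, (10, 5))
        model = build_ssbr_model(ped, ph, geno, g2, np.full(5, 0.5), ainv)
        alpha = rng.standard_normal(5)
        eps_a = rng.standard_normal(model.non_genotyped.size)
        chain_a = g.PosteriorChain(var_alpha=np.ones(2), var_eps=np.ones(2),
                                   var_e=np.ones(2), burn_in=0, seed=0,
                                   alpha_mean=alpha, eps_mean=eps_a)
        chain_b = g.PosteriorChain(var_alpha=np.ones(2), var_eps=np.ones(2),
                                   var_e=np.ones(2), burn_in=0, seed=0,
                                   alpha_mean=alpha, eps_mean=eps_a * -3.0)
        ga, gb = gebv(model, chain_a), gebv(model, chain_b)
        assert ga[geno] == pytest.approx(gb[geno])
        assert not np.allclose(ga[model.non_genotyped], gb[model.non_genotyped])

    def test_heritability_uses_total_genetic_route(self):
        chain = g.PosteriorChain(var_alpha=np.ones(4), var_eps=np.full(4, 3.0),
                                 var_e=np.full(4, 5.0), burn_in=1, seed=0)
        assert chain.heritability() == pytest.approx(3.0 / 8.0)
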