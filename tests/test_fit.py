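"""ELBO estimation, fitting, sampling, density evaluation, serialization."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy import integrate, special

from polyatree import (
    ApproxLikelihood,
    BaseParams,
    FitConfig,
    ReadCompat,
    approx_log_density,
    approx_sample,
    baseline_tree,
    elbo_estimate,
    fit_approximation,
    load_approx,
    save_approx,
)
from polyatree.basedist import base_draws

from test_compat import quadrature_posterior_n2


def unambiguous_compat(counts):
    n = len(counts)
    dense = np.eye(n)
    return ReadCompat(sp.csr_matrix(dense), np.asarray(counts))


class TestElbo:
    def test_flat_likelihood_is_loglik_plus_entropy(self):
        """With a flat likelihood the ELBO is m log c plus the entropy of q."""
        from polyatree import log_density, ptt_forward, reparam_sample
        from polyatree.tree import ptt_log_abs_det_jacobian

        c = ReadCompat(sp.csr_matrix(np.full((7, 3), 0.4)))
        tree = baseline_tree(3, "sequential")
        base = BaseParams("logit_normal", mu=np.zeros(2), sigma=np.full(2, 0.5))
        draws = base_draws("logit_normal", (4000, 2), np.random.default_rng(0))
        elbo = elbo_estimate(c, tree, base, draws)
        entropy = 0.0  # MC estimate of -E[log q(x)] with the same draws
        for z in draws:
            y = reparam_sample(base, z)
            _, u = ptt_forward(tree, y)
            entropy += (-log_density(base, y) + ptt_log_abs_det_jacobian(u, 3)) / len(draws)
        assert elbo == pytest.approx(7 * np.log(0.4) + entropy, abs=1e-9)

    def test_zero_ambiguity_elbo_bounded_by_log_normalizer(self):
        """ELBO lower-bounds the log normalizer of the Dirichlet posterior."""
        c = unambiguous_compat([3, 1])
        log_norm = np.log(special.beta(4, 2))  # integral of x1^3 x2^1 over simplex
        config = FitConfig(steps=3000, seed=0, family="logit_normal", tree_method="sequential")
        approx = fit_approximation(c, config)
        draws = base_draws("logit_normal", (20000, 1), np.random.default_rng(1))
        elbo = elbo_estimate(c, approx.tree, approx.base, draws)
        assert elbo <= log_norm + 1e-3
        assert log_norm - elbo < 0.05  # a moment-matched logit-normal is close


class TestFitApproximation:
    @pytest.mark.parametrize("tree_method", ["jaccard", "random", "sequential"])
    def test_zero_ambiguity_means_match_dirichlet(self, tree_method):
        counts = np.array([50, 20, 10, 5, 1, 0])
        c = unambiguous_compat(counts[counts > 0])
        # keep the zero-count transcript: build explicitly
        dense = np.zeros((5, 6))
        dense[np.arange(5), np.arange(5)] = 1.0
        c = ReadCompat(sp.csr_matrix(dense), counts[:5])
        config = FitConfig(steps=3000, seed=2, tree_method=tree_method)
        approx = fit_approximation(c, config)
        draws = approx_sample(approx, 20000, seed=3)
        alpha = counts + 1.0
        np.testing.assert_allclose(draws.mean(0), alpha / alpha.sum(), atol=0.02)

    def test_ambiguous_n2_matches_quadrature(self, two_transcript_ambiguous):
        mean, sd = quadrature_posterior_n2(two_transcript_ambiguous)
        config = FitConfig(steps=4000, seed=4, tree_method="sequential")
        approx = fit_approximation(two_transcript_ambiguous, config)
        draws = approx_sample(approx, 20000, seed=5)
        assert draws[:, 0].mean() == pytest.approx(mean, abs=0.02)
        assert draws[:, 0].std() == pytest.approx(sd, abs=0.02)

    def test_seed_reproducible(self, two_transcript_ambiguous):
        config = FitConfig(steps=50, seed=11)
        a1 = fit_approximation(two_transcript_ambiguous, config)
        a2 = fit_approximation(two_transcript_ambiguous, config)
        np.testing.assert_array_equal(a1.base.mu, a2.base.mu)
        np.testing.assert_array_equal(a1.base.sigma, a2.base.sigma)

    def test_smoothed_elbo_improves(self, small_experiment):
        c = small_experiment.compat[0]
        approx = fit_approximation(c, FitConfig(steps=800, seed=1))
        assert approx.fit_meta["elbo"] >= approx.fit_meta["elbo_first"]


class TestApproxSample:
    def test_simplex_invariants_and_consistency(self, small_experiment):
        c = small_experiment.compat[0]
        approx = fit_approximation(c, FitConfig(steps=400, seed=6))
        draws = approx_sample(approx, 10000, seed=7)
        assert ((draws > 0) & (draws < 1)).all()
        np.testing.assert_allclose(draws.sum(1), 1.0, atol=1e-8)
        d2 = approx_sample(approx, 10000, seed=7)
        np.testing.assert_array_equal(draws, d2)

    def test_sample_mean_matches_larger_sample(self, two_transcript_ambiguous):
        approx = fit_approximation(two_transcript_ambiguous, FitConfig(steps=2000, seed=8))
        d1 = approx_sample(approx, 10000, seed=9)
        d2 = approx_sample(approx, 100000, seed=10)
        se = d2[:, 0].std() / np.sqrt(10000)
        assert abs(d1[:, 0].mean() - d2[:, 0].mean()) < 3 * se


class TestApproxLogDensity:
    def test_integrates_to_one_n2(self, two_transcript_ambiguous):
        approx = fit_approximation(two_transcript_ambiguous, FitConfig(steps=1000, seed=12))

        def dens(x1):
            return np.exp(approx_log_density(approx, np.array([x1, 1 - x1])))

        total, err = integrate.quad(dens, 1e-9, 1 - 1e-9, limit=200)
        assert total == pytest.approx(1.0, abs=max(1e-5, 10 * err))

    def test_mode_near_dirichlet_mode(self):
        # zero ambiguity, counts (30, 10): posterior Beta(31, 11), mode 0.75
        c = unambiguous_compat([30, 10])
        approx = fit_approximation(c, FitConfig(steps=3000, seed=13, family="logit_normal"))
        grid = np.linspace(0.02, 0.98, 481)
        dens = [approx_log_density(approx, np.array([g, 1 - g])) for g in grid]
        assert grid[np.argmax(dens)] == pytest.approx(30 / 40, abs=0.02)

    def test_density_consistent_with_samples(self, two_transcript_ambiguous):
        approx = fit_approximation(two_transcript_ambiguous, FitConfig(steps=500, seed=14))
        draws = approx_sample(approx, 50, seed=15)
        vals = [approx_log_density(approx, d) for d in draws]
        assert np.isfinite(vals).all()


class TestSerialization:
    @pytest.mark.parametrize("family", ["logit_normal", "logit_skew_normal", "kumaraswamy"])
    def test_round_trip_bit_identical_samples(self, family, tmp_path, small_experiment):
        c = small_experiment.compat[0]
        approx = fit_approximation(
            c,
            FitConfig(steps=100, seed=16, family=family),
            transcript_ids=small_experiment.transcript_ids,
            effective_lengths=small_experiment.effective_lengths,
        )
        path = tmp_path / "approx.h5"
        save_approx(approx, path)
        loaded = load_approx(path)
        np.testing.assert_array_equal(
            approx_sample(approx, 100, seed=17), approx_sample(loaded, 100, seed=17)
        )
        assert loaded.transcript_ids == approx.transcript_ids
        np.testing.assert_array_equal(loaded.tree.left, approx.tree.left)
        np.testing.assert_array_equal(loaded.effective_lengths, approx.effective_lengths)
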