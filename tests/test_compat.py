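"""Exact likelihood, EM estimate, and the Gibbs oracle."""

import numpy as np
import pytest
import scipy.sparse as sp

from polyatree import ReadCompat, gibbs_sample, log_likelihood, ml_estimate
from polyatree.compat import log_likelihood_grad


def quadrature_posterior_n2(compat, grid=10**-4):
    """Normalized-likelihood mean/sd of x1 for n=2 by grid integration."""
    x1 = np.arange(grid / 2, 1.0, grid)
    dense = compat.matrix.toarray()
    logp = np.zeros_like(x1)
    for row, w in zip(dense, compat.weights):
        logp += w * np.log(row[0] * x1 + row[1] * (1 - x1))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    mean = float(p @ x1)
    sd = float(np.sqrt(p @ (x1 - mean) ** 2))
    return mean, sd


class TestLogLikelihood:
    def test_single_unambiguous_read(self):
        c = ReadCompat(sp.csr_matrix(np.array([[1.0, 0.0]])))
        assert log_likelihood(c, np.array([0.3, 0.7])) == pytest.approx(np.log(0.3))

    def test_flat_rows_independent_of_x(self):
        c = ReadCompat(sp.csr_matrix(np.full((4, 3), 0.2)))
        for x in (np.array([0.1, 0.2, 0.7]), np.full(3, 1 / 3)):
            assert log_likelihood(c, x) == pytest.approx(4 * np.log(0.2))

    def test_three_read_example(self):
        c = ReadCompat(sp.csr_matrix(np.array([[1, 0], [0, 1], [0.5, 0.5]], dtype=float)))
        assert log_likelihood(c, np.array([0.5, 0.5])) == pytest.approx(
            np.log(0.5 * 0.5 * 0.5)
        )

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_dense_bruteforce(self, trial, rng):
        m, n = int(rng.integers(1, 11)), int(rng.integers(2, 11))
        dense = rng.random((m, n)) * (rng.random((m, n)) < 0.6)
        dense[np.arange(m), rng.integers(0, n, m)] = rng.random(m) + 0.05
        w = rng.integers(1, 5, m)
        x = rng.dirichlet(np.ones(n))
        x = np.clip(x, 1e-12, None)
        x /= x.sum()
        expected = float(w @ np.log(dense @ x))
        c = ReadCompat(sp.csr_matrix(dense), w)
        assert log_likelihood(c, x) == pytest.approx(expected, abs=1e-10)

    def test_weights_equal_row_repetition(self, rng):
        dense = np.array([[0.5, 0.5], [1.0, 0.0]])
        x = np.array([0.4, 0.6])
        c1 = ReadCompat(sp.csr_matrix(np.vstack([dense[0], dense[0], dense[1]])))
        c2 = ReadCompat(sp.csr_matrix(dense), np.array([2, 1]))
        assert log_likelihood(c1, x) == pytest.approx(log_likelihood(c2, x))

    def test_gradient_matches_finite_difference(self, rng):
        dense = rng.random((6, 4)) + 0.01
        c = ReadCompat(sp.csr_matrix(dense), rng.integers(1, 4, 6))
        x = rng.dirichlet(np.ones(4))
        g = log_likelihood_grad(c, x)
        h = 1e-7
        for j in range(4):
            xp, xm = x.copy(), x.copy()
            xp[j] += h
            xm[j] -= h
            num = (log_likelihood(c, xp) - log_likelihood(c, xm)) / (2 * h)
            assert g[j] == pytest.approx(num, rel=1e-5)

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            ReadCompat(sp.csr_matrix(np.array([[1.0, 0.0], [0.0, 0.0]])))
        with pytest.raises(ValueError):
            ReadCompat(sp.csr_matrix(np.array([[1.0, -0.5]])))
        c = ReadCompat(sp.csr_matrix(np.array([[1.0, 0.0]])))
        with pytest.raises(ValueError):
            log_likelihood(c, np.array([0.2, 0.3, 0.5]))

    def test_collapse_is_lossless(self):
        dense = np.array([[0.5, 0.5], [0.5, 0.5], [1.0, 0.0], [0.5, 0.5]])
        c = ReadCompat.collapse(sp.csr_matrix(dense))
        assert c.m == 2
        assert c.total_reads == 4
        x = np.array([0.3, 0.7])
        full = ReadCompat(sp.csr_matrix(dense))
        assert log_likelihood(c, x) == pytest.approx(log_likelihood(full, x))


class TestMlEstimate:
    def test_unambiguous_closed_form(self):
        dense = np.zeros((3, 3))
        dense[0, 0] = dense[1, 1] = dense[2, 2] = 1.0
        c = ReadCompat(sp.csr_matrix(dense), np.array([6, 3, 1]))
        np.testing.assert_allclose(ml_estimate(c), [0.6, 0.3, 0.1], atol=1e-8)

    def test_boundary_maximizer_clamped(self):
        c = ReadCompat(sp.csr_matrix(np.array([[1.0, 0.0], [0.5, 0.5]])))
        x = ml_estimate(c, max_iter=20000)
        # grid oracle: maximize x1 * 0.5 -> x1 -> 1; interior clamp keeps it < 1
        grid = np.arange(1e-4, 1.0, 1e-4)
        best = grid[np.argmax(np.log(grid) + np.log(0.5))]
        assert best == pytest.approx(grid[-1])
        assert x[0] > 0.999

    def test_symmetric_instance(self):
        c = ReadCompat(sp.csr_matrix(np.full((5, 2), 0.5)))
        np.testing.assert_allclose(ml_estimate(c), [0.5, 0.5], atol=1e-12)

    def test_monotone_loglikelihood(self, small_experiment):
        c = small_experiment.compat[0]
        x = np.full(c.n, 1.0 / c.n)
        prev = log_likelihood(c, x)
        M, w = c.matrix, c.weights.astype(float)
        for _ in range(50):
            x = x * (M.T @ (w / (M @ x))) / w.sum()
            x = np.clip(x, 1e-12, None)
            x /= x.sum()
            cur = log_likelihood(c, x)
            assert cur >= prev - 1e-9
            prev = cur


class TestGibbs:
    def test_retained_draw_count_default_protocol(self):
        # 25000 iterations thinned by 25 -> 1000 retained draws per chain
        assert 25000 // 25 == 1000
        c = ReadCompat(sp.csr_matrix(np.array([[1.0, 0.0], [0.0, 1.0]])), np.array([3, 1]))
        run = gibbs_sample(c, chains=2, burn_in=10, iterations=100, thin=25, seed=0)
        assert run.draws.shape == (2, 4, 2)

    def test_indivisible_thinning_rejected(self):
        c = ReadCompat(sp.csr_matrix(np.array([[1.0, 0.0]])))
        with pytest.raises(ValueError):
            gibbs_sample(c, iterations=103, thin=25)

    def test_unambiguous_matches_dirichlet_moments(self):
        counts = np.array([40, 10, 5])
        dense = np.zeros((3, 3))
        dense[np.arange(3), np.arange(3)] = 1.0
        c = ReadCompat(sp.csr_matrix(dense), counts)
        run = gibbs_sample(c, chains=4, burn_in=200, iterations=10000, thin=10, seed=3)
        draws = run.draws.reshape(-1, 3)
        alpha = counts + 1.0
        a0 = alpha.sum()
        mean = alpha / a0
        var = alpha * (a0 - alpha) / (a0**2 * (a0 + 1))
        se = draws.std(0, ddof=1) / np.sqrt(len(draws))
        assert (np.abs(draws.mean(0) - mean) < 3 * se).all()
        m4 = ((draws - draws.mean(0)) ** 4).mean(0)
        se_var = np.sqrt((m4 - draws.var(0) ** 2) / len(draws))
        assert (np.abs(draws.var(0, ddof=1) - var) < 3 * se_var).all()

    def test_ambiguous_mean_matches_quadrature(self, two_transcript_ambiguous):
        mean, _ = quadrature_posterior_n2(two_transcript_ambiguous)
        run = gibbs_sample(
            two_transcript_ambiguous, chains=4, burn_in=500, iterations=10000, thin=10, seed=4
        )
        draws = run.draws.reshape(-1, 2)
        se = draws[:, 0].std(ddof=1) / np.sqrt(len(draws))
        assert abs(draws[:, 0].mean() - mean) < 3 * se

    def test_seed_reproducible(self, two_transcript_ambiguous):
        r1 = gibbs_sample(two_transcript_ambiguous, chains=2, burn_in=10, iterations=100, thin=10, seed=7)
        r2 = gibbs_sample(two_transcript_ambiguous, chains=2, burn_in=10, iterations=100, thin=10, seed=7)
        np.testing.assert_array_equal(r1.draws, r2.draws)
        r3 = gibbs_sample(two_transcript_ambiguous, chains=2, burn_in=10, iterations=100, thin=10, seed=8)
        assert not np.array_equal(r1.draws, r3.draws)

    def test_transcripts_without_reads_keep_prior_mass(self):
        dense = np.array([[1.0, 0.0, 0.0]])
        c = ReadCompat(sp.csr_matrix(dense), np.array([10]))
        run = gibbs_sample(c, chains=2, burn_in=100, iterations=2000, thin=10, seed=5)
        draws = run.draws.reshape(-1, 3)
        # Dirichlet(11, 1, 1): unexpressed transcripts still average 1/13
        np.testing.assert_allclose(draws[:, 1:].mean(0), 1 / 13, atol=0.01)
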