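"""Read–transcript compatibility data and exact-likelihood computations.

The sufficient data for transcript quantification is a sparse matrix of
conditional read probabilities ``p_j(r_i)``: the probability of read (or
read-equivalence-class) ``i`` under transcript ``j``'s read distribution.
Given relative expression ``x`` on the simplex, the likelihood is the
sparse mixture

    P(r | x) = prod_i [ sum_j x_j p_j(r_i) ] ** w_i

with integer multiplicities ``w_i`` for collapsed identical rows.  This
module provides the exact log-likelihood, the EM maximum-likelihood
estimate, and a data-augmented Gibbs sampler for the normalized
likelihood (the posterior under a uniform Dirichlet prior) that serves as
the exactness oracle for the approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from numba import njit

INTERIOR_EPS = 1e-12  # open-simplex clamp: no component ever reaches 0 or 1

__all__ = [
    "ReadCompat",
    "GibbsRun",
    "clamp_simplex",
    "log_likelihood",
    "ml_estimate",
    "gibbs_sample",
]


def clamp_simplex(x: np.ndarray) -> np.ndarray:
    """Clamp to [eps, 1-eps] and renormalize; keeps points strictly interior."""
    x = np.clip(x, INTERIOR_EPS, 1.0 - INTERIOR_EPS)
    return x / x.sum(axis=-1, keepdims=True)


@dataclass
class ReadCompat:
    """Sparse m x n compatibility matrix with per-row multiplicities.

    ``matrix`` holds ``p_j(r_i)`` for distinct rows; ``weights[i]`` counts
    how many reads share row ``i``.  Collapsing identical rows is exact:
    the likelihood factors over rows.
    """

    matrix: sp.csr_matrix
    weights: np.ndarray

    def __init__(self, matrix, weights=None):
        matrix = sp.csr_matrix(matrix, dtype=np.float64)
        matrix.sum_duplicates()
        if weights is None:
            weights = np.ones(matrix.shape[0], dtype=np.int64)
        weights = np.asarray(weights, dtype=np.int64)
        if matrix.shape[0] < 1 or matrix.shape[1] < 1:
            raise ValueError("need at least one read row and one transcript")
        if weights.shape != (matrix.shape[0],) or (weights <= 0).any():
            raise ValueError("weights must be positive with one entry per row")
        if not np.isfinite(matrix.data).all() or (matrix.data < 0).any():
            raise ValueError("entries must be finite and nonnegative")
        support = np.diff(matrix.indptr)
        if (support == 0).any() or (matrix.data == 0).any():
            # explicit zeros are pruned; fully empty rows are invalid
            matrix.eliminate_zeros()
            if (np.diff(matrix.indptr) == 0).any():
                raise ValueError("every row needs at least one positive entry")
        self.matrix = matrix
        self.weights = weights

    @property
    def m(self) -> int:
        """Number of distinct rows (read equivalence classes)."""
        return self.matrix.shape[0]

    @property
    def n(self) -> int:
        return self.matrix.shape[1]

    @property
    def total_reads(self) -> int:
        return int(self.weights.sum())

    def read_counts(self) -> np.ndarray:
        """Per-transcript read counts, attributing each row to its support.

        Only exact for unambiguous rows; ambiguous rows are split equally
        (used for diagnostics and Dirichlet closed forms at zero ambiguity).
        """
        support = np.diff(self.matrix.indptr)
        frac = np.repeat(self.weights / support, support)
        counts = np.zeros(self.n)
        np.add.at(counts, self.matrix.indices, frac)
        return counts

    @classmethod
    def collapse(cls, matrix) -> "ReadCompat":
        """Collapse identical rows into weighted equivalence classes."""
        matrix = sp.csr_matrix(matrix, dtype=np.float64)
        keys = {}
        order, weights = [], []
        for i in range(matrix.shape[0]):
            lo, hi = matrix.indptr[i], matrix.indptr[i + 1]
            key = (matrix.indices[lo:hi].tobytes(), matrix.data[lo:hi].tobytes())
            if key in keys:
                weights[keys[key]] += 1
            else:
                keys[key] = len(order)
                order.append(i)
                weights.append(1)
        return cls(matrix[order], np.asarray(weights))


# ----------------------------------------------------------------------


def log_likelihood(compat: ReadCompat, x: np.ndarray) -> float:
    """Exact log-likelihood, with a per-row log-sum-exp over the support."""
    x = np.asarray(x, dtype=float)
    if x.shape != (compat.n,):
        raise ValueError("x has wrong length")
    M = compat.matrix
    logs = np.log(M.data) + np.log(x[M.indices])
    # row-wise logsumexp over the sparse support
    row_max = np.fmax.reduceat(logs, M.indptr[:-1])
    row_sum = np.add.reduceat(np.exp(logs - np.repeat(row_max, np.diff(M.indptr))), M.indptr[:-1])
    row_ll = row_max + np.log(row_sum)
    return float(np.dot(compat.weights, row_ll))


def log_likelihood_grad(compat: ReadCompat, x: np.ndarray) -> np.ndarray:
    """d log P / d x — sparse: per-read work proportional to row support."""
    M = compat.matrix
    denom = M @ x
    return M.T @ (compat.weights / denom)


def ml_estimate(compat: ReadCompat, tol: float = 1e-9, max_iter: int = 1000) -> np.ndarray:
    """EM fixed point of the mixture likelihood from a uniform start.

    Update: ``x_j ∝ sum_i w_i x_j p_j(r_i) / sum_k x_k p_k(r_i)``; the
    log-likelihood is non-decreasing and the iteration stops when the
    largest component change falls below ``tol``.
    """
    M = compat.matrix
    w = compat.weights.astype(float)
    total = w.sum()
    x = np.full(compat.n, 1.0 / compat.n)
    for _ in range(max_iter):
        denom = M @ x
        x_new = x * (M.T @ (w / denom)) / total
        x_new = clamp_simplex(x_new)
        if np.abs(x_new - x).max() < tol:
            x = x_new
            break
        x = x_new
    return x


# ----------------------------------------------------------------------
# Gibbs sampler


@dataclass
class GibbsRun:
    """Multi-chain draws from the normalized likelihood."""

    chains: int
    draws: np.ndarray  # (chains, draws_per_chain, n)
    burn_in: int
    thin: int
    seed: int

    @property
    def draws_per_chain(self) -> int:
        return self.draws.shape[1]

    def pooled(self, count: int | None = None, seed: int = 0) -> np.ndarray:
        """Pool chains and subsample ``count`` draws (without replacement)."""
        flat = self.draws.reshape(-1, self.draws.shape[-1])
        if count is None or count >= flat.shape[0]:
            return flat
        idx = np.random.default_rng(seed).choice(flat.shape[0], count, replace=False)
        return flat[np.sort(idx)]


@njit(cache=False)
def _gibbs_chain(
    n,
    uw_counts,
    amb_indptr,
    amb_indices,
    amb_p,
    amb_w,
    burn_in,
    iterations,
    thin,
    seed,
    out,
):  # pragma: no cover - exercised via gibbs_sample
    np.random.seed(seed)
    x = np.empty(n)
    for j in range(n):
        x[j] = np.random.gamma(1.0, 1.0)
    x /= x.sum()
    counts = np.empty(n)
    n_amb = amb_indptr.shape[0] - 1
    max_support = 1
    for r in range(n_amb):
        s = amb_indptr[r + 1] - amb_indptr[r]
        if s > max_support:
            max_support = s
    q = np.empty(max_support)
    saved = 0
    for it in range(burn_in + iterations):
        for j in range(n):
            counts[j] = uw_counts[j]
        # multinomial split of each ambiguous row via sequential binomials
        for r in range(n_amb):
            lo, hi = amb_indptr[r], amb_indptr[r + 1]
            s = hi - lo
            tot = 0.0
            for k in range(s):
                q[k] = x[amb_indices[lo + k]] * amb_p[lo + k]
                tot += q[k]
            wrem = amb_w[r]
            qrem = tot
            for k in range(s - 1):
                if wrem == 0:
                    break
                pk = q[k] / qrem
                if pk > 1.0:
                    pk = 1.0
                c = np.random.binomial(wrem, pk)
                counts[amb_indices[lo + k]] += c
                wrem -= c
                qrem -= q[k]
            if wrem > 0:
                counts[amb_indices[lo + s - 1]] += wrem
        # x | z ~ Dirichlet(1 + counts)
        tot = 0.0
        for j in range(n):
            x[j] = np.random.gamma(1.0 + counts[j], 1.0)
            tot += x[j]
        for j in range(n):
            x[j] /= tot
        if it >= burn_in and (it - burn_in + 1) % thin == 0:
            for j in range(n):
                out[saved, j] = x[j]
            saved += 1


def gibbs_sample(
    compat: ReadCompat,
    chains: int = 8,
    burn_in: int = 2000,
    iterations: int = 25000,
    thin: int = 25,
    seed: int = 0,
) -> GibbsRun:
    """Data-augmented Gibbs sampler targeting the normalized likelihood.

    Alternates drawing read assignments ``z_i | x ∝ x_j p_j(r_i)`` over
    each row's support with ``x | z ~ Dirichlet(1 + counts)`` (the uniform
    Dirichlet prior).  Defaults follow the reference protocol: 8 randomly
    initialized chains, 2000 burn-in iterations, 25000 further iterations
    with every 25th draw retained (1000 draws per chain).
    """
    if iterations % thin != 0:
        raise ValueError("iterations must be divisible by thin")
    M = compat.matrix
    support = np.diff(M.indptr)
    unamb = support == 1
    uw_counts = np.zeros(compat.n)
    rows1 = np.flatnonzero(unamb)
    if rows1.size:
        cols = M.indices[M.indptr[rows1]]
        np.add.at(uw_counts, cols, compat.weights[rows1])
    amb = ~unamb
    Ma = M[amb]
    amb_w = compat.weights[amb]
    draws_per = iterations // thin
    out = np.empty((chains, draws_per, compat.n))
    for c in range(chains):
        chain_seed = int((seed + 1_000_003 * (c + 1)) % (2**31 - 1))
        _gibbs_chain(
            compat.n,
            uw_counts,
            Ma.indptr.astype(np.int64),
            Ma.indices.astype(np.int64),
            Ma.data,
            amb_w.astype(np.int64),
            burn_in,
            iterations,
            thin,
            chain_seed,
            out[c],
        )
    return GibbsRun(chains=chains, draws=out, burn_in=burn_in, thin=thin, seed=seed)
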