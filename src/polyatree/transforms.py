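"""Classical compositional-data bijections: alr, mlr and (balanced) ilr.

These map the open unit simplex to unconstrained coordinates and back,
and are used to induce baseline distribution families for comparison with
the Pólya tree transformation.  The mlr transform is exactly the logit of
the sequential stick-breaking fractions, i.e. the caterpillar-tree special
case of the Pólya tree transform.
"""

from __future__ import annotations

import numpy as np

__all__ = ["alr", "alr_inv", "mlr", "mlr_inv", "ilr_balanced", "ilr_balanced_inv"]


def _check_simplex(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if (x <= 0).any():
        raise ValueError("x must be strictly positive")
    return x


def alr(x: np.ndarray, divisor_index: int | None = None) -> np.ndarray:
    """Additive log-ratio: ``log(x_i / x_D)`` for the n-1 non-divisor parts.

    ``divisor_index`` is 1-based and defaults to the last component.
    """
    x = _check_simplex(x)
    n = x.shape[-1]
    d = n if divisor_index is None else divisor_index
    if not 1 <= d <= n:
        raise ValueError("divisor_index out of range")
    lx = np.log(x)
    keep = [i for i in range(n) if i != d - 1]
    return lx[..., keep] - lx[..., d - 1 : d]


def alr_inv(v: np.ndarray, n: int | None = None, divisor_index: int | None = None) -> np.ndarray:
    """Inverse alr: softmax with a fixed zero inserted at the divisor slot."""
    v = np.asarray(v, dtype=float)
    m = v.shape[-1] + 1
    d = m if divisor_index is None else divisor_index
    full = np.insert(v, d - 1, 0.0, axis=-1)
    full -= full.max(axis=-1, keepdims=True)
    e = np.exp(full)
    return e / e.sum(axis=-1, keepdims=True)


def mlr(x: np.ndarray) -> np.ndarray:
    """Multiplicative log-ratio: ``log(x_i / (1 - sum_{j<=i} x_j))``.

    Equals the logit of the sequential stick-breaking break fractions.
    """
    x = _check_simplex(x)
    csum = np.cumsum(x, axis=-1)
    total = csum[..., -1:]
    rest = total - csum[..., :-1]  # robust to inputs summing to != 1 exactly
    return np.log(x[..., :-1]) - np.log(rest)


def mlr_inv(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    y = 1.0 / (1.0 + np.exp(-v))  # break fractions
    n1 = v.shape[-1]
    x = np.empty(v.shape[:-1] + (n1 + 1,))
    rest = np.ones(v.shape[:-1])
    for i in range(n1):
        x[..., i] = y[..., i] * rest
        rest = rest * (1.0 - y[..., i])
    x[..., n1] = rest
    return x


def _balanced_splits(lo: int, hi: int, out: list[tuple[int, int, int]]):
    """Recursive balanced bisection of the index range [lo, hi)."""
    if hi - lo < 2:
        return
    mid = (lo + hi + 1) // 2
    out.append((lo, mid, hi))
    _balanced_splits(lo, mid, out)
    _balanced_splits(mid, hi, out)


def ilr_basis(n: int) -> np.ndarray:
    """Orthonormal clr-space basis from a balanced full binary tree.

    Row ``k`` corresponds to a split with left part L (size r) and right
    part R (size s): ``sqrt(rs/(r+s)) * (1/r on L, -1/s on R)``.
    """
    splits: list[tuple[int, int, int]] = []
    _balanced_splits(0, n, splits)
    V = np.zeros((n - 1, n))
    for k, (lo, mid, hi) in enumerate(splits):
        r, s = mid - lo, hi - mid
        c = np.sqrt(r * s / (r + s))
        V[k, lo:mid] = c / r
        V[k, mid:hi] = -c / s
    return V


def ilr_balanced(x: np.ndarray) -> np.ndarray:
    """Isometric log-ratio coordinates wrt the balanced-tree basis."""
    x = _check_simplex(x)
    V = ilr_basis(x.shape[-1])
    return np.log(x) @ V.T


def ilr_balanced_inv(v: np.ndarray, n: int) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    V = ilr_basis(n)
    clr = v @ V
    clr -= clr.max(axis=-1, keepdims=True)
    e = np.exp(clr)
    return e / e.sum(axis=-1, keepdims=True)
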