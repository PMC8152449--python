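"""The Pólya tree transformation.

A full binary tree with ``n`` leaves defines a hierarchical stick-breaking
bijection between break fractions ``y ∈ (0,1)^{n-1}`` (together with an
initial stick length ``u1``) and ``n`` positive stick pieces.  With
``u1 = 1`` the image is the open unit simplex.  Sequential stick breaking
(the mlr transform, after a logit) is the special case of a caterpillar
tree; general topologies let the induced distribution families mirror the
sub-compositional independence structure of sparse mixture likelihoods.

Node labelling convention (kept at every interface and in serialization):
the root is node 1, internal nodes are ``1 … n-1``, leaves ``n … 2n-1``,
and every node's label is strictly greater than its parent's (as produced,
e.g., by a pre-order traversal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PolyaTree",
    "ptt_forward",
    "ptt_inverse",
    "ptt_log_abs_det_jacobian",
    "hierarchical_beta_sample",
]


@dataclass(frozen=True)
class PolyaTree:
    """Full binary tree defining a Pólya tree transformation.

    Parameters
    ----------
    n : int
        Number of leaves (transcripts).
    left, right : ndarray of int, shape (n-1,)
        1-based child labels of internal node ``i+1`` (``i = 0 … n-2``).
    leaf_to_transcript : ndarray of int, shape (n,)
        1-based transcript index attached to leaf node ``n + k``
        (``k = 0 … n-1``); a permutation of ``1 … n``.
    """

    n: int
    left: np.ndarray
    right: np.ndarray
    leaf_to_transcript: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "left", np.asarray(self.left, dtype=np.int64))
        object.__setattr__(self, "right", np.asarray(self.right, dtype=np.int64))
        object.__setattr__(
            self, "leaf_to_transcript", np.asarray(self.leaf_to_transcript, dtype=np.int64)
        )
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        n = self.n
        if n < 1:
            raise ValueError("tree must have at least one leaf")
        if self.left.shape != (n - 1,) or self.right.shape != (n - 1,):
            raise ValueError("left/right must have length n-1")
        if self.leaf_to_transcript.shape != (n,):
            raise ValueError("leaf_to_transcript must have length n")
        if sorted(self.leaf_to_transcript.tolist()) != list(range(1, n + 1)):
            raise ValueError("leaf_to_transcript must be a permutation of 1..n")
        if n == 1:
            return
        children = np.concatenate([self.left, self.right])
        if children.min() < 2 or children.max() > 2 * n - 1:
            raise ValueError("child labels must lie in 2..2n-1")
        if len(set(children.tolist())) != 2 * n - 2:
            raise ValueError("every non-root node must have exactly one parent")
        # no node may have a smaller label than any of its ancestors
        parents = np.arange(1, n)  # internal node labels
        if (self.left <= parents).any() or (self.right <= parents).any():
            raise ValueError("child labels must exceed the parent's label")

    # 0-based views used by the numeric kernels -------------------------
    @property
    def _left0(self) -> np.ndarray:
        return self.left - 1

    @property
    def _right0(self) -> np.ndarray:
        return self.right - 1

    @property
    def _perm0(self) -> np.ndarray:
        """0-based transcript index for leaf nodes in label order n..2n-1."""
        return self.leaf_to_transcript - 1

    @property
    def n_nodes(self) -> int:
        return 2 * self.n - 1

    # ------------------------------------------------------------------
    @classmethod
    def from_arbitrary(
        cls,
        root: int,
        left_child: dict[int, int],
        right_child: dict[int, int],
        leaf_label: dict[int, int],
    ) -> "PolyaTree":
        """Canonicalize an arbitrarily-numbered full binary tree.

        ``left_child``/``right_child`` map internal node ids to child ids;
        ``leaf_label`` maps leaf ids to 1-based transcript indices.  Nodes
        are renumbered by a pre-order traversal: internal nodes receive
        labels ``1 … n-1`` and leaves ``n … 2n-1`` in encounter order.
        """
        n = len(leaf_label)
        if n == 1:
            (t,) = leaf_label.values()
            return cls(1, np.empty(0, np.int64), np.empty(0, np.int64), np.array([t]))
        left = np.zeros(n - 1, dtype=np.int64)
        right = np.zeros(n - 1, dtype=np.int64)
        perm = np.zeros(n, dtype=np.int64)
        next_internal, next_leaf = 1, n
        # iterative pre-order; stack holds (node_id, slot) where slot stores
        # the (parent canonical label, is_left) to fill once numbered
        stack: list[tuple[int, tuple[int, bool] | None]] = [(root, None)]
        while stack:
            node, slot = stack.pop()
            if node in leaf_label:
                label = next_leaf
                next_leaf += 1
                perm[label - n] = leaf_label[node]
            else:
                label = next_internal
                next_internal += 1
                stack.append((right_child[node], (label, False)))
                stack.append((left_child[node], (label, True)))
            if slot is not None:
                parent, is_left = slot
                (left if is_left else right)[parent - 1] = label
        return cls(n, left, right, perm)


# ----------------------------------------------------------------------
# forward / inverse / Jacobian


def _intermediate_forward(tree: PolyaTree, y: np.ndarray, u1: float) -> np.ndarray:
    """Top-down pass filling all 2n-1 intermediate stick lengths."""
    n = tree.n
    u = np.empty(2 * n - 1)
    u[0] = u1
    l0, r0 = tree._left0, tree._right0
    for i in range(n - 1):
        ui = u[i]
        u[l0[i]] = y[i] * ui
        u[r0[i]] = (1.0 - y[i]) * ui
    return u


def ptt_forward(tree: PolyaTree, y: np.ndarray, u1: float = 1.0):
    """Map break fractions to stick pieces (the simplex when ``u1 = 1``).

    Returns ``(x, u)`` where ``x[j]`` is the piece for transcript ``j+1``
    and ``u`` holds the per-node intermediate values.
    """
    y = np.asarray(y, dtype=float)
    n = tree.n
    if y.shape != (n - 1,):
        raise ValueError(f"y must have length n-1 = {n - 1}")
    if u1 <= 0:
        raise ValueError("u1 must be positive")
    if n > 1 and ((y <= 0.0).any() or (y >= 1.0).any()):
        raise ValueError("break fractions must lie strictly in (0, 1)")
    u = _intermediate_forward(tree, y, u1)
    x = np.empty(n)
    x[tree._perm0] = u[n - 1 :]
    return x, u


def ptt_inverse(tree: PolyaTree, x: np.ndarray):
    """Recover break fractions from stick pieces (bottom-up pass).

    Returns ``(y, u)``; ``u1 = u[0]`` is the total length ``sum(x)``.
    """
    x = np.asarray(x, dtype=float)
    n = tree.n
    if x.shape != (n,):
        raise ValueError(f"x must have length n = {n}")
    if (x <= 0).any():
        raise ValueError("x must be strictly positive")
    u = np.empty(2 * n - 1)
    u[n - 1 :] = x[tree._perm0]
    y = np.empty(n - 1)
    l0, r0 = tree._left0, tree._right0
    for i in range(n - 2, -1, -1):
        ul = u[l0[i]]
        ui = ul + u[r0[i]]
        u[i] = ui
        y[i] = ul / ui
    return y, u


def ptt_log_abs_det_jacobian(u: np.ndarray, n: int) -> float:
    """Log |det J| of the general map ``(u1, y) -> x``.

    Equals the sum of the log intermediate values over the internal
    nodes ``1 … n-1`` (the root's ``u1`` included).
    """
    if n == 1:
        return 0.0
    return float(np.sum(np.log(u[: n - 1])))


def backprop_breaks(
    tree: PolyaTree,
    u: np.ndarray,
    y: np.ndarray,
    grad_x: np.ndarray,
    jacobian_term: bool = False,
) -> np.ndarray:
    """Gradient wrt the break fractions of ``f(x(y)) [+ log|det J|(y)]``.

    ``grad_x`` is df/dx.  Reverse sweep of the forward recursion: with
    ``g_i = df/du_i``, an internal node receives
    ``g_i = y_i g_left + (1-y_i) g_right (+ 1/u_i)`` and contributes
    ``df/dy_i = u_i (g_left - g_right)``.  O(n).
    """
    n = tree.n
    g = np.empty(2 * n - 1)
    g[n - 1 :] = grad_x[tree._perm0]
    dy = np.empty(n - 1)
    l0, r0 = tree._left0, tree._right0
    for i in range(n - 2, -1, -1):
        gl, gr = g[l0[i]], g[r0[i]]
        dy[i] = u[i] * (gl - gr)
        gi = y[i] * gl + (1.0 - y[i]) * gr
        if jacobian_term and i > 0:
            gi += 1.0 / u[i]
        g[i] = gi
    return dy


# ----------------------------------------------------------------------
# HierarchicalBeta


def subtree_alpha_sums(tree: PolyaTree, alpha: np.ndarray) -> np.ndarray:
    """Per-node sums of leaf intensities (bottom-up)."""
    n = tree.n
    a = np.empty(2 * n - 1)
    a[n - 1 :] = alpha[tree._perm0]
    l0, r0 = tree._left0, tree._right0
    for i in range(n - 2, -1, -1):
        a[i] = a[l0[i]] + a[r0[i]]
    return a


def hierarchical_beta_sample(
    tree: PolyaTree, alpha: np.ndarray, count: int, seed: int
) -> np.ndarray:
    """Draw from HierarchicalBeta(tree, alpha) — i.e. Dirichlet(alpha).

    Each break ``y_i`` is Beta(A_left(i), A_right(i)) where ``A_c`` sums
    ``alpha`` over the leaves below child ``c``; pushing the breaks through
    the transformation yields Dirichlet(alpha) draws for *any* topology.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (tree.n,) or (alpha <= 0).any():
        raise ValueError("alpha must be positive with length n")
    rng = np.random.default_rng(seed)
    n = tree.n
    if n == 1:
        return np.ones((count, 1))
    a = subtree_alpha_sums(tree, alpha)
    a_l = a[tree._left0]
    a_r = a[tree._right0]
    ys = rng.beta(a_l, a_r, size=(count, n - 1))
    # vectorized forward pass across draws
    u = np.empty((count, 2 * n - 1))
    u[:, 0] = 1.0
    l0, r0 = tree._left0, tree._right0
    for i in range(n - 1):
        u[:, l0[i]] = ys[:, i] * u[:, i]
        u[:, r0[i]] = (1.0 - ys[:, i]) * u[:, i]
    x = np.empty((count, n))
    x[:, tree._perm0] = u[:, n - 1 :]
    return x
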