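"""Heuristics for choosing a Pólya tree topology.

The quality of the fitted approximation depends strongly on the tree.
Because sparse mixture likelihoods exhibit sub-compositional independence
(isoform mixtures at loci sharing no reads are independent), a good tree
places transcripts that share reads under low common ancestors.  The
greedy Jaccard agglomeration below does exactly that; sequential
(caterpillar) and uniformly random topologies serve as baselines.
"""

from __future__ import annotations

import numpy as np

from .tree import PolyaTree

__all__ = ["compat_sets", "jaccard_cluster_tree", "baseline_tree"]


def compat_sets(compat) -> list[set[int]]:
    """Per-transcript sets of compatible row indices (1-based reads)."""
    csc = compat.matrix.tocsc()
    return [
        set((csc.indices[csc.indptr[j] : csc.indptr[j + 1]] + 1).tolist())
        for j in range(compat.n)
    ]


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    inter = len(a & b)
    if inter == 0:
        return 0.0
    return inter / (len(a) + len(b) - inter)


def jaccard_cluster_tree(sets: list[set[int]], seed: int = 0) -> PolyaTree:
    """Greedy agglomeration by maximal Jaccard index of read sets.

    Clusters are repeatedly merged choosing the pair of active clusters
    with the largest Jaccard index of their (unioned) read sets.  Ties are
    broken deterministically in favour of the lexicographically smallest
    (min transcript index, max transcript index) pair, and zero-similarity
    pairs are merged only after all positive-similarity merges are
    exhausted, in transcript-index order (producing a left-deep remainder).
    Candidate pairs are restricted to clusters sharing at least one read —
    cross-group pairs have Jaccard 0, so the restriction is exact.

    ``seed`` is accepted for interface symmetry; the algorithm is
    deterministic.
    """
    n = len(sets)
    if n == 0:
        raise ValueError("need at least one transcript")
    if n == 1:
        return PolyaTree.from_arbitrary(0, {}, {}, {0: 1})

    reads: dict[int, set] = {j: set(sets[j]) for j in range(n)}
    key = {j: j for j in range(n)}  # min transcript index in cluster
    node = {j: j for j in range(n)}  # builder node ids: leaves are 0..n-1
    leaf_label = {j: j + 1 for j in range(n)}
    left_child: dict[int, int] = {}
    right_child: dict[int, int] = {}
    next_internal = n  # transient ids; renumbered at the end

    # inverted index read -> active cluster ids
    by_read: dict[int, set[int]] = {}
    for j in range(n):
        for r in reads[j]:
            by_read.setdefault(r, set()).add(j)

    sim: dict[tuple[int, int], float] = {}
    for members in by_read.values():
        mm = sorted(members)
        for ai in range(len(mm)):
            for bi in range(ai + 1, len(mm)):
                pair = (mm[ai], mm[bi])
                if pair not in sim:
                    sim[pair] = _jaccard(reads[pair[0]], reads[pair[1]])

    active = set(range(n))
    next_cluster = n

    def merge(a: int, b: int) -> int:
        nonlocal next_internal, next_cluster
        if key[b] < key[a]:
            a, b = b, a
        cid = next_cluster
        next_cluster += 1
        nid = next_internal
        next_internal += 1
        left_child[nid] = node[a]
        right_child[nid] = node[b]
        node[cid] = nid
        key[cid] = key[a]
        reads[cid] = reads[a] | reads[b]
        for r in reads[cid]:
            members = by_read[r]
            members.discard(a)
            members.discard(b)
            members.add(cid)
        active.discard(a)
        active.discard(b)
        active.add(cid)
        del reads[a], reads[b]
        return cid

    while len(active) > 1 and sim:
        best = min(
            sim.items(),
            key=lambda kv: (-kv[1], min(key[kv[0][0]], key[kv[0][1]]), max(key[kv[0][0]], key[kv[0][1]])),
        )
        (a, b), j_ab = best
        if j_ab <= 0.0:
            break
        c = merge(a, b)
        sim = {p: v for p, v in sim.items() if a not in p and b not in p}
        neighbours = set()
        for r in reads[c]:
            neighbours |= by_read[r]
        neighbours.discard(c)
        for d in neighbours:
            pair = (min(c, d), max(c, d))
            sim[pair] = _jaccard(reads[c], reads[d])

    # zero-similarity remainder: left-deep merge in transcript-index order
    rest = sorted(active, key=lambda cid: key[cid])
    acc = rest[0]
    for b in rest[1:]:
        acc = merge(acc, b)

    root = node[acc]
    return PolyaTree.from_arbitrary(root, left_child, right_child, leaf_label)


def _remy_topology(n: int, rng: np.random.Generator):
    """Uniform full binary tree with n leaves (Rémy's algorithm)."""
    # node ids; leaf ids carry labels assigned afterwards
    left: dict[int, int] = {}
    right: dict[int, int] = {}
    leaves = [0]
    nodes = [0]
    root = 0
    parent: dict[int, tuple[int, bool]] = {}
    nxt = 1
    for _ in range(n - 1):
        pick = nodes[rng.integers(len(nodes))]
        internal, leaf = nxt, nxt + 1
        nxt += 2
        side_left = bool(rng.integers(2))
        if pick == root:
            root = internal
        else:
            p, was_left = parent[pick]
            if was_left:
                left[p] = internal
            else:
                right[p] = internal
            parent[internal] = (p, was_left)
        if side_left:
            left[internal], right[internal] = leaf, pick
        else:
            left[internal], right[internal] = pick, leaf
        parent[pick] = (internal, not side_left)
        parent[leaf] = (internal, side_left)
        leaves.append(leaf)
        nodes.extend([internal, leaf])
    return root, left, right, leaves


def baseline_tree(n: int, kind: str, seed: int = 0) -> PolyaTree:
    """Sequential (caterpillar, mlr-equivalent) or uniformly random tree."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if kind == "sequential":
        if n == 1:
            return PolyaTree.from_arbitrary(0, {}, {}, {0: 1})
        # internal node i splits off transcript i from the remainder
        left_child: dict[int, int] = {}
        right_child: dict[int, int] = {}
        leaf_label: dict[int, int] = {}
        # ids: internal 0..n-2, leaves 100+t
        for i in range(n - 1):
            left_child[i] = 10 ** 9 + i + 1
            leaf_label[10 ** 9 + i + 1] = i + 1
            right_child[i] = i + 1 if i < n - 2 else 10 ** 9 + n
        leaf_label[10 ** 9 + n] = n
        return PolyaTree.from_arbitrary(0, left_child, right_child, leaf_label)
    if kind == "random":
        rng = np.random.default_rng(seed)
        root, left, right, leaves = _remy_topology(n, rng)
        labels = rng.permutation(n) + 1
        leaf_label = {leaf: int(labels[k]) for k, leaf in enumerate(leaves)}
        return PolyaTree.from_arbitrary(root, left, right, leaf_label)
    raise ValueError(f"unknown tree kind: {kind!r}")
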