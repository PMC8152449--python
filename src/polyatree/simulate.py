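"""Synthetic transcriptomes and read-compatibility matrices.

Reads are generated directly as equivalence classes: distinct
compatibility rows with integer multiplicities.  This emulates the
structure the method actually consumes — a sparse mixture in which most
reads are compatible with a handful of isoforms of one gene — without
simulating sequences.  Genes partition transcripts; a read from
transcript ``t`` is either unambiguous (a unit indicator row) or drawn
from one of a few fixed per-transcript "templates" whose support is a
random subset of the gene's isoforms with relative conditional
probabilities in [0.2, 1].  Template emission probabilities are
normalized per transcript so that the compatibility entries are exactly
the conditional read-class probabilities of the generative model: the
normalized likelihood then genuinely concentrates around ``truth_x``.

An optional paralog-block mode merges pairs of genes into one ambiguity
block (cross-gene shared reads) to stress tree-building heuristics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .compat import ReadCompat

__all__ = [
    "SyntheticExperiment",
    "simulate_transcriptome",
    "simulate_two_condition",
    "simulate_coexpression_cohort",
]


@dataclass
class SyntheticExperiment:
    """Ground truth plus per-sample compatibility matrices."""

    truth_x: np.ndarray  # (samples, n) relative expression
    compat: list[ReadCompat]
    gene_map: list[str]  # transcript -> gene label
    transcript_ids: list[str]
    effective_lengths: np.ndarray
    design: list[str]  # per-sample condition labels
    true_effects: np.ndarray  # per-transcript log2 effects
    seed: int
    corr_pairs: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.gene_map)


class _Annotation:
    """Fixed gene structure and read-class templates shared across samples."""

    def __init__(self, n_genes, isoforms_per_gene, ambiguity, paralog_blocks, rng):
        if np.isscalar(isoforms_per_gene):
            sizes = np.full(n_genes, int(isoforms_per_gene))
        else:
            lo, hi = isoforms_per_gene
            sizes = rng.integers(lo, hi + 1, size=n_genes)
        self.gene_map: list[str] = []
        blocks: list[list[int]] = []  # ambiguity blocks (gene or paralog pair)
        t = 0
        members: list[list[int]] = []
        for g in range(n_genes):
            ids = list(range(t, t + int(sizes[g])))
            t += int(sizes[g])
            self.gene_map += [f"g{g + 1}"] * len(ids)
            members.append(ids)
        self.n = t
        merged = set()
        for b in range(paralog_blocks):
            if 2 * b + 1 >= n_genes:
                break
            blocks.append(members[2 * b] + members[2 * b + 1])
            merged.update((2 * b, 2 * b + 1))
        blocks += [members[g] for g in range(n_genes) if g not in merged]
        self.ambiguity = float(ambiguity)
        # templates: per transcript in a multi-isoform block, a couple of
        # ambiguous read classes supported on a subset of the block
        self.templates: list[tuple[np.ndarray, np.ndarray]] = []  # (cols, pvals)
        self.t_templates: dict[int, list[int]] = {j: [] for j in range(self.n)}
        for block in blocks:
            if len(block) < 2:
                continue
            for j in block:
                for _ in range(2):
                    size = rng.integers(2, len(block) + 1)
                    others = [k for k in block if k != j]
                    rng.shuffle(others)
                    cols = np.array(sorted([j] + others[: size - 1]))
                    pvals = rng.uniform(0.2, 1.0, size=cols.shape[0])
                    idx = len(self.templates)
                    self.templates.append((cols, pvals))
                    for k in cols:
                        self.t_templates[int(k)].append(idx)
        # per-transcript emission distribution over its ambiguous templates,
        # proportional to the template's conditional probability for it
        self.emit: dict[int, np.ndarray] = {}
        for j, tids in self.t_templates.items():
            if tids:
                w = np.array([self.templates[i][1][list(self.templates[i][0]).index(j)]
                              for i in tids])
                self.emit[j] = w / w.sum()

    def sample_compat(self, truth_x: np.ndarray, depth: int, rng) -> ReadCompat:
        counts = rng.multinomial(depth, truth_x)
        unamb = np.zeros(self.n, dtype=np.int64)
        tmpl_w = np.zeros(len(self.templates), dtype=np.int64)
        for j in range(self.n):
            c = int(counts[j])
            if c == 0:
                continue
            tids = self.t_templates[j]
            if not tids:
                unamb[j] += c
                continue
            c_amb = rng.binomial(c, self.ambiguity)
            unamb[j] += c - c_amb
            if c_amb:
                split = rng.multinomial(c_amb, self.emit[j])
                for tid, ck in zip(tids, split):
                    tmpl_w[tid] += ck
        rows, cols, data, weights = [], [], [], []
        r = 0
        for j in np.flatnonzero(unamb):
            rows.append(r)
            cols.append(j)
            data.append(1.0)
            weights.append(int(unamb[j]))
            r += 1
        for tid in np.flatnonzero(tmpl_w):
            tc, tp = self.templates[tid]
            rows += [r] * len(tc)
            cols += tc.tolist()
            data += tp.tolist()
            weights.append(int(tmpl_w[tid]))
            r += 1
        mat = sp.csr_matrix(
            (data, (rows, cols)), shape=(r, self.n), dtype=np.float64
        )
        return ReadCompat(mat, np.asarray(weights))


def _base_expression(n: int, rng, log_sd: float = 2.0) -> np.ndarray:
    x = np.exp(rng.normal(0.0, log_sd, size=n))
    return x / x.sum()


def _finalize(ann: _Annotation, rng) -> tuple[list[str], np.ndarray]:
    ids = [f"t{j + 1}" for j in range(ann.n)]
    eff_len = np.exp(rng.normal(np.log(1500.0), 0.4, size=ann.n))
    return ids, eff_len


def simulate_transcriptome(
    n_genes: int = 50,
    isoforms_per_gene=(2, 4),
    depth: int = 20000,
    ambiguity: float = 0.5,
    seed: int = 0,
    paralog_blocks: int = 0,
) -> SyntheticExperiment:
    """One sample with known expression and controlled read ambiguity.

    ``ambiguity`` is the expected fraction of reads landing in
    multi-transcript equivalence classes (exact when every gene has at
    least two isoforms).  ``ambiguity=0`` gives purely indicator rows, the
    sub-compositionally independent regime where the normalized
    likelihood is exactly Dirichlet(1 + counts).
    """
    rng = np.random.default_rng(seed)
    ann = _Annotation(n_genes, isoforms_per_gene, ambiguity, paralog_blocks, rng)
    truth = _base_expression(ann.n, rng)
    compat = ann.sample_compat(truth, depth, rng)
    ids, eff = _finalize(ann, rng)
    return SyntheticExperiment(
        truth_x=truth[None, :],
        compat=[compat],
        gene_map=ann.gene_map,
        transcript_ids=ids,
        effective_lengths=eff,
        design=["a"],
        true_effects=np.zeros(ann.n),
        seed=seed,
    )


def simulate_two_condition(
    n_genes: int = 50,
    isoforms_per_gene=(2, 4),
    depth: int = 20000,
    ambiguity: float = 0.5,
    n_per_group: int = 3,
    frac_de: float = 0.1,
    effect_bits: float = 1.0,
    biovar_sd: float = 0.2,
    seed: int = 0,
) -> SyntheticExperiment:
    """Two-condition experiment with known log2 effects.

    A fraction ``frac_de`` of transcripts get a ±``effect_bits`` log2
    shift in condition "b"; all samples add independent Normal(0,
    ``biovar_sd``) biological noise on log2 expression.  As in standard
    differential-expression benchmarks, effects are assigned among
    transcripts that are actually expressed (expected count >= ~10 at
    the requested depth); a fold change on a transcript producing no
    reads is unobservable by construction.
    """
    rng = np.random.default_rng(seed)
    ann = _Annotation(n_genes, isoforms_per_gene, ambiguity, 0, rng)
    base = _base_expression(ann.n, rng)
    n_de = int(round(frac_de * ann.n))
    eligible = np.flatnonzero(base * depth >= 10.0)
    if len(eligible) < n_de:
        eligible = np.argsort(base)[-n_de:]
    de_idx = rng.choice(eligible, size=n_de, replace=False)
    effects = np.zeros(ann.n)
    effects[de_idx] = effect_bits * rng.choice([-1.0, 1.0], size=n_de)
    design = ["a"] * n_per_group + ["b"] * n_per_group
    truth, compat = [], []
    for cond in design:
        l2 = np.log2(base) + (effects if cond == "b" else 0.0)
        l2 = l2 + rng.normal(0.0, biovar_sd, size=ann.n)
        x = 2.0 ** l2
        x /= x.sum()
        truth.append(x)
        compat.append(ann.sample_compat(x, depth, rng))
    ids, eff = _finalize(ann, rng)
    return SyntheticExperiment(
        truth_x=np.array(truth),
        compat=compat,
        gene_map=ann.gene_map,
        transcript_ids=ids,
        effective_lengths=eff,
        design=design,
        true_effects=effects,
        seed=seed,
    )


def simulate_coexpression_cohort(
    n_genes: int = 40,
    isoforms_per_gene: int = 3,
    n_samples: int = 12,
    n_corr_pairs: int = 10,
    rho: float = 0.9,
    depth: int = 2000,
    ambiguity: float = 0.7,
    biovar_sd: float = 1.0,
    seed: int = 0,
) -> SyntheticExperiment:
    """Cohort with known co-regulated transcript pairs.

    Each correlated pair (members in different genes) shares a latent
    per-sample factor: log2 expression of both members moves with the
    factor with weight sqrt(rho), plus independent noise with weight
    sqrt(1-rho), giving correlation ``rho`` on the log scale.  All other
    transcripts fluctuate independently with sd ``biovar_sd`` (log2).
    """
    rng = np.random.default_rng(seed)
    ann = _Annotation(n_genes, isoforms_per_gene, ambiguity, 0, rng)
    base = _base_expression(ann.n, rng)
    # pick pair members from distinct genes, no transcript reused
    order = rng.permutation(ann.n)
    pairs: list[tuple[int, int]] = []
    used: set[int] = set()
    for j in order:
        if len(pairs) == n_corr_pairs:
            break
        if j in used:
            continue
        for k in order:
            if k in used or k == j or ann.gene_map[k] == ann.gene_map[j]:
                continue
            pairs.append((int(j), int(k)))
            used.update((int(j), int(k)))
            break
    truth, compat = [], []
    for _ in range(n_samples):
        eps = rng.normal(0.0, 1.0, size=ann.n)
        l2 = np.log2(base) + biovar_sd * eps
        for (j, k) in pairs:
            f = rng.normal()
            l2[j] = np.log2(base[j]) + biovar_sd * (
                np.sqrt(rho) * f + np.sqrt(1 - rho) * eps[j]
            )
            l2[k] = np.log2(base[k]) + biovar_sd * (
                np.sqrt(rho) * f + np.sqrt(1 - rho) * eps[k]
            )
        x = 2.0 ** l2
        x /= x.sum()
        truth.append(x)
        compat.append(ann.sample_compat(x, depth, rng))
    ids, eff = _finalize(ann, rng)
    return SyntheticExperiment(
        truth_x=np.array(truth),
        compat=compat,
        gene_map=ann.gene_map,
        transcript_ids=ids,
        effective_lengths=eff,
        design=["a"] * n_samples,
        true_effects=np.zeros(ann.n),
        seed=seed,
        corr_pairs=pairs,
    )
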