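"""Fit the variational approximation to the normalized likelihood.

The approximation family is a mean-field base distribution on the break
fractions pushed through a Pólya tree transformation.  Fitting maximizes
a Monte-Carlo ELBO

    E_q[ log P(r|x) ] + H(q)
        = E_z[ log P(r|x(z, phi)) + log|det J|(z, phi) - log q_y(y(z, phi)) ]

via the reparameterization trick with analytic gradients: the likelihood
term is backpropagated through the sparse mixture and the tree (O(nnz +
n) per draw), and the entropy pieces use closed forms where available.
Maximizing the ELBO is equivalent to minimizing KL(q || normalized
likelihood) up to the unknown normalizer, so the likelihood never needs
to be normalized explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import h5py
import numpy as np

from . import basedist
from .basedist import BaseParams
from .compat import ReadCompat, log_likelihood, log_likelihood_grad, ml_estimate
from .tree import (
    PolyaTree,
    backprop_breaks,
    ptt_forward,
    ptt_inverse,
    ptt_log_abs_det_jacobian,
)
from .tree_builder import baseline_tree, compat_sets, jaccard_cluster_tree

__all__ = [
    "FitConfig",
    "ApproxLikelihood",
    "elbo_estimate",
    "fit_approximation",
    "approx_sample",
    "approx_log_density",
    "save_approx",
    "load_approx",
]

SCHEMA_VERSION = 1


@dataclass
class FitConfig:
    """Optimizer and model configuration for one approximation fit."""

    steps: int = 5000
    mc_samples_per_step: int = 4
    learning_rate: float = 0.05
    seed: int = 0
    family: str = "logit_skew_normal"
    tree_method: str = "jaccard"
    lr_decay: bool = True  # cosine decay to zero over the run
    average_frac: float = 0.25  # Polyak-average the final fraction of steps

    def __post_init__(self):
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class ApproxLikelihood:
    """A fitted, serializable stand-in for the likelihood function."""

    tree: PolyaTree
    base: BaseParams
    n: int
    transcript_ids: list[str] = field(default_factory=list)
    effective_lengths: np.ndarray | None = None
    fit_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.tree.n != self.n:
            raise ValueError("tree leaf count must equal n")
        if self.n > 1 and self.base.dim != self.n - 1:
            raise ValueError("base distribution must have n-1 coordinates")
        if not self.transcript_ids:
            self.transcript_ids = [f"t{j + 1}" for j in range(self.n)]
        if self.effective_lengths is None:
            self.effective_lengths = np.full(self.n, 1000.0)
        self.effective_lengths = np.asarray(self.effective_lengths, dtype=float)
        if (self.effective_lengths <= 0).any():
            raise ValueError("effective lengths must be positive")


# ----------------------------------------------------------------------


def elbo_estimate(
    compat: ReadCompat, tree: PolyaTree, base: BaseParams, base_draws: np.ndarray
) -> float:
    """Monte-Carlo ELBO from pre-drawn base variables."""
    draws = np.atleast_2d(np.asarray(base_draws, dtype=float))
    vals = np.empty(draws.shape[0])
    for k, z in enumerate(draws):
        y = basedist.reparam_sample(base, z)
        x, u = ptt_forward(tree, y)
        vals[k] = (
            log_likelihood(compat, x)
            + ptt_log_abs_det_jacobian(u, tree.n)
            - basedist.log_density(base, y)
        )
    return float(vals.mean())


def build_tree(compat: ReadCompat, method: str, seed: int = 0) -> PolyaTree:
    if method == "jaccard":
        return jaccard_cluster_tree(compat_sets(compat), seed=seed)
    return baseline_tree(compat.n, method, seed=seed)


def _init_params(compat: ReadCompat, tree: PolyaTree, family: str) -> dict[str, np.ndarray]:
    """Start near the likelihood mode: breaks from the EM estimate."""
    x0 = ml_estimate(compat)
    x0 = 0.95 * x0 + 0.05 / compat.n  # soften boundary components
    y0, _ = ptt_inverse(tree, x0 / x0.sum())
    y0 = np.clip(y0, 1e-4, 1.0 - 1e-4)
    if family == "kumaraswamy":
        # match the median: median(a, b) = (1 - 2**(-1/b))**(1/a)
        b = np.full(tree.n - 1, 2.0)
        a = np.clip(np.log(1.0 - 2.0 ** (-1.0 / b)) / np.log(y0), 5e-2, 5e2)
        return {"log_a": np.log(a), "log_b": np.log(b)}
    mu = np.log(y0) - np.log1p(-y0)
    out = {"mu": mu, "log_sigma": np.full(tree.n - 1, np.log(0.1))}
    if family == "logit_skew_normal":
        out["skew"] = np.zeros(tree.n - 1)
    return out


def _params_from_unconstrained(family: str, theta: dict[str, np.ndarray]) -> BaseParams:
    if family == "kumaraswamy":
        return BaseParams(family, kum_a=np.exp(theta["log_a"]), kum_b=np.exp(theta["log_b"]))
    if family == "logit_normal":
        return BaseParams(family, mu=theta["mu"], sigma=np.exp(theta["log_sigma"]))
    return BaseParams(
        family, mu=theta["mu"], sigma=np.exp(theta["log_sigma"]), skew=theta["skew"]
    )


def fit_approximation(
    compat: ReadCompat,
    config: FitConfig | None = None,
    transcript_ids: list[str] | None = None,
    effective_lengths: np.ndarray | None = None,
    tree: PolyaTree | None = None,
) -> ApproxLikelihood:
    """Build a tree, then run Adam ascent on the reparameterized ELBO."""
    config = config or FitConfig()
    n = compat.n
    if tree is None:
        tree = build_tree(compat, config.tree_method, seed=config.seed)
    if n == 1:
        base = BaseParams(config.family, mu=np.empty(0), sigma=np.empty(0),
                          skew=np.empty(0)) if config.family != "kumaraswamy" else BaseParams(
            config.family, kum_a=np.empty(0), kum_b=np.empty(0))
        return ApproxLikelihood(tree, base, n, transcript_ids or [], effective_lengths,
                                {"elbo": 0.0, "seed": config.seed})

    rng = np.random.default_rng(config.seed)
    theta = _init_params(compat, tree, config.family)
    names = sorted(theta)
    adam_m = {k: np.zeros_like(v) for k, v in theta.items()}
    adam_v = {k: np.zeros_like(v) for k, v in theta.items()}
    avg = {k: np.zeros_like(v) for k, v in theta.items()}
    n_avg = 0
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    smoothed = None
    for step in range(1, config.steps + 1):
        params = _params_from_unconstrained(config.family, theta)
        grad = {k: np.zeros_like(v) for k, v in theta.items()}
        value = 0.0
        zs = basedist.base_draws(config.family, (config.mc_samples_per_step, n - 1), rng)
        for z in zs:
            y, dy, path_extra, direct, neg_logq = basedist.fit_pieces(params, z)
            x, u = ptt_forward(tree, y)
            gA_x = log_likelihood_grad(compat, x)
            dA_dy = backprop_breaks(tree, u, y, gA_x, jacobian_term=True)
            G = dA_dy + path_extra
            for k in names:
                grad[k] += (G * dy[k] + direct[k]) / len(zs)
            value += (
                log_likelihood(compat, x)
                + ptt_log_abs_det_jacobian(u, tree.n)
                + float(neg_logq.sum())
            ) / len(zs)
        if not np.isfinite(value) or any(not np.isfinite(g).all() for g in grad.values()):
            raise RuntimeError(f"ELBO optimization diverged at step {step}")
        smoothed = value if smoothed is None else 0.95 * smoothed + 0.05 * value
        if step == 1:
            first_smoothed = value
        bc1 = 1.0 - beta1 ** step
        bc2 = 1.0 - beta2 ** step
        lr = config.learning_rate
        if config.lr_decay:
            lr *= 0.5 * (1.0 + np.cos(np.pi * step / config.steps))
        for k in names:
            adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * grad[k]
            adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * grad[k] ** 2
            theta[k] = theta[k] + lr * (adam_m[k] / bc1) / (
                np.sqrt(adam_v[k] / bc2) + eps
            )
        if step > config.steps * (1.0 - config.average_frac):
            for k in names:
                avg[k] += theta[k]
            n_avg += 1

    if n_avg:
        theta = {k: avg[k] / n_avg for k in names}
    base = _params_from_unconstrained(config.family, theta)
    meta = {
        "elbo": float(smoothed),
        "elbo_first": float(first_smoothed),
        "seed": config.seed,
        "config": asdict(config),
    }
    return ApproxLikelihood(tree, base, n, transcript_ids or [], effective_lengths, meta)


# ----------------------------------------------------------------------


def approx_sample(approx: ApproxLikelihood, count: int, seed: int = 0) -> np.ndarray:
    """Draw ``count`` expression vectors from the approximation, O(n) each."""
    n = approx.n
    if n == 1:
        return np.ones((count, 1))
    rng = np.random.default_rng(seed)
    z = basedist.base_draws(approx.base.family, (count, n - 1), rng)
    ys = basedist.reparam_sample(approx.base, z)
    tree = approx.tree
    u = np.empty((count, 2 * n - 1))
    u[:, 0] = 1.0
    l0, r0 = tree._left0, tree._right0
    for i in range(n - 1):
        u[:, l0[i]] = ys[:, i] * u[:, i]
        u[:, r0[i]] = (1.0 - ys[:, i]) * u[:, i]
    x = np.empty((count, n))
    x[:, tree._perm0] = u[:, n - 1 :]
    return x


def approx_log_density(approx: ApproxLikelihood, x: np.ndarray) -> float:
    """log q(x): base density at the inverse breaks minus the log-Jacobian."""
    if approx.n == 1:
        return 0.0
    y, u = ptt_inverse(approx.tree, x)
    return float(
        basedist.log_density(approx.base, y) - ptt_log_abs_det_jacobian(u, approx.n)
    )


# ----------------------------------------------------------------------
# HDF5 container


def save_approx(approx: ApproxLikelihood, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        g = f.create_group("tree")
        g.create_dataset("left", data=approx.tree.left)
        g.create_dataset("right", data=approx.tree.right)
        g.create_dataset("leaf_to_transcript", data=approx.tree.leaf_to_transcript)
        g = f.create_group("base")
        g.attrs["family"] = approx.base.family
        for name in ("mu", "sigma", "skew", "kum_a", "kum_b"):
            v = getattr(approx.base, name)
            if v is not None:
                g.create_dataset(name, data=np.asarray(v, dtype=np.float64))
        g = f.create_group("meta")
        g.create_dataset(
            "transcript_ids",
            data=np.array(approx.transcript_ids, dtype=h5py.string_dtype()),
        )
        g.create_dataset("effective_lengths", data=approx.effective_lengths)
        g.attrs["seed"] = int(approx.fit_meta.get("seed", 0))
        g.attrs["objective"] = float(approx.fit_meta.get("elbo", np.nan))
        g.attrs["fit_meta_json"] = json.dumps(approx.fit_meta)


def load_approx(path) -> ApproxLikelihood:
    with h5py.File(path, "r") as f:
        t = f["tree"]
        left = t["left"][...]
        tree = PolyaTree(
            n=left.shape[0] + 1,
            left=left,
            right=t["right"][...],
            leaf_to_transcript=t["leaf_to_transcript"][...],
        )
        b = f["base"]
        kw = {name: b[name][...] for name in ("mu", "sigma", "skew", "kum_a", "kum_b") if name in b}
        base = BaseParams(b.attrs["family"], **kw)
        m = f["meta"]
        fit_meta = json.loads(m.attrs.get("fit_meta_json", "{}"))
        return ApproxLikelihood(
            tree=tree,
            base=base,
            n=tree.n,
            transcript_ids=[s.decode() if isinstance(s, bytes) else str(s)
                            for s in m["transcript_ids"][...]],
            effective_lengths=m["effective_lengths"][...],
            fit_meta=fit_meta,
        )
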