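"""Goodness-of-fit and convergence protocols.

The approximation is judged by comparing draws from it with draws from
the Gibbs sampler (the exact normalized likelihood): a per-transcript
Wilcoxon signed-rank test on paired draws should produce near-uniform
p-values if the fit is good, and the error it induces in minimum log2
fold-change estimates should be near zero.  Split-chain potential scale
reduction (R-hat) checks that the Gibbs reference itself has converged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .compat import GibbsRun
from .inference import min_log2_fc

__all__ = ["GofReport", "wilcoxon_gof", "rhat", "min_lfc_error"]


@dataclass
class GofReport:
    """Per-transcript Wilcoxon p-values with summary statistics."""

    p_values: np.ndarray
    quantiles: dict[str, float]
    frac_below_01: float

    @property
    def median_p(self) -> float:
        return self.quantiles["50"]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"p_value": self.p_values})


def wilcoxon_gof(exact_draws: np.ndarray, approx_draws: np.ndarray) -> GofReport:
    """Per-transcript signed-rank comparison of exact vs approximate draws.

    Draws are paired by index; zero differences are dropped (the standard
    convention), and a transcript whose differences are all zero gets
    p = 1.  A perfect approximation yields uniform p-values.
    """
    exact = np.asarray(exact_draws, dtype=float)
    approx = np.asarray(approx_draws, dtype=float)
    if exact.shape != approx.shape:
        raise ValueError("draw sets must have identical shapes")
    n = exact.shape[1]
    pvals = np.empty(n)
    diffs = exact - approx
    for j in range(n):
        d = diffs[:, j]
        d = d[d != 0.0]
        if d.size == 0:
            pvals[j] = 1.0
            continue
        pvals[j] = stats.wilcoxon(d, zero_method="wilcox", method="approx").pvalue
    qs = np.percentile(pvals, [1, 25, 50, 75, 99])
    return GofReport(
        p_values=pvals,
        quantiles={k: float(v) for k, v in zip(("1", "25", "50", "75", "99"), qs)},
        frac_below_01=float(np.mean(pvals < 0.01)),
    )


def rhat(run: GibbsRun, return_flags: bool = False):
    """Split-chain potential scale reduction, per transcript.

    Each chain is halved, within-chain variance W and between-chain
    variance B compared; values near 1 indicate convergence.  Transcripts
    with zero within-chain variance (constant chains) are reported as 1
    and flagged.
    """
    draws = run.draws
    if draws.shape[0] < 2 or draws.shape[1] < 4:
        raise ValueError("need at least 2 chains with at least 4 draws each")
    half = draws.shape[1] // 2
    split = np.concatenate([draws[:, :half], draws[:, half : 2 * half]], axis=0)
    nchains, ndraw, n = split.shape
    chain_means = split.mean(axis=1)
    within = split.var(axis=1, ddof=1).mean(axis=0)
    between = ndraw * chain_means.var(axis=0, ddof=1)
    flags = within <= 0.0
    w = np.where(flags, 1.0, within)
    var_plus = (ndraw - 1) / ndraw * w + between / (ndraw * 1.0)
    r = np.sqrt(var_plus / w)
    r[flags] = 1.0
    if return_flags:
        return r, flags
    return r


def min_lfc_error(
    exact_a: np.ndarray,
    exact_b: np.ndarray,
    approx_a: np.ndarray,
    approx_b: np.ndarray,
) -> np.ndarray:
    """Approximation-induced error in minimum log2 fold change.

    Positive values mean the approximation overestimates the effect
    (false-positive direction), negative underestimates it.
    """
    exact = min_log2_fc(exact_a, exact_b)
    approx = min_log2_fc(approx_a, approx_b)
    return approx.delta - exact.delta
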