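"""Readers and writers for the on-disk interchange formats.

Compatibility matrices travel as MatrixMarket coordinate files (1-based
indices per the MTX standard), row multiplicities as a 2-column TSV
(row, weight), and transcript metadata as a TSV with columns
``transcript_id``, ``gene_id``, ``effective_length``.  The fitted
approximation container is HDF5 (see :mod:`polyatree.fit`).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .compat import ReadCompat

__all__ = [
    "read_compat",
    "write_compat",
    "read_metadata",
    "write_metadata",
    "write_draws",
]

METADATA_COLUMNS = ["transcript_id", "gene_id", "effective_length"]


def write_compat(compat: ReadCompat, mtx_path, weights_path=None) -> None:
    scipy.io.mmwrite(str(mtx_path), compat.matrix.tocoo())
    if weights_path is not None:
        pd.DataFrame(
            {"row": np.arange(1, compat.m + 1), "weight": compat.weights}
        ).to_csv(weights_path, sep="\t", index=False)


def read_compat(mtx_path, weights_path=None) -> ReadCompat:
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except Exception as exc:  # surface the offending file, not a traceback
        raise ValueError(f"malformed MatrixMarket file {mtx_path}: {exc}") from exc
    weights = None
    if weights_path is not None and Path(weights_path).exists():
        wdf = pd.read_csv(weights_path, sep="\t")
        if "weight" not in wdf.columns:
            raise ValueError(f"{weights_path}: expected columns 'row', 'weight'")
        weights = wdf.sort_values("row")["weight"].to_numpy()
    return ReadCompat(sp.csr_matrix(mat), weights)


def write_metadata(path, transcript_ids, gene_ids, effective_lengths) -> None:
    pd.DataFrame(
        {
            "transcript_id": transcript_ids,
            "gene_id": gene_ids,
            "effective_length": effective_lengths,
        }
    ).to_csv(path, sep="\t", index=False)


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    if (df["effective_length"] <= 0).any():
        raise ValueError(f"{path}: effective_length must be positive")
    return df


def write_draws(path, draws: np.ndarray, transcript_ids) -> None:
    """Posterior draws as TSV: one row per draw, one column per transcript."""
    pd.DataFrame(draws, columns=list(transcript_ids)).to_csv(path, sep="\t", index=False)
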