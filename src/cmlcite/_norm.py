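"""Shared normalization helpers used across the pipeline stages."""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp


def to_dense(X) -> np.ndarray:
    """Return a dense float64 array view of a counts matrix."""
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=np.float64)
    return np.asarray(X, dtype=np.float64)


def library_sizes(X) -> np.ndarray:
    if sp.issparse(X):
        return np.asarray(X.sum(axis=1)).ravel().astype(np.float64)
    return np.asarray(X, dtype=np.float64).sum(axis=1)


def normalize_log(X, target_sum: float | None = None) -> tuple[np.ndarray, float]:
    """Library-size normalize cells to ``target_sum`` total counts, then log1p.

    ``target_sum`` defaults to the median library size of the matrix, the
    convention used throughout this pipeline. Cells with zero counts are left
    at zero. Returns the dense transformed matrix and the target sum used, so
    the same scaling can later be applied to query cells.
    """
    libs = library_sizes(X)
    if target_sum is None:
        nonzero = libs[libs > 0]
        target_sum = float(np.median(nonzero)) if nonzero.size else 1.0
    dense = to_dense(X)
    scale = np.divide(target_sum, libs, out=np.zeros_like(libs), where=libs > 0)
    return np.log1p(dense * scale[:, None]), target_sum


def zscore_columns(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score each column; constant columns map to zero.

    Returns (z, mean, std) with std set to 1 where the column is constant.
    """
    mean = M.mean(axis=0)
    std = M.std(axis=0)
    std_safe = np.where(std > 0, std, 1.0)
    return (M - mean) / std_safe, mean, std_safe
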