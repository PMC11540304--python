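"""Reference-based bulk expression deconvolution.

A signature matrix of cluster mean expression over cluster-specific marker
genes is built from labeled single-cell data; bulk profiles are then
decomposed by non-negative least squares and the coefficients normalized to
fractions summing to 1. The solver is constrained linear least squares — a
deliberately simple estimator sharing the input/output contract of
reference-based deconvolution tools: a genes x clusters signature in, a
samples x clusters fraction table out.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import ttest_ind

from ._norm import normalize_log
from .embed import marker_specificity

log = logging.getLogger(__name__)

MIN_CLUSTER_CELLS = 10


def build_signature_matrix(
    sc_counts,
    cluster_labels,
    n_markers_per_cluster: int = 50,
) -> pd.DataFrame:
    """Cluster mean expression over the union of top marker genes.

    Markers are ranked by the rank-based cluster-specificity statistic;
    means are of library-size normalized (linear-scale) expression.
    Clusters with fewer than 10 cells are excluded with a warning.
    """
    labels = pd.Series(np.asarray(cluster_labels), index=sc_counts.obs_names)
    sizes = labels.value_counts()
    small = sizes[sizes < MIN_CLUSTER_CELLS].index.tolist()
    if small:
        log.warning("build_signature_matrix: excluding small clusters %s", small)
        keep = ~labels.isin(small).to_numpy()
        sc_counts = sc_counts[keep]
        labels = labels[keep]
    if labels.nunique() < 2:
        raise ValueError("need at least 2 clusters of sufficient size")

    spec = marker_specificity(sc_counts, labels)
    if n_markers_per_cluster >= sc_counts.n_vars:
        log.warning("build_signature_matrix: n_markers_per_cluster >= gene "
                    "count, using the full gene set")
        marker_union = list(sc_counts.var_names)
    else:
        marker_union = sorted(
            set().union(
                *(
                    spec[c].sort_values(ascending=False)
                    .index[:n_markers_per_cluster]
                    for c in spec.columns
                )
            )
        )
    norm, _ = normalize_log(sc_counts.X)
    expr = np.expm1(norm)
    cols = sc_counts.var_names.get_indexer(marker_union)
    out = {}
    for c in sorted(labels.unique()):
        members = (labels == c).to_numpy()
        out[c] = expr[np.ix_(members, cols)].mean(axis=0)
    signature = pd.DataFrame(out, index=marker_union)
    signature = signature[(signature.sum(axis=1) > 0)]
    return signature


def _quantile_scale(columns: np.ndarray) -> np.ndarray:
    """Quantile-normalize columns onto their average sorted distribution."""
    order = np.argsort(columns, axis=0)
    ranks = np.empty_like(order)
    n = columns.shape[0]
    for j in range(columns.shape[1]):
        ranks[order[:, j], j] = np.arange(n)
    mean_sorted = np.sort(columns, axis=0).mean(axis=1)
    return mean_sorted[ranks]


def deconvolve(
    bulk: pd.DataFrame,
    signature: pd.DataFrame,
    scale: str | None = None,
) -> pd.DataFrame:
    """Estimate per-sample cluster fractions by non-negative least squares.

    ``bulk`` is samples x genes; ``signature`` genes x clusters. Genes
    missing from either side are dropped symmetrically (at least 50% of
    signature genes must remain). With ``scale="quantile"`` bulk and
    signature columns are jointly quantile-normalized before solving (for
    cross-platform bulk); the default solves on the given scales, so exact
    mixtures of signature columns are recovered exactly. Fractions are the
    NNLS coefficients normalized to sum 1.
    """
    shared = [g for g in signature.index if g in bulk.columns]
    if len(shared) < 0.5 * len(signature.index):
        raise ValueError(
            f"only {len(shared)}/{len(signature.index)} signature genes in bulk "
            "(< 50%)"
        )
    S = signature.loc[shared].to_numpy(dtype=float)
    B = bulk[shared].to_numpy(dtype=float).T   # genes x samples
    if np.linalg.matrix_rank(S) < S.shape[1]:
        log.warning("deconvolve: rank-deficient signature matrix")
    zero_samples = np.where(B.sum(axis=0) == 0)[0]
    if zero_samples.size:
        raise ValueError(
            f"all-zero bulk samples: {list(bulk.index[zero_samples])}"
        )
    if scale == "quantile":
        joint = _quantile_scale(np.hstack([S, B]))
        S, B = joint[:, : S.shape[1]], joint[:, S.shape[1]:]
    elif scale is not None:
        raise ValueError(f"unknown scale option {scale!r}")

    fractions = np.empty((bulk.shape[0], S.shape[1]))
    for i in range(bulk.shape[0]):
        coef, _ = nnls(S, B[:, i])
        total = coef.sum()
        fractions[i] = coef / total if total > 0 else np.full(S.shape[1], np.nan)
    return pd.DataFrame(fractions, index=bulk.index, columns=signature.columns)


def compare_groups(
    result: pd.DataFrame,
    groups,
    p_cut: float = 0.05,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-cluster fold change and two-sample t-test between two groups.

    ``groups`` maps sample ids to exactly two labels; fold change is the
    ratio of group mean fractions (first label over second, labels in sorted
    order). Welch's unequal-variance t-test by default. Degenerate
    zero-variance comparisons report a missing p.
    """
    groups = pd.Series(groups).reindex(result.index)
    labels = sorted(groups.dropna().unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 group labels, got {labels}")
    a = result[groups == labels[0]]
    b = result[groups == labels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 samples")
    rows = []
    for cluster in result.columns:
        ma, mb = a[cluster].mean(), b[cluster].mean()
        fold = ma / mb if mb > 0 else np.inf if ma > 0 else np.nan
        if a[cluster].std() == 0 and b[cluster].std() == 0:
            p = np.nan
        else:
            p = float(ttest_ind(a[cluster], b[cluster], equal_var=equal_var).pvalue)
        rows.append((cluster, ma, mb, fold, p))
    out = pd.DataFrame(
        rows,
        columns=["cluster", f"mean_{labels[0]}", f"mean_{labels[1]}",
                 "fold_change", "pvalue"],
    ).set_index("cluster")
    out["significant"] = out.pvalue < p_cut
    return out
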