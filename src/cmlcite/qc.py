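"""Cell quality filtering, hashtag demultiplexing, and doublet exclusion.

QC removes cells by detected-gene count and mitochondrial UMI fraction.
Hashtag demultiplexing thresholds each hashtag independently with an Otsu
cut computed on log1p counts (with a background-buffer relaxation and an
override floor), then labels cells singlet / multiplet / unassigned by which
cuts they exceed. A second doublet filter flags cells where an RNA cluster
and an HTO 2-group partition overlap reciprocally above 70%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import AgglomerativeClustering
from sklearn.neighbors import kneighbors_graph

from ._norm import to_dense

log = logging.getLogger(__name__)

UNASSIGNED = "unassigned"
MULTIPLET = "multiplet"

OTSU_BINS = 256


@dataclass
class QCThresholds:
    """Cell-level QC cutoffs.

    The defaults follow the CML-sample convention: cells with fewer than
    1000 or more than 9000 detected genes are excluded, as are cells with a
    mitochondrial UMI fraction above ``max_mito_fraction`` (0.11 for patient
    samples; use 0.06 for the normal bone marrow reference).
    """

    min_genes: int = 1000
    max_genes: int = 9000
    max_mito_fraction: float = 0.11

    def __post_init__(self) -> None:
        if not 0 < self.min_genes < self.max_genes:
            raise ValueError("require 0 < min_genes < max_genes")
        if not 0.0 < self.max_mito_fraction < 1.0:
            raise ValueError("max_mito_fraction must be in (0, 1)")


REFERENCE_QC = QCThresholds(max_mito_fraction=0.06)


@dataclass
class HashtagAssignment:
    """Per-cell hashtag labels and the per-hashtag cut values used."""

    labels: pd.Series
    thresholds: dict[str, float | None] = field(default_factory=dict)


def filter_cells(rna, thresholds: QCThresholds, mito_gene_set) -> np.ndarray:
    """Boolean mask of cells passing gene-count and mito-fraction rules."""
    mito = [g for g in mito_gene_set]
    unknown = set(mito) - set(rna.var_names)
    if unknown:
        raise ValueError(f"mito genes absent from matrix: {sorted(unknown)[:5]}")
    if rna.n_obs == 0:
        log.warning("filter_cells: empty matrix")
        return np.zeros(0, dtype=bool)
    X = rna.X
    if sp.issparse(X):
        n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
        totals = np.asarray(X.sum(axis=1)).ravel().astype(float)
    else:
        n_genes = (np.asarray(X) > 0).sum(axis=1)
        totals = np.asarray(X, dtype=float).sum(axis=1)
    mito_idx = rna.var_names.get_indexer(mito)
    mito_counts = (
        np.asarray(X[:, mito_idx].sum(axis=1)).ravel().astype(float)
        if len(mito_idx)
        else np.zeros(rna.n_obs)
    )
    mito_frac = np.divide(
        mito_counts, totals, out=np.zeros_like(mito_counts), where=totals > 0
    )
    return (
        (n_genes >= thresholds.min_genes)
        & (n_genes <= thresholds.max_genes)
        & (mito_frac <= thresholds.max_mito_fraction)
    )


def _between_class_variance(values: np.ndarray, cut: float) -> float:
    """Weighted between-class variance of a split at ``cut`` (lower: < cut)."""
    lower = values < cut
    n0 = int(lower.sum())
    n1 = values.size - n0
    if n0 == 0 or n1 == 0:
        return -np.inf
    mu0 = values[lower].mean()
    mu1 = values[~lower].mean()
    return n0 * n1 * (mu0 - mu1) ** 2 / values.size**2


def otsu_log_cut(values) -> float | None:
    """Pre-relaxation Otsu cut on the log1p scale.

    The log1p-transformed counts are binned into a 256-bin histogram; the
    candidate cuts are the bin upper edges, and the returned cut maximizes
    the between-class variance of the induced two-class split (ties broken
    toward the lowest cut). Returns None for (near-)constant input.
    """
    v = np.log1p(np.asarray(values, dtype=float))
    if v.size < 2 or np.ptp(v) == 0:
        return None
    edges = np.histogram_bin_edges(v, bins=OTSU_BINS)
    candidates = edges[1:]
    scores = np.array([_between_class_variance(v, c) for c in candidates])
    return float(candidates[int(np.argmax(scores))])


def otsu_threshold(
    values,
    background_buffer: float = 0.1,
    override: float = 0.5,
) -> float | None:
    """Otsu threshold for one hashtag's counts, on the original count scale.

    The raw Otsu cut (see :func:`otsu_log_cut`) is relaxed downward by
    ``background_buffer`` times the log-scale range; if the relaxed cut
    falls below ``override`` times the log-scale maximum, that floor is used
    instead. Returns None when the input is constant (no threshold; callers
    treat all cells as background).
    """
    raw = otsu_log_cut(values)
    if raw is None:
        return None
    v = np.log1p(np.asarray(values, dtype=float))
    relaxed = raw - background_buffer * (v.max() - v.min())
    floor = override * v.max()
    return float(np.expm1(max(relaxed, floor)))


def demultiplex(
    hto,
    fixed_thresholds: dict[str, float] | None = None,
    background_buffer: float = 0.1,
    override: float = 0.5,
) -> HashtagAssignment:
    """Assign each cell a hashtag, multiplet, or unassigned label.

    Per hashtag the cut is the fixed threshold when provided, else the Otsu
    threshold of that hashtag's counts. A cell exceeding exactly one cut
    (strictly) gets that hashtag; two or more, multiplet; none, unassigned.
    """
    if hto.n_vars < 1:
        raise ValueError("HTO matrix has no hashtag features")
    fixed = dict(fixed_thresholds or {})
    unknown = set(fixed) - set(hto.var_names)
    if unknown:
        raise ValueError(f"fixed thresholds for unknown hashtags: {sorted(unknown)}")
    X = to_dense(hto.X)
    cuts: dict[str, float | None] = {}
    exceed = np.zeros_like(X, dtype=bool)
    for j, name in enumerate(hto.var_names):
        cut = fixed[name] if name in fixed else otsu_threshold(
            X[:, j], background_buffer, override
        )
        cuts[name] = cut
        if cut is not None:
            exceed[:, j] = X[:, j] > cut
    n_exceed = exceed.sum(axis=1)
    labels = np.full(hto.n_obs, UNASSIGNED, dtype=object)
    labels[n_exceed >= 2] = MULTIPLET
    single = n_exceed == 1
    hash_names = np.asarray(hto.var_names, dtype=object)
    labels[single] = hash_names[np.argmax(exceed[single], axis=1)]
    return HashtagAssignment(
        labels=pd.Series(labels, index=hto.obs_names, name="hashtag"),
        thresholds=cuts,
    )


def hto_partition(hto, n_groups: int = 2, n_neighbors: int = 15) -> np.ndarray:
    """Partition cells into ``n_groups`` in HTO space.

    Agglomerative (Ward) clustering constrained to a KNN connectivity graph
    over log1p hashtag counts — a stand-in for graph-based 2-way partitions
    of the HTO landscape.
    """
    X = np.log1p(to_dense(hto.X))
    k = min(n_neighbors, hto.n_obs - 1)
    connectivity = kneighbors_graph(X, n_neighbors=k, include_self=False)
    model = AgglomerativeClustering(
        n_clusters=n_groups, linkage="ward", connectivity=connectivity
    )
    return model.fit_predict(X)


def exclude_hto_doublets(
    rna_clusters,
    hto,
    overlap_threshold: float = 0.7,
) -> np.ndarray:
    """Flag cells in reciprocally-overlapping RNA-cluster / HTO-group pairs.

    The HTO matrix is partitioned into 2 groups; for every (RNA cluster r,
    HTO group h) pair with |r∩h|/|r| > threshold and |r∩h|/|h| > threshold,
    the cells of r∩h are flagged as doublets.
    """
    rna_clusters = pd.Series(rna_clusters)
    if len(rna_clusters) != hto.n_obs:
        raise ValueError("rna_clusters must cover every cell in the HTO matrix")
    if hto.n_obs < 2:
        log.warning("exclude_hto_doublets: fewer than 2 cells, no flags")
        return np.zeros(hto.n_obs, dtype=bool)
    groups = hto_partition(hto)
    flags = np.zeros(hto.n_obs, dtype=bool)
    r_values = np.asarray(rna_clusters)
    for r in pd.unique(r_values):
        in_r = r_values == r
        for h in np.unique(groups):
            in_h = groups == h
            inter = in_r & in_h
            n_inter = int(inter.sum())
            if n_inter == 0:
                continue
            if (n_inter / in_r.sum() > overlap_threshold
                    and n_inter / in_h.sum() > overlap_threshold):
                flags |= inter
    return flags


def qc_report(rna, mask: np.ndarray, assignment: HashtagAssignment | None,
              doublet_flags: np.ndarray | None) -> pd.DataFrame:
    """Per-cell QC/demux summary table (for the TSV report)."""
    X = rna.X
    if sp.issparse(X):
        n_genes = np.asarray((X > 0).sum(axis=1)).ravel()
        totals = np.asarray(X.sum(axis=1)).ravel().astype(float)
    else:
        n_genes = (np.asarray(X) > 0).sum(axis=1)
        totals = np.asarray(X, dtype=float).sum(axis=1)
    mito_genes = [g for g in rna.var_names if g.startswith("MT-")]
    mito_idx = rna.var_names.get_indexer(mito_genes)
    mito = (
        np.asarray(X[:, mito_idx].sum(axis=1)).ravel().astype(float)
        if len(mito_idx) else np.zeros(rna.n_obs)
    )
    report = pd.DataFrame(
        {
            "n_genes": n_genes,
            "mito_fraction": np.divide(
                mito, totals, out=np.zeros_like(mito), where=totals > 0
            ),
            "qc_pass": mask,
        },
        index=rna.obs_names,
    )
    if assignment is not None:
        report["hashtag"] = assignment.labels.reindex(report.index)
    if doublet_flags is not None:
        report["hto_doublet"] = doublet_flags
    return report
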