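"""HVG selection, PCA/KNN graph construction, clustering, embedding, and the
rank-based marker-specificity statistic.

The processing contract is: per-cell total-count scaling to the median
library size, log1p, restriction to highly variable genes, per-gene
z-scaling, PCA to the top components, then a Euclidean KNN graph in PC
space. Community detection is Leiden (modularity, configurable resolution)
and the 2-D embedding is UMAP; both are established algorithms invoked by
contract, seeded for reproducibility.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.stats import rankdata
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from ._norm import normalize_log, to_dense, zscore_columns

log = logging.getLogger(__name__)


@dataclass
class GraphParams:
    """Parameters of the HVG → PCA → KNN → Leiden/UMAP stage.

    Defaults follow the patient-sample dialect (2000 HVGs, min_cells 50,
    20 PCs, k=11, Leiden resolution 1.0, UMAP min_dist 1 / spread 2 /
    2000 epochs); the reference dialect uses resolution 0.76, and one
    low-depth patient dialect uses 1000 HVGs / min_cells 30.
    """

    n_hvgs: int = 2000
    min_cells: int = 50
    n_pcs: int = 20
    k_neighbors: int = 11
    leiden_resolution: float = 1.0
    umap_min_dist: float = 1.0
    umap_spread: float = 2.0
    umap_epochs: int = 2000

    def __post_init__(self) -> None:
        for name in ("n_hvgs", "min_cells", "n_pcs", "k_neighbors",
                     "leiden_resolution", "umap_min_dist", "umap_spread",
                     "umap_epochs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_pcs > self.n_hvgs:
            raise ValueError("n_pcs must not exceed n_hvgs")


REFERENCE_PARAMS = GraphParams(leiden_resolution=0.76)
LOW_DEPTH_PARAMS = GraphParams(n_hvgs=1000, min_cells=30)
# dialect used when merging primitive cells across patients
PRIMITIVE_MERGE_PARAMS = GraphParams(
    n_hvgs=500, min_cells=30, leiden_resolution=0.1, umap_epochs=500
)


@dataclass
class CellGraph:
    """PCA coordinates and KNN graph of one sample."""

    pcs: np.ndarray
    neighbors: np.ndarray       # (n_cells, k) neighbor indices
    distances: np.ndarray       # (n_cells, k)
    adjacency: sp.csr_matrix    # symmetrized unweighted adjacency
    cell_ids: pd.Index


def select_hvgs(
    rna,
    n_hvgs: int = 2000,
    min_cells: int = 50,
    exclude: list[str] | None = None,
) -> list[str]:
    """Top highly-variable genes by mean-corrected dispersion.

    Genes detected in fewer than ``min_cells`` cells (or listed in
    ``exclude``) are ineligible. Under a negative binomial noise model the
    dispersion (variance/mean of library-size normalized expression) is
    1 + phi * mean, so the mean trend is removed by that line with the
    Poisson intercept fixed and phi estimated robustly as the median of
    (dispersion - 1)/mean over eligible genes; the top ``n_hvgs`` genes by
    residual dispersion are returned in decreasing order.
    """
    if rna.n_obs == 0 or rna.n_vars == 0:
        raise ValueError("empty matrix")
    X = rna.X
    detected = (
        np.asarray((X > 0).sum(axis=0)).ravel()
        if sp.issparse(X)
        else (np.asarray(X) > 0).sum(axis=0)
    )
    eligible = detected >= min_cells
    if exclude:
        eligible &= ~rna.var_names.isin(exclude)
    norm, _ = normalize_log(X)
    expr = np.expm1(norm)  # normalized linear scale
    mean = expr.mean(axis=0)
    var = expr.var(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        dispersion = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    eligible &= mean > 0

    df = pd.DataFrame(
        {"mean": mean, "dispersion": dispersion, "eligible": eligible},
        index=rna.var_names,
    )
    sub = df[df.eligible].copy()
    if sub.empty:
        log.warning("select_hvgs: no eligible genes")
        return []
    if len(sub) >= 3:
        phi_hat = max(
            float(np.median((sub["dispersion"] - 1.0) / sub["mean"])), 0.0
        )
        sub["residual"] = sub["dispersion"] - (1.0 + phi_hat * sub["mean"])
    else:
        sub["residual"] = sub["dispersion"]
    ranked = sub.sort_values("residual", ascending=False)
    if len(ranked) < n_hvgs:
        log.warning(
            "select_hvgs: only %d eligible genes (< %d requested)",
            len(ranked), n_hvgs,
        )
    return ranked.index[:n_hvgs].tolist()


def build_graph(
    rna,
    hvgs: list[str],
    params: GraphParams,
    fit_cells: np.ndarray | None = None,
    mp_denoise: bool = False,
) -> CellGraph:
    """Normalize, reduce to PC space, and build the Euclidean KNN graph.

    When ``fit_cells`` is given, the gene standardization and PCA are fitted
    on that cell subset only and applied to all cells. With ``mp_denoise``
    the PC coordinates are shrunk by the random-matrix factor
    sqrt(max(λ − λ₊, 0)/λ), where λ₊ = (1 + sqrt(n_genes/n_fit))² is the
    Marchenko-Pastur bulk edge for z-scored data: components indistinguishable
    from sampling noise then carry (near-)zero weight in neighbor distances.
    When no component exceeds the bulk edge the coordinates are left
    unscaled.
    """
    missing = [g for g in hvgs if g not in rna.var_names]
    if missing:
        raise ValueError(f"HVGs absent from matrix: {missing[:5]}")
    norm, _ = normalize_log(rna.X)
    cols = rna.var_names.get_indexer(hvgs)
    M = norm[:, cols]
    if fit_cells is None:
        fit_cells = np.ones(rna.n_obs, dtype=bool)
    else:
        fit_cells = np.asarray(fit_cells, dtype=bool)
        if fit_cells.sum() == 0:
            raise ValueError("fit_cells selects no cells")
    _, mean, std = zscore_columns(M[fit_cells])
    Z = (M - mean) / std

    n_pcs = min(params.n_pcs, int(fit_cells.sum()) - 1, Z.shape[1])
    if n_pcs < params.n_pcs:
        log.warning("build_graph: reducing n_pcs to %d (rank limit)", n_pcs)
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=0)
    pca.fit(Z[fit_cells])
    pcs = pca.transform(Z)
    if mp_denoise:
        lam = pcs[fit_cells].var(axis=0)
        bulk_edge = (1.0 + np.sqrt(len(hvgs) / fit_cells.sum())) ** 2
        weight = np.sqrt(np.maximum(lam - bulk_edge, 0.0) / np.maximum(lam, 1e-12))
        if (weight > 0).any():
            pcs = pcs * weight

    k = min(params.k_neighbors, rna.n_obs - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pcs)
    dist, idx = nn.kneighbors(pcs)
    # drop self-neighbors (first column after sorting by distance)
    neighbors = np.empty((rna.n_obs, k), dtype=np.int64)
    distances = np.empty((rna.n_obs, k))
    for i in range(rna.n_obs):
        row = [(j, d) for j, d in zip(idx[i], dist[i]) if j != i][:k]
        neighbors[i] = [j for j, _ in row]
        distances[i] = [d for _, d in row]

    rows = np.repeat(np.arange(rna.n_obs), k)
    adj = sp.csr_matrix(
        (np.ones(rna.n_obs * k), (rows, neighbors.ravel())),
        shape=(rna.n_obs, rna.n_obs),
    )
    adj = ((adj + adj.T) > 0).astype(np.float64)
    return CellGraph(
        pcs=pcs,
        neighbors=neighbors,
        distances=distances,
        adjacency=adj,
        cell_ids=rna.obs_names,
    )


def leiden_cluster(graph: CellGraph | sp.spmatrix, resolution: float,
                   seed: int) -> np.ndarray:
    """Leiden community detection on the KNN graph; labels as strings."""
    adj = graph.adjacency if isinstance(graph, CellGraph) else sp.csr_matrix(graph)
    if adj.shape[0] == 0:
        raise ValueError("empty graph")
    sources, targets = adj.nonzero()
    keep = sources < targets
    g = ig.Graph(
        n=adj.shape[0],
        edges=list(zip(sources[keep].tolist(), targets[keep].tolist())),
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership).astype(str)


def umap_embed(graph: CellGraph | np.ndarray, params: GraphParams,
               seed: int) -> np.ndarray:
    """2-D UMAP embedding of the PC coordinates; deterministic under seed."""
    pcs = graph.pcs if isinstance(graph, CellGraph) else np.asarray(graph)
    if pcs.shape[0] < 3:
        raise ValueError("need at least 3 cells to embed")
    import umap  # deferred: numba compilation is slow at import time

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = umap.UMAP(
            n_components=2,
            n_neighbors=min(params.k_neighbors, pcs.shape[0] - 1),
            min_dist=params.umap_min_dist,
            spread=params.umap_spread,
            n_epochs=params.umap_epochs,
            random_state=seed,
        )
        coords = model.fit_transform(pcs)
    return np.asarray(coords)


def marker_specificity(rna, clusters) -> pd.DataFrame:
    """Rank-based marker specificity: genes x clusters, rows summing to 1.

    Expression values are ranked within each cell (average ranks for ties,
    higher expression ⇒ higher rank); the per-(gene, cluster) mean rank is
    divided by the gene's total mean rank across clusters.
    """
    clusters = pd.Series(np.asarray(clusters), index=rna.obs_names)
    labels = [c for c in pd.unique(clusters)]
    if len(labels) < 2:
        raise ValueError("need at least 2 clusters")
    X = to_dense(rna.X)
    ranks = rankdata(X, axis=1)
    cols = {}
    for c in labels:
        members = (clusters == c).to_numpy()
        if members.sum() == 0:
            log.warning("marker_specificity: cluster %r has no cells", c)
            continue
        cols[c] = ranks[members].mean(axis=0)
    table = pd.DataFrame(cols, index=rna.var_names)
    return table.div(table.sum(axis=1), axis=0)


def top_markers(specificity: pd.DataFrame, n: int = 10) -> dict[str, list[str]]:
    """Top-``n`` most specific genes per cluster (annotation aid)."""
    return {
        c: specificity[c].sort_values(ascending=False).index[:n].tolist()
        for c in specificity.columns
    }
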