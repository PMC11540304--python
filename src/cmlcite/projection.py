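"""Reference projection and label transfer.

Query cells are normalized with the reference's statistics, projected with
the reference PCA loadings, and matched to their nearest reference cells in
PC space. Cluster labels are transferred by a thresholded inverse-distance
weighted vote (abstaining to "NA" when no cluster wins a strict majority of
the weight), and per-reference-cell mapping scores summarize how often each
reference cell is hit by query neighborhoods.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from ._norm import normalize_log, zscore_columns
from .embed import GraphParams, select_hvgs

log = logging.getLogger(__name__)

EPSILON = 1e-9
ABSTAIN = "NA"


@dataclass
class ReferenceModel:
    """Frozen reference: HVGs, normalization statistics, PCA, coordinates,
    and per-cell cluster labels."""

    hvgs: list[str]
    target_sum: float
    gene_mean: np.ndarray
    gene_std: np.ndarray
    components: np.ndarray      # (n_pcs, n_hvgs) loadings
    pcs: np.ndarray             # (n_ref, n_pcs)
    labels: pd.Series           # indexed by reference cell id

    def __post_init__(self) -> None:
        gram = self.components @ self.components.T
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-6):
            raise ValueError("PCA loadings are not orthonormal")
        if len(self.labels) != self.pcs.shape[0]:
            raise ValueError("every reference cell must carry a label")

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(
            directory / "model.npz",
            gene_mean=self.gene_mean,
            gene_std=self.gene_std,
            components=self.components,
            pcs=self.pcs,
        )
        self.labels.rename("cluster").to_frame().to_csv(
            directory / "labels.tsv", sep="\t"
        )
        meta = {"hvgs": self.hvgs, "target_sum": self.target_sum}
        (directory / "meta.json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, directory: str | Path) -> "ReferenceModel":
        directory = Path(directory)
        arrays = np.load(directory / "model.npz")
        labels = pd.read_csv(directory / "labels.tsv", sep="\t", index_col=0)[
            "cluster"
        ]
        meta = json.loads((directory / "meta.json").read_text())
        return cls(
            hvgs=meta["hvgs"],
            target_sum=meta["target_sum"],
            gene_mean=arrays["gene_mean"],
            gene_std=arrays["gene_std"],
            components=arrays["components"],
            pcs=arrays["pcs"],
            labels=labels,
        )


@dataclass
class ProjectionResult:
    """Per-query-cell neighbors, distances, and normalized weights."""

    neighbor_ids: np.ndarray   # (n_query, k) reference cell indices
    distances: np.ndarray
    weights: np.ndarray        # rows sum to 1
    query_ids: pd.Index


def build_reference(rna, labels, params: GraphParams | None = None) -> ReferenceModel:
    """Fit a ReferenceModel from a labeled reference sample."""
    params = params or GraphParams()
    labels = pd.Series(np.asarray(labels), index=rna.obs_names)
    hvgs = select_hvgs(rna, params.n_hvgs, params.min_cells)
    norm, target_sum = normalize_log(rna.X)
    M = norm[:, rna.var_names.get_indexer(hvgs)]
    Z, mean, std = zscore_columns(M)
    from sklearn.decomposition import PCA

    n_pcs = min(params.n_pcs, Z.shape[0] - 1, Z.shape[1])
    pca = PCA(n_components=n_pcs, svd_solver="full", random_state=0)
    pcs = pca.fit_transform(Z)
    return ReferenceModel(
        hvgs=hvgs,
        target_sum=target_sum,
        gene_mean=mean,
        gene_std=std,
        components=pca.components_,
        pcs=pcs,
        labels=labels,
    )


def map_cells(reference: ReferenceModel, query_rna, n_neighbors: int = 5
              ) -> ProjectionResult:
    """Project query cells onto the reference and find nearest neighbors.

    Reference HVGs missing from the query are zero-filled (with a warning,
    rejected when more than 10% are missing); query genes outside the HVG
    list are ignored. Neighbor weights are normalized inverse distances,
    weight_j = (1/(d_j+eps)) / sum(1/(d+eps)).
    """
    if query_rna.n_obs == 0:
        return ProjectionResult(
            neighbor_ids=np.zeros((0, n_neighbors), dtype=int),
            distances=np.zeros((0, n_neighbors)),
            weights=np.zeros((0, n_neighbors)),
            query_ids=pd.Index([]),
        )
    present = [g for g in reference.hvgs if g in query_rna.var_names]
    missing = len(reference.hvgs) - len(present)
    if missing:
        if missing > 0.1 * len(reference.hvgs):
            raise ValueError(
                f"query shares only {len(present)}/{len(reference.hvgs)} "
                "reference HVGs (< 90%)"
            )
        log.warning("map_cells: %d reference HVGs missing from query, "
                    "imputed as zero", missing)
    norm, _ = normalize_log(query_rna.X, target_sum=reference.target_sum)
    M = np.zeros((query_rna.n_obs, len(reference.hvgs)))
    pos = {g: i for i, g in enumerate(reference.hvgs)}
    cols = [pos[g] for g in present]
    M[:, cols] = norm[:, query_rna.var_names.get_indexer(present)]
    Z = (M - reference.gene_mean) / reference.gene_std
    pcs = Z @ reference.components.T

    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(reference.pcs)
    dist, idx = nn.kneighbors(pcs)
    inv = 1.0 / (dist + EPSILON)
    weights = inv / inv.sum(axis=1, keepdims=True)
    return ProjectionResult(
        neighbor_ids=idx, distances=dist, weights=weights,
        query_ids=query_rna.obs_names,
    )


def transfer_labels(
    projection: ProjectionResult,
    reference_labels,
    threshold: float = 0.5,
) -> pd.Series:
    """Weighted-vote label transfer with abstention.

    Per query cell, neighbor weights are summed by reference cluster; the
    top cluster is assigned iff its summed weight strictly exceeds
    ``threshold``, else the cell abstains to "NA".
    """
    ref_labels = np.asarray(pd.Series(reference_labels))
    out = []
    for ids, w in zip(projection.neighbor_ids, projection.weights):
        votes: dict[str, float] = {}
        for j, wj in zip(ids, w):
            votes[ref_labels[j]] = votes.get(ref_labels[j], 0.0) + wj
        best = max(votes, key=votes.get)
        out.append(best if votes[best] > threshold else ABSTAIN)
    return pd.Series(out, index=projection.query_ids, name="transferred_label")


def mapping_score(projection: ProjectionResult, n_reference: int) -> np.ndarray:
    """Per-reference-cell mapping score, normalized to mean 1.

    score_r = (number of query cells with r among their k neighbors)
    * n_reference / (k * n_query); useful to scale reference point sizes.
    """
    if projection.neighbor_ids.size == 0:
        raise ValueError("empty projection")
    n_query, k = projection.neighbor_ids.shape
    counts = np.bincount(projection.neighbor_ids.ravel(), minlength=n_reference)
    return counts * n_reference / (k * n_query)
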