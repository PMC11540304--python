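"""BCR::ABL1 status classification of primitive cells.

Primitive-cluster cells from all patients are merged with normal control
cells, re-embedded with a dedicated dialect (500 HVGs fitted on the patient
cells only), and clustered coarsely. Each cell is scored against leukemic
(LSC) and normal (HSC) stem-cell signatures, and coarse clusters are then
called BCR::ABL1 positive / negative / control by a deterministic rule:
the control-dominated cluster is the control; a remaining cluster is
positive iff its mean LSC score exceeds its mean HSC score and exceeds the
control cluster's LSC scores by a one-sided rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu

from ._norm import normalize_log, zscore_columns
from .embed import PRIMITIVE_MERGE_PARAMS, CellGraph, build_graph, leiden_cluster, select_hvgs
from .signature import GeneSignature

log = logging.getLogger(__name__)

STATUS_POS = "BCR::ABL1_pos"
STATUS_NEG = "BCR::ABL1_neg"
STATUS_CONTROL = "control"

# Sex-chromosome-linked genes excluded from HVG selection when merging
# samples from patients of different sex; configurable.
DEFAULT_SEX_GENES = ["XIST", "RPS4Y1", "DDX3Y", "UTY", "KDM5D", "EIF1AY", "TSIX"]


@dataclass
class StatusCall:
    """Cluster-level status calls and their per-cell propagation."""

    cluster_status: dict[str, str]
    cell_status: pd.Series


def merge_primitive(
    patient_matrices: dict[str, ad.AnnData],
    control: ad.AnnData | None,
) -> ad.AnnData:
    """Concatenate per-patient primitive cells (plus control) with provenance.

    The merged matrix keeps, per cell, the patient of origin (``patient``,
    "control" for control cells), the original cell id (``origin_id``) and an
    ``is_control`` flag. Patients contributing zero cells are skipped with a
    warning. Merged obs_names are prefixed with the patient id so they stay
    unique.
    """
    parts = []
    for patient, mat in patient_matrices.items():
        if mat.n_obs == 0:
            log.warning("merge_primitive: patient %r has no primitive cells", patient)
            continue
        part = mat.copy()
        part.obs["patient"] = patient
        part.obs["origin_id"] = part.obs_names
        part.obs["is_control"] = False
        part.obs_names = [f"{patient}:{c}" for c in part.obs_names]
        parts.append(part)
    if control is not None and control.n_obs > 0:
        part = control.copy()
        part.obs["patient"] = "control"
        part.obs["origin_id"] = part.obs_names
        part.obs["is_control"] = True
        part.obs_names = [f"control:{c}" for c in part.obs_names]
        parts.append(part)
    if not parts:
        raise ValueError("no cells to merge")
    universe = parts[0].var_names
    for part in parts[1:]:
        if not part.var_names.equals(universe):
            raise ValueError("merged matrices must share one feature universe")
    merged = ad.concat(parts, join="inner", merge="same")
    merged.var = parts[0].var.loc[merged.var_names].copy()
    return merged


def primitive_merge_graph(
    merged: ad.AnnData,
    exclude_genes: list[str] | None = None,
    params=PRIMITIVE_MERGE_PARAMS,
) -> CellGraph:
    """Build the merged-primitive graph: HVGs and PCA fitted on patient
    (non-control) cells only, control cells projected."""
    exclude = list(exclude_genes) if exclude_genes is not None else list(DEFAULT_SEX_GENES)
    cml_mask = ~merged.obs["is_control"].to_numpy()
    if cml_mask.sum() == 0:
        raise ValueError("no patient cells in merged matrix")
    fit_view = merged[cml_mask]
    hvgs = select_hvgs(fit_view, params.n_hvgs, params.min_cells, exclude=exclude)
    # MP denoising suppresses the noise-bulk PCs; with only a few hundred
    # merged primitive cells over 500 HVGs the sampling-noise eigenvalues
    # otherwise dominate neighbor distances and blur the coarse structure
    return build_graph(merged, hvgs, params, fit_cells=cml_mask, mp_denoise=True)


def coarse_cluster(graph: CellGraph, resolution: float = 0.1,
                   seed: int = 0) -> pd.Series:
    """Coarse Leiden partition of the merged primitive graph."""
    if graph.pcs.shape[0] < 2:
        raise ValueError("cannot cluster fewer than 2 cells")
    labels = leiden_cluster(graph, resolution, seed)
    return pd.Series(labels, index=graph.cell_ids, name="coarse_cluster")


def score_signature(rna, signature: GeneSignature, genes: str = "up") -> pd.Series:
    """Per-cell signature score.

    Counts are library-size normalized and log1p transformed; each signature
    gene present in the matrix is z-scored across cells, and the score is
    the mean z over the chosen gene list ("up" or "down"). Genes constant
    across cells contribute 0; genes absent from the matrix are dropped with
    a warning.
    """
    gene_list = signature.up_genes if genes == "up" else signature.down_genes
    present = [g for g in gene_list if g in rna.var_names]
    if not present:
        raise ValueError(
            f"no genes of signature {signature.name!r} ({genes}) in the matrix"
        )
    if len(present) < len(gene_list):
        log.warning(
            "score_signature: %d/%d %s-genes of %r absent, dropped",
            len(gene_list) - len(present), len(gene_list), genes, signature.name,
        )
    norm, _ = normalize_log(rna.X)
    M = norm[:, rna.var_names.get_indexer(present)]
    Z, _, _ = zscore_columns(M)
    # zscore_columns maps constant genes to exactly 0
    return pd.Series(Z.mean(axis=1), index=rna.obs_names,
                     name=f"{signature.name}_{genes}")


def assign_status(
    clusters,
    lsc_score: pd.Series,
    hsc_score: pd.Series,
    control_ids,
    alpha: float = 0.05,
) -> StatusCall:
    """Call each coarse cluster control / BCR::ABL1_pos / BCR::ABL1_neg.

    A cluster whose membership is majority control cells is the control
    cluster. A remaining cluster is positive iff its mean LSC score exceeds
    its mean HSC score AND its LSC scores exceed the control cluster's by a
    one-sided Mann-Whitney rank-sum test at ``alpha``; otherwise negative.
    Without control cells the rank-sum comparison is against the pooled
    other clusters (with a warning).
    """
    clusters = pd.Series(clusters)
    control_ids = set(control_ids)
    lsc = lsc_score.reindex(clusters.index)
    hsc = hsc_score.reindex(clusters.index)
    is_control = clusters.index.isin(control_ids)

    labels = pd.unique(clusters)
    control_clusters = [
        c for c in labels
        if is_control[(clusters == c).to_numpy()].mean() > 0.5
    ]
    cml_clusters = [c for c in labels if c not in control_clusters]
    if len(cml_clusters) < 2:
        raise ValueError("need at least 2 non-control clusters")

    if control_clusters:
        baseline = lsc[clusters.isin(control_clusters).to_numpy()]
    else:
        log.warning("assign_status: no control cells; comparing CML clusters "
                    "pairwise against each other")
        baseline = None

    cluster_status: dict[str, str] = {c: STATUS_CONTROL for c in control_clusters}
    for c in cml_clusters:
        members = (clusters == c).to_numpy()
        mean_lsc = float(lsc[members].mean())
        mean_hsc = float(hsc[members].mean())
        other = baseline if baseline is not None else lsc[~members & ~is_control]
        enriched = False
        if mean_lsc > mean_hsc and len(other) > 0:
            stat_p = mannwhitneyu(
                lsc[members], other, alternative="greater"
            ).pvalue
            enriched = stat_p < alpha
        cluster_status[c] = STATUS_POS if enriched else STATUS_NEG

    cell_status = clusters.map(cluster_status)
    cell_status.name = "bcr_abl1_status"
    return StatusCall(cluster_status=cluster_status, cell_status=cell_status)


def link_status(
    patient_cells: pd.DataFrame,
    cell_status: pd.Series,
) -> tuple[pd.DataFrame, list[str]]:
    """Attach per-cell statuses to a patient's merged cell table by cell id.

    ``patient_cells`` is indexed by cell id with a ``label`` column (cluster
    labels from projection). Cells found in ``cell_status`` get their status
    in a new ``status`` column; other cells keep their label there. Status
    ids not present in the table are returned as the unmatched report
    rather than silently dropped.
    """
    if patient_cells.index.has_duplicates:
        raise ValueError("cell ids must be unique within a patient")
    out = patient_cells.copy()
    matched = cell_status.reindex(out.index)
    out["status"] = matched.where(matched.notna(), out["label"])
    unmatched = [i for i in cell_status.index if i not in out.index]
    if unmatched:
        log.warning("link_status: %d status ids not found in patient table",
                    len(unmatched))
    return out, unmatched
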