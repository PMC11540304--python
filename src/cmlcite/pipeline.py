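"""End-to-end pipeline driver.

Executes the analysis stages in order — QC, hashtag demultiplexing,
embedding/clustering, reference projection with label transfer, BCR::ABL1
classification, differential expression (RNA pseudobulk and ADT), gating,
and optional bulk deconvolution — writing each stage's tables under the
output directory as it completes. A stage failure halts the run with the
stage name; tables already written are left in place. All randomness flows
from the config seed, so identical configs reproduce identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import differential, gating, io, qc, status
from .config import PipelineConfig
from .embed import GraphParams, build_graph, leiden_cluster, select_hvgs, umap_embed
from .projection import build_reference, map_cells, mapping_score, transfer_labels
from .signature import read_signature

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _resolve(base: Path, value: str | None) -> Path | None:
    if value is None:
        return None
    path = Path(value)
    return path if path.is_absolute() else base / path


def run_pipeline(config: PipelineConfig, outdir: str | Path,
                 base_dir: str | Path = ".") -> dict[str, Path]:
    """Run all configured stages; returns {output name: path} for the
    emitted tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    base = Path(base_dir)
    outputs: dict[str, Path] = {}
    state: dict = {}

    stages = [
        ("qc", _stage_qc),
        ("demux", _stage_demux),
        ("embed", _stage_embed),
        ("project", _stage_project),
    ]
    if config.classify.enabled:
        stages += [("classify", _stage_classify), ("de", _stage_de),
                   ("adt-de", _stage_adt_de), ("gate", _stage_gate)]
    if config.deconvolution.enabled:
        stages.append(("deconvolve", _stage_deconvolve))

    _log_params(config, outdir)
    for name, fn in stages:
        log.info("pipeline stage: %s", name)
        try:
            fn(config, base, outdir, state, outputs)
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise PipelineError(name, exc) from exc
    return outputs


def _log_params(config: PipelineConfig, outdir: Path) -> None:
    import yaml

    (outdir / "run_params.yaml").write_text(
        yaml.safe_dump(config.to_dict(), sort_keys=True)
    )


def _sample_params(config: PipelineConfig, entry) -> GraphParams:
    params = config.graph
    if entry.n_hvgs or entry.min_cells:
        params = GraphParams(
            n_hvgs=entry.n_hvgs or params.n_hvgs,
            min_cells=entry.min_cells or params.min_cells,
            n_pcs=params.n_pcs,
            k_neighbors=params.k_neighbors,
            leiden_resolution=params.leiden_resolution,
            umap_min_dist=params.umap_min_dist,
            umap_spread=params.umap_spread,
            umap_epochs=params.umap_epochs,
        )
    return params


def _stage_qc(config, base, outdir, state, outputs):
    mito = None
    samples = {}
    for entry in config.samples:
        mods = io.read_counts(_resolve(base, entry.path))
        rna = mods["rna"]
        mito = [g for g in rna.var_names if g.startswith("MT-")]
        mask = qc.filter_cells(rna, config.qc, mito)
        samples[entry.id] = {"mods": mods, "qc_mask": mask, "entry": entry}
    state["samples"] = samples
    if config.reference.path:
        ref_mods = io.read_counts(_resolve(base, config.reference.path))
        ref_qc = qc.QCThresholds(
            min_genes=config.qc.min_genes,
            max_genes=config.qc.max_genes,
            max_mito_fraction=config.reference.max_mito_fraction,
        )
        mito = [g for g in ref_mods["rna"].var_names if g.startswith("MT-")]
        ref_mask = qc.filter_cells(ref_mods["rna"], ref_qc, mito)
        state["reference"] = {"mods": ref_mods, "qc_mask": ref_mask}


def _stage_demux(config, base, outdir, state, outputs):
    for sid, s in state["samples"].items():
        mods, mask = s["mods"], s["qc_mask"]
        keep = mask.copy()
        assignment = None
        if "hto" in mods:
            assignment = qc.demultiplex(
                mods["hto"], fixed_thresholds=config.demux.fixed_thresholds or None
            )
            singlet = ~assignment.labels.isin([qc.MULTIPLET, qc.UNASSIGNED])
            keep &= singlet.to_numpy()
        s["keep"] = keep
        s["assignment"] = assignment
        report = qc.qc_report(mods["rna"], mask, assignment, None)
        report["retained"] = keep
        path = outdir / f"{sid}_qc_demux.tsv"
        report.to_csv(path, sep="\t")
        outputs[f"{sid}_qc_demux"] = path
    if "reference" in state:
        state["reference"]["keep"] = state["reference"]["qc_mask"]


def _stage_embed(config, base, outdir, state, outputs):
    for i, (sid, s) in enumerate(state["samples"].items()):
        rna = s["mods"]["rna"][s["keep"]]
        params = _sample_params(config, s["entry"])
        hvgs = select_hvgs(rna, params.n_hvgs, params.min_cells)
        graph = build_graph(rna, hvgs, params)
        clusters = leiden_cluster(graph, params.leiden_resolution,
                                  seed=config.seed + i)
        coords = umap_embed(graph, params, seed=config.seed + i)
        s["rna_qc"] = rna
        s["clusters"] = pd.Series(clusters, index=rna.obs_names)
        # HTO/RNA-cluster doublet exclusion needs both the RNA partition
        # and hashtag counts of the same retained cells
        if s["assignment"] is not None:
            hto = s["mods"]["hto"][s["keep"]]
            doublet = qc.exclude_hto_doublets(
                clusters, hto, config.demux.doublet_overlap
            )
            s["keep2"] = ~doublet
        else:
            s["keep2"] = np.ones(rna.n_obs, dtype=bool)
        table = pd.DataFrame(
            {"cluster": clusters, "umap1": coords[:, 0], "umap2": coords[:, 1],
             "hto_doublet": ~s["keep2"]},
            index=rna.obs_names,
        )
        path = outdir / f"{sid}_embedding.tsv"
        table.to_csv(path, sep="\t")
        outputs[f"{sid}_embedding"] = path


def _stage_project(config, base, outdir, state, outputs):
    if "reference" not in state:
        log.warning("no reference configured; skipping projection")
        return
    ref = state["reference"]
    ref_rna = ref["mods"]["rna"][ref["keep"]]
    if config.reference.labels:
        labels = pd.read_csv(
            _resolve(base, config.reference.labels), sep="\t", index_col=0
        ).iloc[:, 0].reindex(ref_rna.obs_names)
        if labels.isna().any():
            raise ValueError("reference labels missing for some retained cells")
    else:
        ref_params = GraphParams(
            n_hvgs=config.graph.n_hvgs, min_cells=config.graph.min_cells,
            n_pcs=config.graph.n_pcs, k_neighbors=config.graph.k_neighbors,
            leiden_resolution=config.reference.leiden_resolution,
            umap_min_dist=config.graph.umap_min_dist,
            umap_spread=config.graph.umap_spread,
            umap_epochs=config.graph.umap_epochs,
        )
        hvgs = select_hvgs(ref_rna, ref_params.n_hvgs, ref_params.min_cells)
        graph = build_graph(ref_rna, hvgs, ref_params)
        labels = pd.Series(
            leiden_cluster(graph, ref_params.leiden_resolution, seed=config.seed),
            index=ref_rna.obs_names,
        )
    model = build_reference(ref_rna, labels, config.graph)
    state["reference_model"] = model
    state["reference_labels"] = labels
    for sid, s in state["samples"].items():
        query = s["rna_qc"][s["keep2"]]
        projection = map_cells(model, query, config.projection.neighbors)
        transferred = transfer_labels(
            projection, model.labels, config.projection.threshold
        )
        scores = mapping_score(projection, model.pcs.shape[0])
        s["transferred"] = transferred
        table = transferred.to_frame()
        path = outdir / f"{sid}_labels.tsv"
        table.to_csv(path, sep="\t")
        outputs[f"{sid}_labels"] = path
        spath = outdir / f"{sid}_mapping_scores.tsv"
        pd.DataFrame(
            {"cell_id": model.labels.index, "score": scores}
        ).to_csv(spath, sep="\t", index=False)
        outputs[f"{sid}_mapping_scores"] = spath


def _stage_classify(config, base, outdir, state, outputs):
    sig = read_signature(_resolve(base, config.classify.signature))
    primitive_label = config.classify.primitive_label
    per_patient = {}
    for sid, s in state["samples"].items():
        ids = s["transferred"].index[s["transferred"] == primitive_label]
        per_patient[sid] = s["rna_qc"][s["rna_qc"].obs_names.isin(ids)]
    control = None
    if "reference_model" in state:
        ref_rna = state["reference"]["mods"]["rna"][state["reference"]["keep"]]
        labels = state["reference_labels"]
        control = ref_rna[labels.reindex(ref_rna.obs_names) == primitive_label]
    merged = status.merge_primitive(per_patient, control)
    graph = status.primitive_merge_graph(merged)
    clusters = status.coarse_cluster(graph, seed=config.seed)
    lsc = status.score_signature(merged, sig, "up")
    hsc = status.score_signature(merged, sig, "down")
    control_ids = merged.obs_names[merged.obs["is_control"]]
    call = status.assign_status(clusters, lsc, hsc, control_ids,
                                alpha=config.classify.alpha)
    state["merged"] = merged
    state["status_call"] = call
    table = pd.DataFrame(
        {
            "patient": merged.obs["patient"],
            "origin_id": merged.obs["origin_id"],
            "coarse_cluster": clusters,
            "lsc_score": lsc,
            "hsc_score": hsc,
            "status": call.cell_status,
        }
    )
    path = outdir / "bcr_abl1_status.tsv"
    table.to_csv(path, sep="\t")
    outputs["bcr_abl1_status"] = path


def _stage_de(config, base, outdir, state, outputs):
    merged = state["merged"]
    call = state["status_call"]
    pos = call.cell_status.index[call.cell_status == status.STATUS_POS]
    neg = call.cell_status.index[call.cell_status == status.STATUS_NEG]
    if len(pos) < differential.MIN_CLUSTER_CELLS or (
        len(neg) < differential.MIN_CLUSTER_CELLS
    ):
        log.warning("de: pos/neg groups below %d cells, skipping",
                    differential.MIN_CLUSTER_CELLS)
        return
    reps_pos = differential.pseudobulk_replicates(merged, pos, seed=config.seed)
    reps_neg = differential.pseudobulk_replicates(merged, neg,
                                                  seed=config.seed + 1)
    result = differential.de_test(reps_pos, reps_neg)
    path = outdir / "primitive_pos_vs_neg_de.csv"
    result.to_csv(path)
    outputs["primitive_de"] = path


def _stage_adt_de(config, base, outdir, state, outputs):
    call = state["status_call"]
    merged = state["merged"]
    adt_parts = []
    for sid, s in state["samples"].items():
        adt = s["mods"]["adt"]
        part = adt[adt.obs_names.isin(s["rna_qc"].obs_names)].copy()
        part.obs_names = [f"{sid}:{c}" for c in part.obs_names]
        adt_parts.append(part)
    import anndata as ad

    adt_all = ad.concat(adt_parts, merge="same") if adt_parts else None
    if adt_all is None:
        return
    pos = [c for c in call.cell_status.index
           if call.cell_status[c] == status.STATUS_POS and c in adt_all.obs_names]
    neg = [c for c in call.cell_status.index
           if call.cell_status[c] == status.STATUS_NEG and c in adt_all.obs_names]
    if not pos or not neg:
        log.warning("adt-de: empty status group, skipping")
        return
    result = differential.adt_differential(adt_all, pos, neg)
    path = outdir / "primitive_adt_de.csv"
    result.to_csv(path)
    outputs["primitive_adt_de"] = path
    state["adt_all"] = adt_all


def _stage_gate(config, base, outdir, state, outputs):
    adt_all = state.get("adt_all")
    if adt_all is None:
        return
    clr = differential.clr_normalize(adt_all)
    scaled = gating.adt_to_scale(clr)
    g = config.gates
    thr26 = g.cd26_threshold or gating.auto_threshold(scaled, g.cd26)
    thr35 = g.cd35_threshold or gating.auto_threshold(scaled, g.cd35)
    gates = gating.combination_gates(g.cd26, thr26, g.cd35, thr35)
    call = state["status_call"]
    statuses = call.cell_status.reindex(scaled.index)
    populations = {
        s: (statuses == s).to_numpy()
        for s in [status.STATUS_POS, status.STATUS_NEG]
    }
    report = gating.capture_report(scaled, gates, populations)
    path = outdir / "gate_capture.csv"
    report.to_csv(path, index=False)
    outputs["gate_capture"] = path


def _stage_deconvolve(config, base, outdir, state, outputs):
    from .deconvolution import build_signature_matrix, compare_groups, deconvolve

    bulk = pd.read_csv(_resolve(base, config.deconvolution.bulk), index_col=0)
    ref = state["reference"]
    ref_rna = ref["mods"]["rna"][ref["keep"]]
    labels = state["reference_labels"].reindex(ref_rna.obs_names)
    signature = build_signature_matrix(
        ref_rna, labels, config.deconvolution.n_markers_per_cluster
    )
    result = deconvolve(bulk, signature)
    path = outdir / "deconvolution_fractions.csv"
    result.to_csv(path)
    outputs["deconvolution_fractions"] = path
    if config.deconvolution.groups:
        groups = pd.read_csv(
            _resolve(base, config.deconvolution.groups), index_col=0
        ).iloc[:, 0]
        comparison = compare_groups(result, groups)
        cpath = outdir / "deconvolution_group_comparison.csv"
        comparison.to_csv(cpath)
        outputs["deconvolution_groups"] = cpath
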