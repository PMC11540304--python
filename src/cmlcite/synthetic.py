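"""Synthetic CITE-seq data with known ground truth.

Generates RNA / ADT / HTO count matrices and bulk mixtures that emulate the
structure of sorted CML and normal bone marrow CITE-seq experiments: an
11-cluster hematopoietic hierarchy with cluster-specific marker genes and
marker antibodies, a primitive (stem-like) population split into leukemic
(BCR::ABL1+) and non-leukemic sub-states that differ on a signature gene set
and on LSC/HSC surface markers, hashtag counts with doublets, and bulk
profiles mixed from cluster means. Every generated cell and bulk sample has a
truth record, so each downstream stage can be tested against ground truth.

Counts follow a gamma-Poisson (negative binomial) model: mean m, dispersion
phi, variance m + phi * m^2. A per-cell library-size factor drawn log-normal
makes normalization stages non-trivial.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .signature import GeneSignature

DEFAULT_PHI = 0.3
DEFAULT_LIBSIZE_SD = 0.3
DEFAULT_MARKER_BOOST = 8.0
DEFAULT_ADT_BOOST = 10.0
LEUKEMIC_ADT_BOOST = 16.0

CLUSTER_NAMES = [
    "Primitive", "MPP1", "MPP2", "MEP", "MkP", "ErP",
    "GMP", "Myeloid", "Lymphoid", "pDC", "Mono",
]

MITO_GENES = [
    "MT-ND1", "MT-ND2", "MT-ND3", "MT-ND4", "MT-ND4L", "MT-ND5", "MT-ND6",
    "MT-CO1", "MT-CO2", "MT-CO3", "MT-ATP6", "MT-ATP8", "MT-CYB",
]

ADT_PANEL = [
    "CD34", "CD38", "CD90", "CD26", "CD25", "CD93", "CD35", "CD117",
    "CD45RA", "CD49f", "CD10", "CD7", "CD71", "CD41", "CD123", "CD33",
    "CD14", "CD19", "CD56", "CD11b", "CD13", "CD135", "CD36", "CD105",
    "CD110", "CD62L", "CD44", "CD47", "CD52", "CD99", "CD9", "CD81",
    "CD164", "CD32", "CD69", "CD109", "IgG1-ctrl", "IgG2a-ctrl",
    "IgG2b-ctrl", "IgG-ctrl",
]

# Signature genes carry a few literature marker names (CD26 = DPP4,
# CD25 = IL2RA, and stem-cell genes CRHBP / CXCR4) for readability.
_SIG_UP_NAMED = ["DPP4", "IL2RA", "IL1RAP", "LEPR"]
_SIG_DOWN_NAMED = ["CRHBP", "CXCR4"]
_PAN_NAMED = ["CD81-G", "NME2", "BRD7"]


@dataclass
class ClusterProfile:
    """Expected expression of one cluster over the shared feature universe."""

    name: str
    rna_means: pd.Series
    adt_means: pd.Series
    marker_genes: list[str] = field(default_factory=list)
    marker_adts: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.rna_means < 0).any() or (self.adt_means < 0).any():
            raise ValueError(f"profile {self.name!r}: negative mean")
        if not (self.rna_means > 0).any() or not (self.adt_means > 0).any():
            raise ValueError(f"profile {self.name!r}: all-zero means")
        if not self.marker_genes or not self.marker_adts:
            raise ValueError(f"profile {self.name!r}: empty marker sets")


@dataclass
class PatientDesign:
    """Design of one synthetic patient sample."""

    patient_id: str
    composition: dict[str, float]
    bcr_abl1_fraction: float
    signature_effect: float
    n_cells: int
    seed: int

    def __post_init__(self) -> None:
        total = float(sum(self.composition.values()))
        if any(p < 0 for p in self.composition.values()) or abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"patient {self.patient_id!r}: composition must be non-negative "
                f"and sum to 1 (got {total})"
            )
        if not 0.0 <= self.bcr_abl1_fraction <= 1.0:
            raise ValueError(
                f"patient {self.patient_id!r}: bcr_abl1_fraction "
                f"{self.bcr_abl1_fraction} outside [0, 1]"
            )
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")


@dataclass
class SyntheticTruth:
    """Ground-truth records for generated cells and bulk samples.

    ``cells`` is indexed by cell id with columns: cluster, bcr_abl1
    (pos / neg / n/a), hashtag, doublet. ``bulk_fractions`` is a
    samples x clusters table of true mixing fractions.
    """

    cells: pd.DataFrame
    bulk_fractions: pd.DataFrame | None = None


def _check_universe(profiles: list[ClusterProfile]) -> None:
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError("duplicate cluster names among profiles")
    ref = profiles[0]
    for p in profiles[1:]:
        if not p.rna_means.index.equals(ref.rna_means.index) or not (
            p.adt_means.index.equals(ref.adt_means.index)
        ):
            raise ValueError(
                f"profile {p.name!r} has a different feature universe than "
                f"{ref.name!r}"
            )


def default_gene_universe(n_genes: int = 2000) -> list[str]:
    """Feature universe with mitochondrial, ribosomal, signature, pan-CML and
    generic filler genes, in a fixed deterministic order."""
    ribo = [f"RPS{i}" for i in range(1, 26)] + [f"RPL{i}" for i in range(1, 26)]
    sig_up = _SIG_UP_NAMED + [f"LSCG{i:02d}" for i in range(len(_SIG_UP_NAMED) + 1, 51)]
    sig_down = _SIG_DOWN_NAMED + [
        f"HSCG{i:02d}" for i in range(len(_SIG_DOWN_NAMED) + 1, 21)
    ]
    pan = _PAN_NAMED + [f"CMLG{i:02d}" for i in range(len(_PAN_NAMED) + 1, 51)]
    named = MITO_GENES + ribo + sig_up + sig_down + pan
    if n_genes < len(named) + 11 * 20:
        raise ValueError(f"n_genes must be at least {len(named) + 220}")
    filler = [f"GENE{i:04d}" for i in range(1, n_genes - len(named) + 1)]
    return named + filler


def default_signature() -> GeneSignature:
    """The built-in leukemic-stem-cell signature: 50 up / 20 down genes."""
    genes = default_gene_universe()
    up = [g for g in genes if g in _SIG_UP_NAMED or g.startswith("LSCG")]
    down = [g for g in genes if g in _SIG_DOWN_NAMED or g.startswith("HSCG")]
    return GeneSignature(name="bcr_abl1_lsc", up_genes=up, down_genes=down)


def default_pan_cml_genes() -> list[str]:
    genes = default_gene_universe()
    return [g for g in genes if g in _PAN_NAMED or g.startswith("CMLG")]


def default_reference_profiles(
    n_genes: int = 2000,
    n_markers: int = 20,
    marker_boost: float = DEFAULT_MARKER_BOOST,
    adt_boost: float = DEFAULT_ADT_BOOST,
) -> list[ClusterProfile]:
    """Eleven-cluster hematopoietic hierarchy profiles.

    Every cluster shares a baseline expression level; each gets ``n_markers``
    filler genes boosted ``marker_boost``-fold and three ADTs boosted
    ``adt_boost``-fold. Mitochondrial and ribosomal genes run hotter than the
    baseline so QC fractions are realistic.
    """
    genes = default_gene_universe(n_genes)
    gene_idx = pd.Index(genes)
    adts = pd.Index(ADT_PANEL)
    base_rna = pd.Series(1.0, index=gene_idx)
    base_rna[MITO_GENES] = 6.0
    base_rna[[g for g in genes if g.startswith(("RPS", "RPL"))]] = 4.0
    # signature and pan-CML genes sit at a moderate baseline: DE-derived
    # signatures are inherently biased toward robustly detected genes
    base_rna[[g for g in genes
              if g in _SIG_UP_NAMED + _SIG_DOWN_NAMED + _PAN_NAMED
              or g.startswith(("LSCG", "HSCG", "CMLG"))]] = 3.0

    filler = [g for g in genes if g.startswith("GENE")]
    profiles = []
    for i, name in enumerate(CLUSTER_NAMES):
        markers = filler[i * n_markers : (i + 1) * n_markers]
        rna = base_rna.copy()
        rna[markers] *= marker_boost
        adt = pd.Series(10.0, index=adts)
        marker_adts = [ADT_PANEL[(3 * i) % 36], ADT_PANEL[(3 * i + 1) % 36],
                       ADT_PANEL[(3 * i + 2) % 36]]
        adt[marker_adts] *= adt_boost
        profiles.append(
            ClusterProfile(
                name=name,
                rna_means=rna,
                adt_means=adt,
                marker_genes=markers,
                marker_adts=marker_adts,
            )
        )
    return profiles


def default_composition(kind: str = "optimal") -> dict[str, float]:
    """Cluster compositions emulating optimal-responder vs treatment-failure
    patients: failures carry a much larger primitive fraction at diagnosis."""
    if kind == "optimal":
        props = [0.08, 0.10, 0.10, 0.12, 0.08, 0.12, 0.12, 0.10, 0.08, 0.04, 0.06]
    elif kind == "failure":
        props = [0.45, 0.08, 0.07, 0.06, 0.05, 0.06, 0.06, 0.06, 0.05, 0.02, 0.04]
    else:
        raise ValueError(f"unknown composition kind {kind!r}")
    return dict(zip(CLUSTER_NAMES, props))


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """Gamma-Poisson draw with variance mean + phi * mean^2 (phi=0: Poisson)."""
    mean = np.asarray(mean, dtype=np.float64)
    if phi <= 0:
        return rng.poisson(mean)
    lam = np.zeros_like(mean)
    pos = mean > 0
    lam[pos] = rng.gamma(shape=1.0 / phi, scale=mean[pos] * phi)
    return rng.poisson(lam)


def _counts_adata(counts: np.ndarray, cell_ids, features, feature_type: str):
    adata = ad.AnnData(
        X=sp.csr_matrix(counts.astype(np.int64)),
        obs=pd.DataFrame(index=pd.Index(cell_ids, name="cell_id")),
        var=pd.DataFrame(
            {"feature_type": feature_type}, index=pd.Index(features, name="feature")
        ),
    )
    return adata


def _allocate(n_cells: int, weights: list[float]) -> list[int]:
    """Largest-remainder allocation of n_cells across weights."""
    raw = np.asarray(weights, dtype=float) * n_cells
    counts = np.floor(raw).astype(int)
    remainder = n_cells - counts.sum()
    order = np.argsort(-(raw - counts))
    counts[order[:remainder]] += 1
    return counts.tolist()


def _sample_modalities(rng, cluster_sizes, rna_mean_rows, adt_mean_rows,
                       phi, adt_phi, libsize_sd):
    rna_blocks, adt_blocks = [], []
    for size, rna_mu, adt_mu in zip(cluster_sizes, rna_mean_rows, adt_mean_rows):
        factors = np.exp(rng.normal(0.0, libsize_sd, size=size)) if libsize_sd > 0 \
            else np.ones(size)
        rna_blocks.append(_nb_sample(rng, factors[:, None] * rna_mu[None, :], phi))
        adt_blocks.append(_nb_sample(rng, factors[:, None] * adt_mu[None, :], adt_phi))
    return np.vstack(rna_blocks), np.vstack(adt_blocks)


def generate_reference(
    profiles: list[ClusterProfile],
    n_cells: int,
    seed: int,
    phi: float = DEFAULT_PHI,
    adt_phi: float = DEFAULT_PHI,
    libsize_sd: float = DEFAULT_LIBSIZE_SD,
    cell_prefix: str = "ref",
) -> tuple[ad.AnnData, ad.AnnData, SyntheticTruth]:
    """Generate a reference sample with cells split evenly across clusters."""
    _check_universe(profiles)
    if n_cells < len(profiles):
        raise ValueError("n_cells must be at least the number of profiles")
    rng = np.random.default_rng(seed)
    sizes = _allocate(n_cells, [1.0 / len(profiles)] * len(profiles))
    rna, adt = _sample_modalities(
        rng, sizes,
        [p.rna_means.to_numpy() for p in profiles],
        [p.adt_means.to_numpy() for p in profiles],
        phi, adt_phi, libsize_sd,
    )
    clusters = np.repeat([p.name for p in profiles], sizes)
    cell_ids = [f"{cell_prefix}_cell{i:05d}" for i in range(n_cells)]
    truth = SyntheticTruth(
        cells=pd.DataFrame(
            {"cluster": clusters, "bcr_abl1": "n/a", "hashtag": pd.NA,
             "doublet": False},
            index=pd.Index(cell_ids, name="cell_id"),
        )
    )
    genes = profiles[0].rna_means.index
    adts = profiles[0].adt_means.index
    return (
        _counts_adata(rna, cell_ids, genes, "Gene Expression"),
        _counts_adata(adt, cell_ids, adts, "Antibody Capture"),
        truth,
    )


def generate_patient(
    design: PatientDesign,
    profiles: list[ClusterProfile],
    signature: GeneSignature,
    pan_cml_genes: list[str] | None = None,
    cml_effect: float = 1.5,
    cml_effect_sd: float = 0.9,
    leukemic_adts: tuple[str, ...] = ("CD26", "CD25"),
    hsc_adts: tuple[str, ...] = ("CD35",),
    adt_effect: float = LEUKEMIC_ADT_BOOST,
    primitive_cluster: str = "Primitive",
    phi: float = DEFAULT_PHI,
    adt_phi: float = DEFAULT_PHI,
    libsize_sd: float = DEFAULT_LIBSIZE_SD,
) -> tuple[ad.AnnData, ad.AnnData, SyntheticTruth]:
    """Generate one patient sample.

    Cells are allocated to clusters by the design composition. Primitive
    cells split into leukemic (BCR::ABL1+) and non-leukemic sub-states per
    ``bcr_abl1_fraction``: leukemic cells have signature up-genes scaled by
    2**signature_effect, down-genes by 2**-signature_effect, and the leukemic
    surface markers (CD26/CD25) boosted; non-leukemic primitive cells have
    the normal-HSC marker (CD35) boosted. All patient cells additionally
    carry a pan-CML expression shift (``cml_effect`` log2 units on
    ``pan_cml_genes``, varying cell to cell with standard deviation
    ``cml_effect_sd`` log2 units) so that even BCR::ABL1- cells differ from
    a healthy control — mirroring the pan-CML signature seen in patient
    data, whose expression is heterogeneous across cells.
    """
    _check_universe(profiles)
    genes = profiles[0].rna_means.index
    missing = [g for g in signature.up_genes + signature.down_genes
               if g not in genes]
    if missing:
        raise ValueError(f"signature genes absent from feature universe: {missing[:5]}")
    if pan_cml_genes is None:
        pan_cml_genes = [g for g in default_pan_cml_genes() if g in genes]

    by_name = {p.name: p for p in profiles}
    unknown = set(design.composition) - set(by_name)
    if unknown:
        raise ValueError(f"composition references unknown clusters: {sorted(unknown)}")
    order = [c for c in design.composition if design.composition[c] > 0]
    sizes = _allocate(design.n_cells, [design.composition[c] for c in order])

    rng = np.random.default_rng(design.seed)
    up_mask = genes.isin(signature.up_genes)
    down_mask = genes.isin(signature.down_genes)
    pan_mask = genes.isin(pan_cml_genes)

    rna_rows, adt_rows, group_sizes, cluster_lab, status_lab = [], [], [], [], []
    for cname, size in zip(order, sizes):
        prof = by_name[cname]
        base = prof.rna_means.to_numpy().copy()
        base[pan_mask] *= 2.0 ** cml_effect
        adt_base = prof.adt_means.to_numpy()
        adt_index = prof.adt_means.index
        if cname == primitive_cluster and size > 0:
            n_pos = int(rng.binomial(size, design.bcr_abl1_fraction))
            pos_rna = base.copy()
            pos_rna[up_mask] *= 2.0 ** design.signature_effect
            pos_rna[down_mask] *= 2.0 ** -design.signature_effect
            pos_adt = adt_base.copy()
            pos_adt[adt_index.isin(leukemic_adts)] *= adt_effect
            neg_adt = adt_base.copy()
            neg_adt[adt_index.isin(hsc_adts)] *= adt_effect
            for sub_n, sub_rna, sub_adt, status in (
                (n_pos, pos_rna, pos_adt, "pos"),
                (size - n_pos, base, neg_adt, "neg"),
            ):
                if sub_n == 0:
                    continue
                rna_rows.append(sub_rna)
                adt_rows.append(sub_adt)
                group_sizes.append(sub_n)
                cluster_lab.append(cname)
                status_lab.append(status)
        else:
            rna_rows.append(base)
            adt_rows.append(adt_base)
            group_sizes.append(size)
            cluster_lab.append(cname)
            status_lab.append("n/a")

    mean_rna = np.repeat(np.vstack(rna_rows), group_sizes, axis=0)
    mean_adt = np.repeat(np.vstack(adt_rows), group_sizes, axis=0)
    if cml_effect_sd > 0 and pan_mask.any():
        # upward half-normal heterogeneity: every leukemic cell expresses the
        # pan-CML program at least at the clonal floor (cml_effect), varying
        # upward cell to cell
        delta = np.abs(rng.normal(0.0, cml_effect_sd, size=design.n_cells))
        mean_rna[:, pan_mask] *= (2.0 ** delta)[:, None]
    factors = (
        np.exp(rng.normal(0.0, libsize_sd, size=design.n_cells))
        if libsize_sd > 0 else np.ones(design.n_cells)
    )
    rna = _nb_sample(rng, factors[:, None] * mean_rna, phi)
    adt = _nb_sample(rng, factors[:, None] * mean_adt, adt_phi)
    clusters = np.repeat(cluster_lab, group_sizes)
    statuses = np.repeat(status_lab, group_sizes)
    cell_ids = [f"{design.patient_id}_cell{i:05d}" for i in range(design.n_cells)]
    truth = SyntheticTruth(
        cells=pd.DataFrame(
            {"cluster": clusters, "bcr_abl1": statuses, "hashtag": pd.NA,
             "doublet": False},
            index=pd.Index(cell_ids, name="cell_id"),
        )
    )
    adts = profiles[0].adt_means.index
    return (
        _counts_adata(rna, cell_ids, genes, "Gene Expression"),
        _counts_adata(adt, cell_ids, adts, "Antibody Capture"),
        truth,
    )


def generate_hto(
    truth: SyntheticTruth,
    n_hashtags: int,
    doublet_rate: float,
    seed: int,
    background_mean: float = 2.0,
    signal_mean: float = 100.0,
) -> tuple[ad.AnnData, SyntheticTruth]:
    """Generate hashtag counts for the cells in ``truth``.

    Singlets get one high-signal hashtag; a ``doublet_rate`` fraction of
    cells get two. Returns the HTO matrix and a copy of the truth with the
    hashtag identity and doublet flag filled in.
    """
    if n_hashtags < 1:
        raise ValueError("n_hashtags must be at least 1")
    if not 0.0 <= doublet_rate < 1.0:
        raise ValueError("doublet_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    cells = truth.cells.index
    n = len(cells)
    names = [f"HTO_{i + 1}" for i in range(n_hashtags)]

    primary = rng.integers(0, n_hashtags, size=n)
    is_doublet = rng.random(n) < doublet_rate if n_hashtags > 1 else np.zeros(n, bool)
    secondary = (primary + rng.integers(1, max(n_hashtags, 2), size=n)) % n_hashtags

    mean = np.full((n, n_hashtags), background_mean, dtype=float)
    mean[np.arange(n), primary] = signal_mean
    mean[is_doublet, secondary[is_doublet]] = signal_mean
    counts = rng.poisson(mean)

    new_cells = truth.cells.copy()
    new_cells["hashtag"] = [names[p] for p in primary]
    new_cells["doublet"] = is_doublet
    return (
        _counts_adata(counts, cells, names, "Multiplexing Capture"),
        SyntheticTruth(cells=new_cells, bulk_fractions=truth.bulk_fractions),
    )


def generate_bulk(
    profiles: list[ClusterProfile],
    fractions: pd.DataFrame,
    noise_sd: float,
    seed: int,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Generate bulk expression as fraction-weighted sums of cluster means.

    ``fractions`` is a samples x clusters table; each row must be
    non-negative and sum to 1. Multiplicative log-normal noise of standard
    deviation ``noise_sd`` is applied gene-wise (noise_sd=0 yields the exact
    weighted mean).
    """
    _check_universe(profiles)
    by_name = {p.name: p for p in profiles}
    unknown = set(fractions.columns) - set(by_name)
    if unknown:
        raise ValueError(f"fractions reference unknown clusters: {sorted(unknown)}")
    F = fractions.to_numpy(dtype=float)
    if (F < 0).any():
        raise ValueError("negative fractions")
    if not np.allclose(F.sum(axis=1), 1.0, atol=1e-9):
        raise ValueError("each sample's fractions must sum to 1")
    M = np.vstack([by_name[c].rna_means.to_numpy() for c in fractions.columns])
    bulk = F @ M
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        bulk = bulk * np.exp(rng.normal(0.0, noise_sd, size=bulk.shape))
    genes = profiles[0].rna_means.index
    table = pd.DataFrame(bulk, index=fractions.index, columns=genes)
    truth = SyntheticTruth(
        cells=pd.DataFrame(
            columns=["cluster", "bcr_abl1", "hashtag", "doublet"],
            index=pd.Index([], name="cell_id"),
        ),
        bulk_fractions=fractions.copy(),
    )
    return table, truth
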