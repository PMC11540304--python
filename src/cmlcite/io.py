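"""Readers and writers for count matrices and tables.

Count matrices use the 10x-style directory convention: per modality a
directory holding ``matrix.mtx`` (Matrix Market triplet, features x cells),
``features.tsv`` (id, name, feature type) and ``barcodes.tsv``. Truth and
report tables are TSV.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

FEATURE_TYPES = {
    "rna": "Gene Expression",
    "adt": "Antibody Capture",
    "hto": "Multiplexing Capture",
}
_TYPE_TO_MODALITY = {v: k for k, v in FEATURE_TYPES.items()}


def write_counts(directory: str | Path, **modalities: ad.AnnData) -> None:
    """Write modality matrices (e.g. rna=..., adt=..., hto=...) as 10x-style
    MTX subdirectories of ``directory``."""
    directory = Path(directory)
    for name, adata in modalities.items():
        if name not in FEATURE_TYPES:
            raise ValueError(f"unknown modality {name!r}")
        sub = directory / name
        sub.mkdir(parents=True, exist_ok=True)
        matrix = sp.csc_matrix(adata.X.T)  # features x cells
        scipy.io.mmwrite(str(sub / "matrix.mtx"), matrix, field="integer")
        feature_type = adata.var.get(
            "feature_type", pd.Series(FEATURE_TYPES[name], index=adata.var_names)
        )
        pd.DataFrame(
            {
                "id": adata.var_names,
                "name": adata.var_names,
                "type": np.asarray(feature_type),
            }
        ).to_csv(sub / "features.tsv", sep="\t", header=False, index=False)
        pd.Series(adata.obs_names).to_csv(
            sub / "barcodes.tsv", sep="\t", header=False, index=False
        )


def _first_malformed_line(path: Path) -> int | None:
    """Locate the first malformed triplet line of an MTX file, if any."""
    with open(path) as fh:
        in_body = False
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped.startswith("%") or not stripped:
                continue
            fields = stripped.split()
            if not in_body:
                in_body = True  # size line
                ok = len(fields) == 3 and all(f.isdigit() for f in fields)
            else:
                ok = len(fields) == 3 and fields[0].isdigit() and fields[1].isdigit()
                if ok:
                    try:
                        float(fields[2])
                    except ValueError:
                        ok = False
            if not ok:
                return lineno
    return None


def _read_one(directory: Path) -> ad.AnnData:
    mtx_path = directory / "matrix.mtx"
    try:
        matrix = scipy.io.mmread(str(mtx_path))
    except Exception as exc:
        lineno = _first_malformed_line(mtx_path)
        where = f"{mtx_path}:{lineno}" if lineno else str(mtx_path)
        raise ValueError(f"malformed Matrix Market file at {where}: {exc}") from exc
    features = pd.read_csv(
        directory / "features.tsv", sep="\t", header=None,
        names=["id", "name", "type"],
    )
    barcodes = pd.read_csv(
        directory / "barcodes.tsv", sep="\t", header=None, names=["barcode"]
    )["barcode"]
    dup = barcodes[barcodes.duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicated barcode(s): {dup.unique().tolist()[:5]}")
    X = sp.csr_matrix(matrix.T)
    if X.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"{directory}: matrix shape {X.shape} does not match "
            f"{len(barcodes)} barcodes x {len(features)} features"
        )
    return ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="cell_id")),
        var=pd.DataFrame(
            {"feature_type": features["type"].to_numpy()},
            index=pd.Index(features["id"], name="feature"),
        ),
    )


def read_counts(directory: str | Path) -> dict[str, ad.AnnData]:
    """Read a sample directory into per-modality matrices.

    Accepts either a directory with modality subdirectories (rna/adt/hto)
    or a single-modality directory holding matrix.mtx directly; the
    modality is identified from the feature type column.
    """
    directory = Path(directory)
    out: dict[str, ad.AnnData] = {}
    if (directory / "matrix.mtx").exists():
        adata = _read_one(directory)
        types = adata.var["feature_type"].unique()
        for t in types:
            modality = _TYPE_TO_MODALITY.get(t)
            if modality is None:
                raise ValueError(f"unknown feature type {t!r}")
            out[modality] = adata[:, (adata.var["feature_type"] == t).to_numpy()].copy()
        return out
    for name in FEATURE_TYPES:
        if (directory / name / "matrix.mtx").exists():
            out[name] = _read_one(directory / name)
    if not out:
        raise FileNotFoundError(f"no count matrices found under {directory}")
    return out


def write_truth(truth, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    truth.cells.to_csv(directory / "truth_cells.tsv", sep="\t")
    if truth.bulk_fractions is not None:
        truth.bulk_fractions.to_csv(directory / "truth_bulk_fractions.tsv", sep="\t")


def read_truth(directory: str | Path):
    from .synthetic import SyntheticTruth

    directory = Path(directory)
    cells = pd.read_csv(directory / "truth_cells.tsv", sep="\t", index_col=0)
    bulk_path = directory / "truth_bulk_fractions.tsv"
    bulk = pd.read_csv(bulk_path, sep="\t", index_col=0) if bulk_path.exists() else None
    return SyntheticTruth(cells=cells, bulk_fractions=bulk)
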