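"""Readers and writers for the 10x-style MatrixMarket directory layout.

A cohort matrix directory holds ``matrix.mtx`` (genes x cells, integer UMI
counts or log2-normalized reals), ``features.tsv`` and ``barcodes.tsv``.
An optional ``layer.json`` sidecar records whether the matrix holds raw
counts or log2-normalized values.

In memory the matrix is an :class:`anndata.AnnData` with cells as ``obs``
and genes as ``var`` (the scanpy convention); gene flags live in ``var``
(``is_mito``, ``is_ychrom``) and the layer tag in ``uns["layer"]``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

DEFAULT_MITO_PREFIXES: tuple[str, ...] = ("mt-",)
DEFAULT_Y_GENES: tuple[str, ...] = ("Ddx3y", "Eif2s3y", "Uty", "Kdm5d")

LAYER_KEY = "layer"
LAYER_RAW = "raw"
LAYER_LOGNORM = "lognorm"


def annotate_genes(
    adata: ad.AnnData,
    mito_prefixes: Sequence[str] = DEFAULT_MITO_PREFIXES,
    y_genes: Iterable[str] = DEFAULT_Y_GENES,
) -> ad.AnnData:
    """Attach ``is_mito`` / ``is_ychrom`` flags to ``adata.var`` in place."""
    prefixes = tuple(p.lower() for p in mito_prefixes)
    names = adata.var_names.astype(str)
    adata.var["is_mito"] = np.array([n.lower().startswith(prefixes) for n in names])
    yset = set(y_genes)
    adata.var["is_ychrom"] = np.array([n in yset for n in names])
    return adata


def layer_of(adata: ad.AnnData) -> str:
    return str(adata.uns.get(LAYER_KEY, LAYER_RAW))


def write_matrix_dir(adata: ad.AnnData, out_dir: str | Path) -> dict[str, Path]:
    """Write an AnnData as a 10x-style MTX trio plus the layer sidecar.

    The on-disk matrix is genes x cells, matching the 10x convention.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        mat = sp.csc_matrix(adata.X).T  # genes x cells
        paths = {
            "matrix": out / "matrix.mtx",
            "features": out / "features.tsv",
            "barcodes": out / "barcodes.tsv",
            "layer": out / "layer.json",
        }
        scipy.io.mmwrite(paths["matrix"], mat)
        feat = pd.DataFrame(
            {
                "id": adata.var_names,
                "name": adata.var_names,
                "feature_type": "Gene Expression",
            }
        )
        feat.to_csv(paths["features"], sep="\t", header=False, index=False)
        pd.Series(adata.obs_names).to_csv(paths["barcodes"], header=False, index=False)
        paths["layer"].write_text(json.dumps({LAYER_KEY: layer_of(adata)}) + "\n")
    except OSError as exc:
        raise OSError(f"failed writing matrix directory {out}: {exc}") from exc
    return paths


def read_matrix_dir(
    in_dir: str | Path,
    mito_prefixes: Sequence[str] = DEFAULT_MITO_PREFIXES,
    y_genes: Iterable[str] = DEFAULT_Y_GENES,
) -> ad.AnnData:
    """Read a matrix directory written by :func:`write_matrix_dir`."""
    d = Path(in_dir)
    mat = scipy.io.mmread(d / "matrix.mtx").tocsr().T.tocsr()  # cells x genes
    feat = pd.read_csv(d / "features.tsv", sep="\t", header=None, dtype=str)
    barcodes = pd.read_csv(d / "barcodes.tsv", header=None, dtype=str)[0].tolist()
    layer = LAYER_RAW
    sidecar = d / "layer.json"
    if sidecar.exists():
        layer = json.loads(sidecar.read_text()).get(LAYER_KEY, LAYER_RAW)
    if layer == LAYER_RAW:
        mat = mat.astype(np.int64)
    adata = ad.AnnData(
        X=mat,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(feat[0].tolist(), name="gene")),
    )
    adata.uns[LAYER_KEY] = layer
    annotate_genes(adata, mito_prefixes=mito_prefixes, y_genes=y_genes)
    return adata


def y_gene_totals(adata: ad.AnnData) -> pd.Series:
    """Per-cell total raw UMIs over Y-chromosome-flagged genes."""
    mask = np.asarray(adata.var["is_ychrom"], dtype=bool)
    if mask.sum() == 0:
        return pd.Series(0, index=adata.obs_names, dtype=np.int64)
    tot = np.asarray(adata.X[:, mask].sum(axis=1)).ravel()
    return pd.Series(tot, index=adata.obs_names)


def read_cluster_labels(path: str | Path) -> pd.Series:
    """Read a barcode -> cluster TSV (two columns, with header)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"cluster table {path} must have barcode and cluster columns")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="cluster")


def write_cluster_labels(labels: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"barcode": labels.index, "cluster": labels.values}).to_csv(
        path, sep="\t", index=False
    )
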