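"""Cell quality control and log2 size-factor normalization.

Cells with fewer than 1000 total UMIs, or with more than 10% of UMIs coming
from mitochondrial genes, are droplets of low quality (dying cells leak
cytoplasmic RNA while mitochondrial transcripts persist) and are excluded.
Surviving cells are normalized by a per-cell size factor and the counts
log2-transformed with a pseudocount of 1.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .tenx import LAYER_KEY, LAYER_LOGNORM, LAYER_RAW, layer_of

REASON_PASS = "pass"
REASON_LOW_UMI = "low_umi"
REASON_HIGH_MITO = "high_mito"


def _require_raw(adata: ad.AnnData) -> None:
    if layer_of(adata) != LAYER_RAW:
        raise ValueError(f"expected a raw-count matrix, got layer={layer_of(adata)!r}")


def _totals(adata: ad.AnnData) -> np.ndarray:
    return np.asarray(adata.X.sum(axis=1)).ravel()


def qc_filter(
    adata: ad.AnnData, min_umi: int = 1000, max_mito: float = 0.10
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Remove low-UMI and high-mitochondrial-fraction cells.

    Returns the filtered matrix (gene set unchanged) and a per-cell report
    with columns ``total_umi``, ``mito_frac``, ``kept`` and ``reason``.
    A cell failing both rules is reported as ``low_umi`` (checked first).
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("cannot QC an empty matrix")
    _require_raw(adata)
    totals = _totals(adata)
    if "is_mito" in adata.var and bool(np.asarray(adata.var["is_mito"]).any()):
        mito_mask = np.asarray(adata.var["is_mito"], dtype=bool)
        mito = np.asarray(adata.X[:, mito_mask].sum(axis=1)).ravel()
        with np.errstate(divide="ignore", invalid="ignore"):
            mito_frac = np.where(totals > 0, mito / np.maximum(totals, 1), 0.0)
    else:
        warnings.warn("no mitochondrial genes flagged; mito fraction set to 0")
        mito_frac = np.zeros(adata.n_obs)
    reason = np.full(adata.n_obs, REASON_PASS, dtype=object)
    reason[mito_frac > max_mito] = REASON_HIGH_MITO
    reason[totals < min_umi] = REASON_LOW_UMI
    kept = reason == REASON_PASS
    report = pd.DataFrame(
        {
            "total_umi": totals.astype(np.int64),
            "mito_frac": mito_frac,
            "kept": kept,
            "reason": reason,
        },
        index=adata.obs_names.copy(),
    )
    report.index.name = "barcode"
    return adata[kept].copy(), report


def size_factors(adata: ad.AnnData) -> np.ndarray:
    """Library-size factors scaled to mean 1.

    Pooled-deconvolution factors computed elsewhere can be substituted via
    the ``factors`` argument of :func:`lognormalize`.
    """
    _require_raw(adata)
    totals = _totals(adata)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cells with zero total counts cannot be normalized: "
            f"{list(adata.obs_names[zero[:5]])}"
        )
    return totals / totals.mean()


def lognormalize(adata: ad.AnnData, factors: np.ndarray | None = None) -> ad.AnnData:
    """log2(count / size_factor + 1) per cell; zeros stay zero."""
    _require_raw(adata)
    if factors is None:
        factors = size_factors(adata)
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (adata.n_obs,):
        raise ValueError(f"expected {adata.n_obs} size factors, got {factors.shape}")
    if np.any(factors <= 0):
        raise ValueError("size factors must be strictly positive")
    x = sp.csr_matrix(adata.X, dtype=float)
    scaled = sp.diags(1.0 / factors) @ x
    scaled = sp.csr_matrix(scaled)
    scaled.data = np.log2(scaled.data + 1.0)
    out = ad.AnnData(X=scaled, obs=adata.obs.copy(), var=adata.var.copy())
    out.uns.update(adata.uns)
    out.uns[LAYER_KEY] = LAYER_LOGNORM
    return out
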