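"""Signature scoring and trajectory start-cell selection.

The signature score of a cell is the average Z-score of its log2-normalized
counts over a marker gene set: each gene is standardized across cells
(population standard deviation) and the score is the mean of the
standardized values over the signature genes. The start cell for a
trajectory is the cell with the highest score within a designated cluster.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from .tenx import LAYER_LOGNORM, layer_of


def signature_score(
    adata: ad.AnnData, genes: Iterable[str], name: str = "signature"
) -> pd.Series:
    """Per-cell average Z-score of log2-normalized counts of ``genes``.

    Genes absent from the matrix are dropped (duplicates removed); an empty
    intersection is an error. Genes with zero variance across cells
    contribute a Z of 0 (logged as a warning).
    """
    if layer_of(adata) != LAYER_LOGNORM:
        raise ValueError("signature_score expects a log2-normalized matrix")
    wanted = list(dict.fromkeys(genes))
    present = [g for g in wanted if g in adata.var_names]
    if not present:
        raise ValueError(f"signature {name!r} has no genes in the matrix")
    x = adata[:, present].X
    x = x.toarray() if sp.issparse(x) else np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)  # population formula (ddof=0), fixed for reproducibility
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"signature {name!r}: {int(flat.sum())} constant genes contribute 0"
        )
    z = np.zeros_like(x)
    nz = ~flat
    z[:, nz] = (x[:, nz] - mu[nz]) / sd[nz]
    return pd.Series(z.mean(axis=1), index=adata.obs_names, name=name)


def select_start_cell(
    scores: pd.Series, cluster_labels: Mapping[str, str], cluster_id: str
) -> str:
    """Barcode of the highest-scoring cell within ``cluster_id``.

    Ties are broken toward the lexicographically smallest barcode (logged).
    """
    members = [bc for bc in scores.index if str(cluster_labels.get(bc)) == str(cluster_id)]
    if not members:
        raise ValueError(f"cluster {cluster_id!r} has no scored cells")
    sub = scores.loc[members]
    best = sub.max()
    winners = sorted(sub.index[sub == best])
    if len(winners) > 1:
        warnings.warn(
            f"{len(winners)} cells tie at score {best:.6g}; "
            f"choosing {winners[0]} lexicographically"
        )
    return winners[0]
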