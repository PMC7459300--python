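"""Clonotype repertoire statistics.

Covers the descriptive statistics used to characterize clonal selection of
innate T cells: per-clonotype repeat spectra, Shannon equitability of
clonotype frequencies per cluster, clonotypes shared between cluster
regions, CDR3 length histograms, positional amino-acid composition at the
modal CDR3 length, and canonical / non-canonical TCR classification.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .demux import DemuxRules
from .tcr import CellChains, clonotype_key, normalize_gene

#: WebLogo hydrophobicity color scheme classes.
HYDROPHILIC = frozenset("RKDENQ")
NEUTRAL = frozenset("SGHTAP")
HYDROPHOBIC = frozenset("CVLIMFWY")

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: Restricted ("oligoclonal") Vbeta segments characteristic of each
#: invariant cell type (Vbeta8.1-8.3/Vbeta7/Vbeta2 for iNKT, Vbeta6/Vbeta8
#: for MAIT). Overridable in :func:`classify_canonical`.
DEFAULT_OLIGOCLONAL_VB: dict[str, frozenset[str]] = {
    "iNKT": frozenset({"TRBV13-1", "TRBV13-2", "TRBV13-3", "TRBV29", "TRBV1"}),
    "MAIT": frozenset({"TRBV19", "TRBV13-1", "TRBV13-2", "TRBV13-3"}),
}


def percent(
    numerator: float, denominator: float, decimals: int = 1, mode: str = "floor"
) -> float:
    """Percentage formatter matching the reported-value convention.

    ``floor`` truncates at the requested precision (17/1760 -> 0.96 at two
    decimals; 359/1665 -> 21 at zero decimals); ``round`` is half-even.
    """
    if denominator == 0:
        raise ValueError("percent undefined for a zero denominator")
    x = numerator / denominator * 100.0
    scale = 10**decimals
    if mode == "floor":
        return math.floor(x * scale + 1e-9) / scale
    if mode == "round":
        return round(x * scale) / scale
    raise ValueError(f"unknown mode {mode!r}")


def shannon_equitability(counts: Sequence[float]) -> float:
    """Shannon entropy of clonotype frequencies normalized by ln(richness).

    Lies in [0, 1]; 1 is a perfectly even repertoire. A single clonotype is
    defined as 0 (trivially maximally uneven).
    """
    arr = np.asarray(list(counts), dtype=float)
    if arr.size == 0:
        raise ValueError("shannon_equitability requires at least one clonotype")
    if np.any(arr <= 0):
        raise ValueError("clonotype counts must be positive")
    if arr.size == 1:
        return 0.0
    p = arr / arr.sum()
    h = -float(np.sum(p * np.log(p)))
    return h / math.log(arr.size)


def build_clonotype_table(
    cells: Mapping[str, CellChains],
    cluster_labels: Mapping[str, str] | None = None,
    barcodes: Iterable[str] | None = None,
    level: str = "nt",
) -> pd.DataFrame:
    """One row per distinct clonotype with total and per-cluster cell counts.

    ``barcodes`` restricts the table to one assigned cell type. Cell counts
    are conserved: the ``n_cells`` column sums to the number of keyed cells.
    """
    use = sorted(set(barcodes) & set(cells)) if barcodes is not None else sorted(cells)
    keys = {bc: clonotype_key(cells[bc], level=level) for bc in use}
    clusters = sorted({str(cluster_labels[bc]) for bc in use if bc in cluster_labels}) if cluster_labels else []
    rows: dict[str, dict] = {}
    for bc in use:
        key = keys[bc]
        row = rows.setdefault(
            key, {"n_cells": 0, "chains": key, **{c: 0 for c in clusters}}
        )
        row["n_cells"] += 1
        if cluster_labels and bc in cluster_labels:
            row[str(cluster_labels[bc])] += 1
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "clonotype"
    if not table.empty:
        table = table.sort_values("n_cells", ascending=False)
    table.attrs["cluster_columns"] = clusters
    return table


def repeat_spectrum(table: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Clone-size spectrum: per size, how many clonotypes and cells.

    Also returns a summary with singleton fractions, the count of
    clonotypes repeated more than three times, and the normalized
    clonotype-frequency curve used for cumulative repeat plots.
    """
    if table.empty:
        raise ValueError("repeat_spectrum requires a non-empty clonotype table")
    sizes = table["n_cells"].astype(int)
    n_clonotypes, n_cells = int(len(sizes)), int(sizes.sum())
    spec = (
        sizes.value_counts()
        .sort_index()
        .rename("n_clonotypes")
        .to_frame()
    )
    spec.index.name = "clone_size"
    spec["n_cells"] = spec.index * spec["n_clonotypes"]
    spec["frac_clonotypes"] = spec["n_clonotypes"] / n_clonotypes
    spec["frac_cells"] = spec["n_cells"] / n_cells
    assert int(spec["n_clonotypes"].sum()) == n_clonotypes
    assert int(spec["n_cells"].sum()) == n_cells
    singleton_clonotypes = int(spec.loc[spec.index == 1, "n_clonotypes"].sum())
    gt3 = int(sizes.gt(3).sum())
    summary = {
        "n_clonotypes": n_clonotypes,
        "n_cells": n_cells,
        "singleton_clonotypes": singleton_clonotypes,
        "singleton_cells": singleton_clonotypes,
        "singleton_clonotype_pct": percent(singleton_clonotypes, n_clonotypes, 0),
        "singleton_cell_pct": percent(singleton_clonotypes, n_cells, 0),
        "repeated_gt3_clonotypes": gt3,
        "repeated_gt3_clonotype_pct": percent(gt3, n_clonotypes, 1),
    }
    return spec, summary


def cluster_sharing(
    table: pd.DataFrame,
    region_a: Iterable[str],
    region_b: Iterable[str],
) -> dict:
    """Clonotypes present in both cluster regions and their cell shares.

    ``total_repeats`` is the table-wide cell count of shared clonotypes;
    percentages are over all cells and over "repetitive" cells (cells whose
    clonotype has size >= 2), truncated as reported.
    """
    region_a, region_b = [str(c) for c in region_a], [str(c) for c in region_b]
    known = set(table.attrs.get("cluster_columns", table.columns))
    unknown = [c for c in region_a + region_b if c not in known]
    if unknown:
        raise ValueError(f"unknown cluster ids: {unknown}")
    in_a = table[region_a].sum(axis=1) >= 1
    in_b = table[region_b].sum(axis=1) >= 1
    shared = table.index[in_a & in_b]
    total_repeats = int(table.loc[shared, "n_cells"].sum())
    n_cells = int(table["n_cells"].sum())
    repetitive_cells = int(table.loc[table["n_cells"] >= 2, "n_cells"].sum())
    return {
        "shared_clonotypes": list(shared),
        "n_shared": int(len(shared)),
        "total_repeats": total_repeats,
        "pct_of_cells": percent(total_repeats, n_cells, 0) if n_cells else 0.0,
        "pct_of_repetitive_cells": (
            percent(total_repeats, repetitive_cells, 0) if repetitive_cells else 0.0
        ),
    }


def cdr3_length_hist(
    cells: Mapping[str, CellChains],
    chain: str,
    select: Callable[[tuple[str, str, str, str]], bool] | None = None,
) -> dict[int, int]:
    """Histogram of amino-acid CDR3 lengths over cells, for one locus.

    Cells carrying multiple distinct chains of the locus contribute each
    chain once. ``select`` optionally restricts to a chain partition (e.g.
    canonical vs non-canonical, or a single V gene).
    """
    hist: Counter[int] = Counter()
    multi = 0
    for cell in cells.values():
        chains = [c for c in cell.locus(chain) if select is None or select(c)]
        if len(cell.locus(chain)) > 1:
            multi += 1
        for _, _, _, aa in chains:
            if aa:
                hist[len(aa)] += 1
    if multi:
        warnings.warn(
            f"{multi} cells carry multiple {chain} chains; each chain counted once"
        )
    return dict(sorted(hist.items()))


def hydropathy_class(residue: str) -> str:
    if residue in HYDROPHILIC:
        return "hydrophilic"
    if residue in NEUTRAL:
        return "neutral"
    if residue in HYDROPHOBIC:
        return "hydrophobic"
    raise ValueError(f"unknown residue {residue!r}")


@dataclass(frozen=True)
class LogoMatrix:
    """Positional relative amino-acid frequencies at the modal CDR3 length."""

    modal_length: int
    frequencies: pd.DataFrame  # positions (1-based) x residues, rows sum to 1
    classes: Mapping[str, str]


def composition_logo(sequences: Iterable[str]) -> LogoMatrix:
    """Relative amino-acid composition for the most common sequence length.

    Only sequences of exactly the modal length contribute; a modal-length
    tie is broken toward the shorter length (logged as a warning).
    """
    seqs = [s for s in sequences if s]
    if not seqs:
        raise ValueError("composition_logo requires at least one sequence")
    by_len = Counter(len(s) for s in seqs)
    top = max(by_len.values())
    modal_candidates = sorted(L for L, n in by_len.items() if n == top)
    modal = modal_candidates[0]
    if len(modal_candidates) > 1:
        warnings.warn(
            f"modal-length tie {modal_candidates}; using the shorter ({modal})"
        )
    use = [s for s in seqs if len(s) == modal]
    mat = pd.DataFrame(
        0.0, index=pd.RangeIndex(1, modal + 1, name="position"), columns=list(AA_ALPHABET)
    )
    for s in use:
        for pos, aa in enumerate(s, start=1):
            mat.loc[pos, aa] += 1.0
    mat = mat.div(float(len(use)))
    classes = {aa: hydropathy_class(aa) for aa in AA_ALPHABET}
    return LogoMatrix(modal_length=modal, frequencies=mat, classes=classes)


def classify_canonical(
    cells: Mapping[str, CellChains],
    cell_type: str,
    rules: DemuxRules | None = None,
    oligoclonal_vb: Iterable[str] | None = None,
    cluster_labels: Mapping[str, str] | None = None,
    exclude_both: bool = False,
) -> tuple[pd.DataFrame, dict, pd.DataFrame | None]:
    """Per-cell canonical-alpha / oligoclonal-beta classification.

    A cell (with at least one TRA) is non-canonical-alpha when no alpha
    chain matches the type's canonical V/J pair, and non-oligoclonal-beta
    when it has at least one TRB and none uses a configured oligoclonal V
    segment; cells without a TRB are excluded from beta denominators.

    Returns the per-cell table, the Venn partition counts over the four
    classes, and (when cluster labels are given) per-cluster fractions of
    cells with at least one non-canonical alpha and/or non-oligoclonal
    beta. ``exclude_both`` recomputes the cluster fractions after dropping
    cells in the ``both`` class (the contamination-control re-analysis).
    """
    rules = rules or DemuxRules()
    if cell_type not in ("iNKT", "MAIT"):
        raise ValueError("canonical classification applies to iNKT or MAIT cells")
    vb = frozenset(normalize_gene(v) for v in (oligoclonal_vb or DEFAULT_OLIGOCLONAL_VB[cell_type]))
    is_canon = rules.is_inkt_alpha if cell_type == "iNKT" else rules.is_mait_alpha
    rows = []
    no_trb = 0
    for bc in sorted(cells):
        cell = cells[bc]
        tra = cell.locus("TRA")
        if not tra:
            continue
        canonical_alpha = any(is_canon(v, j) for v, j, _, _ in tra)
        trb = cell.locus("TRB")
        if trb:
            oligo_beta = any(normalize_gene(v) in vb for v, _, _, _ in trb)
        else:
            oligo_beta = None
            no_trb += 1
        nc_a = not canonical_alpha
        nob_b = (oligo_beta is False) if oligo_beta is not None else False
        if nc_a and nob_b:
            klass = "both"
        elif nc_a:
            klass = "nc_alpha_only"
        elif nob_b:
            klass = "nob_beta_only"
        else:
            klass = "canonical_only"
        rows.append(
            {
                "barcode": bc,
                "canonical_alpha": canonical_alpha,
                "oligoclonal_beta": oligo_beta,
                "class": klass,
            }
        )
    if no_trb:
        warnings.warn(f"{no_trb} cells lack a TRB; excluded from beta denominators")
    flags = pd.DataFrame(rows).set_index("barcode") if rows else pd.DataFrame(
        columns=["canonical_alpha", "oligoclonal_beta", "class"]
    )
    venn = {
        k: int((flags["class"] == k).sum())
        for k in ("canonical_only", "nc_alpha_only", "nob_beta_only", "both")
    }
    per_cluster = None
    if cluster_labels is not None and not flags.empty:
        sub = flags.drop(index=flags.index[flags["class"] == "both"]) if exclude_both else flags
        lab = pd.Series({bc: str(cluster_labels[bc]) for bc in sub.index if bc in cluster_labels})
        recs = []
        for cluster, members in lab.groupby(lab):
            cls = sub.loc[members.index, "class"]
            n = int(len(cls))
            n_nc = int((cls != "canonical_only").sum())
            recs.append(
                {
                    "cluster": cluster,
                    "n_cells": n,
                    "n_noncanonical": n_nc,
                    "pct_noncanonical": percent(n_nc, n, 1) if n else 0.0,
                }
            )
        per_cluster = pd.DataFrame(recs).set_index("cluster")
    return flags, venn, per_cluster
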