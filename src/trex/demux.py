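"""Demultiplexing of pooled iNKT / MAIT / gamma-delta T cells.

In the pooling design, iNKT cells come from male mice and MAIT cells from
female mice, so cell type can be recovered per droplet by combining sex
(Y-chromosome gene expression) with TCR genotype:

* iNKT: carries the canonical Valpha14-Jalpha18 (TRAV11/TRAV11D-TRAJ18)
  TCRalpha rearrangement;
* MAIT: carries the canonical Valpha19-Jalpha33 (TRAV1-TRAJ33) TCRalpha
  rearrangement and expresses no Y-chromosomal genes;
* gamma-delta: carries productive TCRgamma and TCRdelta rearrangements.

Droplets with both a productive TRA and TRD, or with both canonical alpha
rearrangements, contain two cells and are removed. Remaining unassigned
cells are rescued by the majority type of their transcriptome cluster
(strictly more than 80% of assigned members), and cells assigned to a
minority type inside such clusters are removed as putative doublets. A
final TCR fallback annotates leftovers in mixed clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .tcr import CellChains, normalize_gene
from .tenx import DEFAULT_Y_GENES

TYPES = ("iNKT", "MAIT", "gdT")

TYPE_INKT = "iNKT"
TYPE_MAIT = "MAIT"
TYPE_GDT = "gdT"
UNASSIGNED = "unassigned"
REMOVED_DOUBLET = "removed_doublet"

PASS_TCR = "1_tcr"
PASS_RESCUE = "2_cluster_rescue"
PASS_FALLBACK = "3_tcr_fallback"
PASS_DOUBLET = "doublet"


@dataclass(frozen=True)
class DemuxRules:
    """Gene rules and thresholds driving the assignment passes."""

    inkt_v: frozenset[str] = frozenset({"TRAV11"})
    inkt_j: str = "TRAJ18"
    mait_v_family: str = "TRAV1"
    mait_j: str = "TRAJ33"
    y_genes: tuple[str, ...] = DEFAULT_Y_GENES
    majority_threshold: float = 0.80
    y_tolerance: int = 0
    require_male_inkt: bool = False

    def __post_init__(self) -> None:
        if not (0.5 < self.majority_threshold <= 1.0):
            raise ValueError("majority_threshold must lie in (0.5, 1]")
        if not self.inkt_v or not self.y_genes:
            raise ValueError("gene lists must be non-empty")

    def is_inkt_alpha(self, v: str, j: str) -> bool:
        return normalize_gene(v) in self.inkt_v and normalize_gene(j) == self.inkt_j

    def is_mait_alpha(self, v: str, j: str) -> bool:
        return self.is_mait_v(v) and normalize_gene(j) == self.mait_j

    def is_mait_v(self, v: str) -> bool:
        # Family match: TRAV1 and dialects such as TRAV1-1, but never TRAV11.
        nv = normalize_gene(v)
        return nv == self.mait_v_family or nv.startswith(self.mait_v_family + "-")


def _has_inkt_alpha(cell: CellChains, rules: DemuxRules) -> bool:
    return any(rules.is_inkt_alpha(v, j) for v, j, _, _ in cell.locus("TRA"))


def _has_mait_alpha(cell: CellChains, rules: DemuxRules) -> bool:
    return any(rules.is_mait_alpha(v, j) for v, j, _, _ in cell.locus("TRA"))


def assign_by_tcr(
    cells: Mapping[str, CellChains],
    y_totals: Mapping[str, int],
    rules: DemuxRules | None = None,
    barcodes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """First pass: assign each barcode by TCR genotype and sex.

    ``y_totals`` maps every barcode in the expression matrix to its raw UMI
    total over Y-chromosome genes. ``barcodes`` defaults to the union of
    ``cells`` and ``y_totals`` keys; contig barcodes absent from the
    expression matrix are warned about and left unassigned.
    """
    rules = rules or DemuxRules()
    if barcodes is None:
        all_bcs = sorted(set(cells) | set(y_totals))
    else:
        all_bcs = sorted(set(barcodes))
    missing = sorted(set(cells) - set(y_totals))
    if missing:
        warnings.warn(
            f"{len(missing)} barcodes have contigs but no expression data; "
            "left unassigned"
        )
    rows = []
    for bc in all_bcs:
        cell = cells.get(bc)
        atype, trace = UNASSIGNED, "no_usable_contigs"
        if cell is not None and bc in y_totals:
            y = int(y_totals[bc])
            male = y > rules.y_tolerance
            inkt = _has_inkt_alpha(cell, rules) and (male or not rules.require_male_inkt)
            mait = _has_mait_alpha(cell, rules) and not male
            gd = cell.has("TRG") and cell.has("TRD")
            if inkt:
                atype, trace = TYPE_INKT, "canonical_inkt_alpha"
            elif mait:
                atype, trace = TYPE_MAIT, "canonical_mait_alpha_no_y"
            elif gd:
                atype, trace = TYPE_GDT, "productive_trg_trd"
            elif _has_mait_alpha(cell, rules) and male:
                atype, trace = UNASSIGNED, "mait_alpha_but_male"
            else:
                atype, trace = UNASSIGNED, "no_rule_matched"
        df_row = {"barcode": bc, "assigned_type": atype, "pass_id": PASS_TCR, "rule_trace": trace}
        rows.append(df_row)
    df = pd.DataFrame(rows).set_index("barcode")
    return df


def flag_doublets(
    assignments: pd.DataFrame,
    cells: Mapping[str, CellChains],
    rules: DemuxRules | None = None,
) -> pd.DataFrame:
    """Remove droplets whose TCR content implies two cells.

    A cell with at least one productive TRA and one productive TRD, or with
    both canonical iNKT and MAIT alpha rearrangements, becomes
    ``removed_doublet`` regardless of its prior label.
    """
    rules = rules or DemuxRules()
    out = assignments.copy()
    for bc, cell in cells.items():
        if bc not in out.index:
            continue
        tra_trd = cell.has("TRA") and cell.has("TRD")
        dual = _has_inkt_alpha(cell, rules) and _has_mait_alpha(cell, rules)
        if tra_trd or dual:
            out.loc[bc, ["assigned_type", "pass_id", "rule_trace"]] = [
                REMOVED_DOUBLET,
                PASS_DOUBLET,
                "tra_and_trd" if tra_trd else "dual_canonical_alpha",
            ]
    return out


def cluster_rescue(
    assignments: pd.DataFrame,
    cluster_labels: Mapping[str, str],
    rules: DemuxRules | None = None,
) -> tuple[pd.DataFrame, set[str]]:
    """Second pass: rescue unassigned cells by cluster majority.

    Majority fractions are computed among already-assigned cells only. In
    clusters whose top type strictly exceeds the threshold, unassigned
    members take the majority type and assigned-but-minority members are
    removed as putative doublets. Returns the updated assignments and the
    set of rescued cluster ids (the rest are "mixed").
    """
    rules = rules or DemuxRules()
    out = assignments.copy()
    labels = pd.Series(
        {bc: cluster_labels[bc] for bc in out.index if bc in cluster_labels}
    )
    rescued: set[str] = set()
    for cluster, members in labels.groupby(labels):
        bcs = members.index
        types = out.loc[bcs, "assigned_type"]
        assigned = types[types.isin(TYPES)]
        if assigned.empty:
            warnings.warn(f"cluster {cluster!r} has no assigned cells; skipped")
            continue
        counts = assigned.value_counts()
        major, frac = counts.index[0], counts.iloc[0] / len(assigned)
        if frac <= rules.majority_threshold:
            continue
        rescued.add(str(cluster))
        for bc in bcs:
            cur = out.loc[bc, "assigned_type"]
            if cur == UNASSIGNED:
                out.loc[bc, ["assigned_type", "pass_id", "rule_trace"]] = [
                    major,
                    PASS_RESCUE,
                    f"cluster_majority_{frac:.2f}",
                ]
            elif cur in TYPES and cur != major:
                out.loc[bc, ["assigned_type", "pass_id", "rule_trace"]] = [
                    REMOVED_DOUBLET,
                    PASS_DOUBLET,
                    "cluster_minority",
                ]
    return out, rescued


def tcr_fallback(
    assignments: pd.DataFrame,
    cells: Mapping[str, CellChains],
    cluster_labels: Mapping[str, str],
    mixed_clusters: Iterable[str],
    rules: DemuxRules | None = None,
) -> pd.DataFrame:
    """Third pass: TCR-expression fallback inside mixed clusters.

    Still-unassigned cells expressing any TRAV1-family alpha become MAIT;
    cells with V segments for both TCRgamma and TCRdelta become gdT.
    """
    rules = rules or DemuxRules()
    mixed = set(str(c) for c in mixed_clusters)
    out = assignments.copy()
    for bc in out.index[out["assigned_type"] == UNASSIGNED]:
        if str(cluster_labels.get(bc)) not in mixed:
            continue
        cell = cells.get(bc)
        if cell is None:
            continue
        if any(rules.is_mait_v(v) for v, _, _, _ in cell.locus("TRA")):
            out.loc[bc, ["assigned_type", "pass_id", "rule_trace"]] = [
                TYPE_MAIT,
                PASS_FALLBACK,
                "trav1_expression",
            ]
        elif cell.has("TRG") and cell.has("TRD"):
            out.loc[bc, ["assigned_type", "pass_id", "rule_trace"]] = [
                TYPE_GDT,
                PASS_FALLBACK,
                "trgv_trdv_expression",
            ]
    return out


def demultiplex(
    cells: Mapping[str, CellChains],
    y_totals: Mapping[str, int],
    cluster_labels: Mapping[str, str],
    rules: DemuxRules | None = None,
    barcodes: Iterable[str] | None = None,
    drop_clusters: Iterable[str] = (),
) -> tuple[pd.DataFrame, dict]:
    """Run the three assignment passes plus doublet removal end to end.

    ``drop_clusters`` excludes whole clusters judged to be artifact
    populations (e.g. contaminating double-positive thymocytes): their
    non-doublet members end unassigned with a ``dropped_cluster`` trace and
    take no part in rescue or fallback.
    """
    rules = rules or DemuxRules()
    dropped = {str(c) for c in drop_clusters}
    labels = {bc: str(c) for bc, c in cluster_labels.items() if str(c) not in dropped}
    df = assign_by_tcr(cells, y_totals, rules, barcodes=barcodes)
    df = flag_doublets(df, cells, rules)
    df, rescued = cluster_rescue(df, labels, rules)
    all_clusters = set(labels.values())
    mixed = all_clusters - rescued
    df = tcr_fallback(df, cells, labels, mixed, rules)
    if dropped:
        drop_bcs = [
            bc for bc in df.index
            if str(cluster_labels.get(bc)) in dropped
            and df.loc[bc, "assigned_type"] != REMOVED_DOUBLET
        ]
        df.loc[drop_bcs, ["assigned_type", "pass_id", "rule_trace"]] = [
            UNASSIGNED, PASS_TCR, "dropped_cluster",
        ]
    summary = {
        "n_barcodes": int(len(df)),
        "by_type": df["assigned_type"].value_counts().to_dict(),
        "by_pass": df["pass_id"].value_counts().to_dict(),
        "rescued_clusters": sorted(rescued),
        "mixed_clusters": sorted(mixed),
        "dropped_clusters": sorted(dropped),
        "majority_denominator": "assigned_cells_only",
    }
    return df, summary
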