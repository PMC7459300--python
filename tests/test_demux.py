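"""Three-pass demultiplexing: TCR rules, doublets, cluster rescue, fallback."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_cell
from trex.demux import (
    DemuxRules,
    assign_by_tcr,
    cluster_rescue,
    demultiplex,
    flag_doublets,
    tcr_fallback,
)
from trex.synthetic import truth_cluster_labels
from trex.tcr import cell_chains, usable_contigs
from trex.tenx import y_gene_totals

TRA_INKT = ("TRA", "TRAV11", "TRAJ18", "TGTGTCGTG", "CVV")
TRA_INKT_D = ("TRA", "TRAV11D", "TRAJ18", "TGTGTCGTG", "CVV")
TRA_MAIT = ("TRA", "TRAV1", "TRAJ33", "TGTGCAGTC", "CAV")
TRA_OTHER = ("TRA", "TRAV10", "TRAJ50", "TGTGCCGTG", "CAV")
TRG = ("TRG", "TRGV4", "TRGJ1", "TGTGCC", "CA")
TRD = ("TRD", "TRDV5", "TRDJ1", "TGTGGC", "CG")


def _assign(cells, y):
    return assign_by_tcr({c.barcode: c for c in cells}, y)


def test_first_pass_rules():
    cells = [
        make_cell("inkt-1", [TRA_INKT]),
        make_cell("inktd-1", [TRA_INKT_D]),
        make_cell("mait-1", [TRA_MAIT]),
        make_cell("male-mait-1", [TRA_MAIT]),
        make_cell("gd-1", [TRG, TRD]),
        make_cell("none-1", [TRA_OTHER]),
    ]
    y = {"inkt-1": 3, "inktd-1": 2, "mait-1": 0, "male-mait-1": 4, "gd-1": 0, "none-1": 0}
    out = _assign(cells, y)
    assert out.loc["inkt-1", "assigned_type"] == "iNKT"
    assert out.loc["inktd-1", "assigned_type"] == "iNKT"  # TRAV11D merges
    assert out.loc["mait-1", "assigned_type"] == "MAIT"
    # canonical MAIT alpha but Y-gene expression: cannot be MAIT (male pool)
    assert out.loc["male-mait-1", "assigned_type"] == "unassigned"
    assert out.loc["gd-1", "assigned_type"] == "gdT"
    assert out.loc["none-1", "assigned_type"] == "unassigned"


def test_barcode_without_expression_warned_and_unassigned():
    cells = {"lost-1": make_cell("lost-1", [TRA_INKT])}
    with pytest.warns(UserWarning, match="no expression"):
        out = assign_by_tcr(cells, {"kept-1": 0})
    assert out.loc["lost-1", "assigned_type"] == "unassigned"


def test_doublet_rules():
    cells = {
        "tra-trd-1": make_cell("tra-trd-1", [TRA_INKT, TRD]),
        "dual-1": make_cell("dual-1", [TRA_INKT, TRA_MAIT]),
        "gd-1": make_cell("gd-1", [TRG, TRD]),
    }
    y = {b: 0 for b in cells}
    out = flag_doublets(_assign(cells.values(), y), cells)
    assert out.loc["tra-trd-1", "assigned_type"] == "removed_doublet"
    assert out.loc["tra-trd-1", "rule_trace"] == "tra_and_trd"
    assert out.loc["dual-1", "assigned_type"] == "removed_doublet"
    assert out.loc["dual-1", "rule_trace"] == "dual_canonical_alpha"
    assert out.loc["gd-1", "assigned_type"] == "gdT"  # TRG+TRD alone is fine


def _cluster_frame(n_major, n_minor, n_unassigned):
    rows = []
    for i in range(n_major):
        rows.append((f"a{i:02d}-1", "iNKT", "1_tcr", "x"))
    for i in range(n_minor):
        rows.append((f"b{i:02d}-1", "MAIT", "1_tcr", "x"))
    for i in range(n_unassigned):
        rows.append((f"u{i:02d}-1", "unassigned", "1_tcr", "x"))
    df = pd.DataFrame(rows, columns=["barcode", "assigned_type", "pass_id", "rule_trace"])
    df = df.set_index("barcode")
    return df, {bc: "K" for bc in df.index}


def test_cluster_rescue_above_threshold():
    df, labels = _cluster_frame(17, 3, 5)  # 85% iNKT among assigned
    out, rescued = cluster_rescue(df, labels)
    assert rescued == {"K"}
    assert (out.loc[[f"u{i:02d}-1" for i in range(5)], "assigned_type"] == "iNKT").all()
    assert (out.loc[[f"b{i:02d}-1" for i in range(3)], "assigned_type"] == "removed_doublet").all()


def test_cluster_rescue_strict_inequality_at_threshold():
    df, labels = _cluster_frame(16, 4, 5)  # exactly 80%: no rescue
    out, rescued = cluster_rescue(df, labels)
    assert rescued == set()
    pd.testing.assert_frame_equal(out, df)


def test_cluster_with_no_assigned_cells_skipped():
    df, labels = _cluster_frame(0, 0, 4)
    with pytest.warns(UserWarning, match="no assigned cells"):
        out, rescued = cluster_rescue(df, labels)
    assert rescued == set()
    assert (out["assigned_type"] == "unassigned").all()


def test_tcr_fallback_in_mixed_clusters():
    cells = {
        "m-1": make_cell("m-1", [("TRA", "TRAV1", "TRAJ12", "TGTGCA", "CA")]),
        "g-1": make_cell("g-1", [TRG]),
        "gd-1": make_cell("gd-1", [TRG, TRD]),
    }
    df = pd.DataFrame(
        {"assigned_type": "unassigned", "pass_id": "1_tcr", "rule_trace": "x"},
        index=pd.Index(list(cells), name="barcode"),
    )
    labels = {bc: "mix" for bc in cells}
    out = tcr_fallback(df, cells, labels, mixed_clusters={"mix"})
    assert out.loc["m-1", "assigned_type"] == "MAIT"  # non-canonical TRAV1 junction
    assert out.loc["g-1", "assigned_type"] == "unassigned"  # TRG alone insufficient
    assert out.loc["gd-1", "assigned_type"] == "gdT"


def test_partition_and_order_independence(small_cohort):
    adata, contigs, truth = small_cohort
    cells = cell_chains(usable_contigs(contigs))
    y = y_gene_totals(adata).to_dict()
    labels = truth_cluster_labels(truth)
    out, _ = demultiplex(cells, y, labels, barcodes=adata.obs_names)
    assert sorted(out.index) == sorted(adata.obs_names)
    assert set(out["assigned_type"]) <= {
        "iNKT", "MAIT", "gdT", "unassigned", "removed_doublet"
    }
    # permuting barcode order leaves every assignment unchanged
    perm = list(np.random.default_rng(0).permutation(list(adata.obs_names)))
    out2, _ = demultiplex(cells, y, labels, barcodes=perm)
    pd.testing.assert_frame_equal(out.sort_index(), out2.sort_index())


def test_ground_truth_recoverable_on_clean_cohort(clean_cohort):
    """Without doublets and QC failures, >=99% of cells recover their type."""
    adata, contigs, truth = clean_cohort
    cells = cell_chains(usable_contigs(contigs))
    out, _ = demultiplex(
        cells, y_gene_totals(adata).to_dict(), truth_cluster_labels(truth),
        barcodes=adata.obs_names,
    )
    merged = out.join(truth)
    assigned = merged[merged["assigned_type"].isin(["iNKT", "MAIT", "gdT"])]
    assert len(assigned) >= 0.99 * len(truth)
    assert (assigned["assigned_type"] == assigned["true_type"]).mean() >= 0.99


def test_drop_clusters_excluded_from_typing(small_cohort):
    adata, contigs, truth = small_cohort
    cells = cell_chains(usable_contigs(contigs))
    y = y_gene_totals(adata).to_dict()
    labels = truth_cluster_labels(truth)
    out, summary = demultiplex(
        cells, y, labels, barcodes=adata.obs_names, drop_clusters=["N1"]
    )
    dropped = [bc for bc, c in labels.items() if c == "N1"]
    sub = out.loc[dropped, "assigned_type"]
    assert set(sub) <= {"unassigned", "removed_doublet"}
    assert summary["dropped_clusters"] == ["N1"]


def test_rules_validation():
    with pytest.raises(ValueError, match="majority_threshold"):
        DemuxRules(majority_threshold=0.4)
    with pytest.raises(ValueError, match="non-empty"):
        DemuxRules(y_genes=())
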