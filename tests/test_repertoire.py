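"""Repertoire statistics: spectra, diversity, sharing, logos, classification."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_cell
from trex.repertoire import (
    build_clonotype_table,
    cdr3_length_hist,
    classify_canonical,
    cluster_sharing,
    composition_logo,
    hydropathy_class,
    percent,
    repeat_spectrum,
    shannon_equitability,
)
from trex.tcr import cell_chains, clonotype_key, usable_contigs


class TestPercent:
    def test_reported_values(self):
        # published worked examples from the clonotype tallies
        assert percent(112, 1898, 1) == 5.9
        assert percent(204, 1898, 1) == 10.7
        assert percent(253, 2775, 1) == 9.1
        assert percent(17, 1760, 2) == 0.96
        assert percent(359, 1665, 0) == 21

    def test_floor_vs_round(self):
        assert percent(17, 1760, 2, mode="floor") == 0.96
        assert percent(17, 1760, 2, mode="round") == 0.97

    def test_zero_denominator(self):
        with pytest.raises(ValueError):
            percent(1, 0)

    @settings(derandomize=True, max_examples=100)
    @given(num=st.integers(0, 10_000), den=st.integers(1, 10_000), dec=st.integers(0, 3))
    def test_floor_never_exceeds_true_value(self, num, den, dec):
        assert percent(num, den, dec) <= num / den * 100 + 1e-9


class TestShannonEquitability:
    def test_uniform_is_one(self):
        assert shannon_equitability([5, 5, 5, 5]) == pytest.approx(1.0)

    def test_single_clonotype_is_zero(self):
        assert shannon_equitability([10]) == 0.0

    def test_hand_computed_three_clonotypes(self):
        # H = -(1/2 ln 1/2 + 2 * 1/4 ln 1/4) = 1.0397; ln 3 = 1.0986
        assert shannon_equitability([2, 1, 1]) == pytest.approx(0.9464, abs=1e-4)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            shannon_equitability([])

    @settings(derandomize=True, max_examples=100)
    @given(
        counts=st.lists(st.integers(1, 50), min_size=2, max_size=20),
        k=st.integers(2, 7),
        seed=st.integers(0, 2**16),
    )
    def test_permutation_and_scale_invariance(self, counts, k, seed):
        base = shannon_equitability(counts)
        perm = list(np.random.default_rng(seed).permutation(counts))
        assert shannon_equitability(perm) == pytest.approx(base)
        assert shannon_equitability([c * k for c in counts]) == pytest.approx(base)


def _toy_cells():
    shared = [("TRA", "TRAV11", "TRAJ18", "TGTGTCGTG", "CVV")]
    other = [("TRA", "TRAV10", "TRAJ50", "TGTGCAGTC", "CAV")]
    return {
        "a-1": make_cell("a-1", shared),
        "b-1": make_cell("b-1", shared),
        "c-1": make_cell("c-1", other),
    }


class TestClonotypeTable:
    def test_toy_counts(self):
        table = build_clonotype_table(_toy_cells())
        assert len(table) == 2
        assert sorted(table["n_cells"]) == [1, 2]
        assert table["n_cells"].sum() == 3

    def test_per_cluster_counts_sum_to_total(self, small_cohort):
        _, contigs, truth = small_cohort
        cells = cell_chains(usable_contigs(contigs))
        labels = {bc: str(c) for bc, c in truth["true_cluster"].items()}
        table = build_clonotype_table(cells, labels)
        clusters = table.attrs["cluster_columns"]
        assert (table[clusters].sum(axis=1) == table["n_cells"]).all()

    def test_matches_brute_force_dictionary(self, small_cohort):
        _, contigs, _ = small_cohort
        cells = cell_chains(usable_contigs(contigs))
        table = build_clonotype_table(cells)
        oracle = Counter(clonotype_key(c) for c in cells.values())
        assert table["n_cells"].to_dict() == dict(oracle)


class TestRepeatSpectrum:
    def test_toy_percentages(self):
        sizes = [1] * 86 + [2] * 10 + [4] * 4
        table = pd.DataFrame({"n_cells": sizes})
        table.attrs["cluster_columns"] = []
        spec, summary = repeat_spectrum(table)
        assert summary["singleton_clonotype_pct"] == 86
        assert summary["repeated_gt3_clonotypes"] == 4
        assert spec.loc[1, "frac_clonotypes"] == pytest.approx(0.86)

    def test_conservation(self, small_cohort):
        _, contigs, _ = small_cohort
        cells = cell_chains(usable_contigs(contigs))
        table = build_clonotype_table(cells)
        spec, summary = repeat_spectrum(table)
        assert spec["n_clonotypes"].sum() == summary["n_clonotypes"] == len(table)
        assert spec["n_cells"].sum() == summary["n_cells"] == table["n_cells"].sum()

    def test_empty_rejected(self):
        empty = pd.DataFrame({"n_cells": []})
        with pytest.raises(ValueError):
            repeat_spectrum(empty)


class TestClusterSharing:
    def _table(self, rows):
        table = pd.DataFrame(rows).set_index("clonotype")
        table.attrs["cluster_columns"] = [c for c in table.columns if c != "n_cells"]
        return table

    def test_disjoint_regions_share_nothing(self):
        t = self._table(
            [
                {"clonotype": "k1", "n_cells": 2, "A": 2, "B": 0},
                {"clonotype": "k2", "n_cells": 3, "A": 0, "B": 3},
            ]
        )
        out = cluster_sharing(t, ["A"], ["B"])
        assert out["n_shared"] == 0 and out["total_repeats"] == 0

    def test_one_shared_key(self):
        t = self._table(
            [
                {"clonotype": "k1", "n_cells": 5, "A": 2, "B": 3},
                {"clonotype": "k2", "n_cells": 1, "A": 1, "B": 0},
                {"clonotype": "k3", "n_cells": 4, "A": 0, "B": 4},
            ]
        )
        out = cluster_sharing(t, ["A"], ["B"])
        assert out["n_shared"] == 1
        assert out["total_repeats"] == 5
        assert out["pct_of_cells"] == percent(5, 10, 0)
        assert out["pct_of_repetitive_cells"] == percent(5, 9, 0)

    def test_unknown_cluster_rejected(self):
        t = self._table([{"clonotype": "k1", "n_cells": 1, "A": 1}])
        with pytest.raises(ValueError, match="unknown cluster"):
            cluster_sharing(t, ["A"], ["Z"])


class TestCdr3Lengths:
    def test_single_bin(self):
        cells = {
            f"b{i}-1": make_cell(f"b{i}-1", [("TRA", "TRAV11", "TRAJ18", "TGT", "C" * 13)])
            for i in range(4)
        }
        assert cdr3_length_hist(cells, "TRA") == {13: 4}

    def test_matches_brute_force(self):
        seqs = ["CAVRF", "CAVRLW", "CARF", "CAVRF", "CAVSDF", "CAW"]
        cells = {
            f"b{i}-1": make_cell(f"b{i}-1", [("TRA", "TRAV1", "TRAJ33", "TGT", s)])
            for i, s in enumerate(seqs)
        }
        assert cdr3_length_hist(cells, "TRA") == dict(Counter(len(s) for s in seqs))

    def test_partition_conserves_cells(self):
        canonical = [("TRA", "TRAV11", "TRAJ18", "TGT", "CVVGD")]
        noncanon = [("TRA", "TRAV10", "TRAJ50", "TGT", "CAVXX")]
        cells = {"a-1": make_cell("a-1", canonical), "b-1": make_cell("b-1", noncanon)}
        is_canon = lambda c: c[0] == "TRAV11"
        h_can = cdr3_length_hist(cells, "TRA", select=is_canon)
        h_non = cdr3_length_hist(cells, "TRA", select=lambda c: not is_canon(c))
        total = cdr3_length_hist(cells, "TRA")
        assert sum(h_can.values()) + sum(h_non.values()) == sum(total.values())


class TestCompositionLogo:
    def test_identical_sequences(self):
        logo = composition_logo(["CARW"] * 5)
        assert logo.modal_length == 4
        assert logo.frequencies.loc[1, "C"] == 1.0
        assert logo.frequencies.loc[4, "W"] == 1.0
        np.testing.assert_allclose(logo.frequencies.sum(axis=1), 1.0, atol=1e-9)

    def test_split_position(self):
        logo = composition_logo(["CAR", "CAK"])
        assert logo.frequencies.loc[3, "R"] == 0.5
        assert logo.frequencies.loc[3, "K"] == 0.5

    def test_modal_tie_breaks_shorter(self):
        with pytest.warns(UserWarning, match="tie"):
            logo = composition_logo(["CAR", "CARW"])
        assert logo.modal_length == 3

    def test_hydropathy_classes(self):
        assert hydropathy_class("D") == "hydrophilic"
        assert hydropathy_class("G") == "neutral"
        assert hydropathy_class("W") == "hydrophobic"
        logo = composition_logo(["CAR"])
        assert logo.classes["D"] == "hydrophilic"


class TestClassifyCanonical:
    def _cells(self):
        oligo_beta = ("TRB", "TRBV13-1", "TRBJ1-1", "TGT", "CASS")
        nono_beta = ("TRB", "TRBV2", "TRBJ1-1", "TGT", "CASS")
        canon = ("TRA", "TRAV11", "TRAJ18", "TGT", "CVVGD")
        noncanon = ("TRA", "TRAV10", "TRAJ50", "TGT", "CAVXX")
        return {
            "canon-1": make_cell("canon-1", [canon, oligo_beta]),
            "nca-1": make_cell("nca-1", [noncanon, oligo_beta]),
            "nob-1": make_cell("nob-1", [canon, nono_beta]),
            "both-1": make_cell("both-1", [noncanon, nono_beta]),
            "no-trb-1": make_cell("no-trb-1", [canon]),
        }

    def test_classes_and_venn(self):
        with pytest.warns(UserWarning, match="lack a TRB"):
            flags, venn, _ = classify_canonical(self._cells(), "iNKT")
        assert flags.loc["canon-1", "class"] == "canonical_only"
        assert flags.loc["nca-1", "class"] == "nc_alpha_only"
        assert flags.loc["nob-1", "class"] == "nob_beta_only"
        assert flags.loc["both-1", "class"] == "both"
        assert flags.loc["no-trb-1", "oligoclonal_beta"] is None
        assert sum(venn.values()) == len(flags)  # exhaustive and disjoint

    def test_per_cluster_fraction_and_exclusion(self):
        labels = {bc: "K" for bc in self._cells()}
        with pytest.warns(UserWarning):
            _, _, per = classify_canonical(self._cells(), "iNKT", cluster_labels=labels)
        assert per.loc["K", "n_cells"] == 5
        assert per.loc["K", "n_noncanonical"] == 3
        with pytest.warns(UserWarning):
            _, _, per_x = classify_canonical(
                self._cells(), "iNKT", cluster_labels=labels, exclude_both=True
            )
        assert per_x.loc["K", "n_cells"] == 4
        assert per_x.loc["K", "n_noncanonical"] == 2

    def test_requires_invariant_type(self):
        with pytest.raises(ValueError):
            classify_canonical({}, "gdT")
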