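import pytest

from trex.synthetic import SyntheticConfig, generate_cohort
from trex.tcr import CellChains


def make_cell(barcode, chains):
    """Build a CellChains from (chain, v, j, cdr3_nt, cdr3_aa) tuples."""
    grouped = {}
    for chain, v, j, nt, aa in chains:
        grouped.setdefault(chain, set()).add((v, j, nt, aa))
    return CellChains(barcode, {c: frozenset(s) for c, s in grouped.items()})


@pytest.fixture(scope="session")
def small_cohort():
    """150 cells/type with 5% designed doublets and QC violators."""
    cfg = SyntheticConfig(
        n_cells_per_type=150,
        doublet_fraction=0.05,
        n_genes=600,
        umi_depth_mean=2500.0,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """No doublets, no QC violators: ground truth should be fully recoverable."""
    cfg = SyntheticConfig(
        n_cells_per_type=150,
        doublet_fraction=0.0,
        mito_violation_rate=0.0,
        low_umi_rate=0.0,
        n_genes=600,
        umi_depth_mean=2500.0,
        seed=3,
    )
    return generate_cohort(cfg)
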