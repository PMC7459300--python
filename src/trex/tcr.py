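"""Parsing and clonotyping of 10x-dialect TCR contig annotation tables.

A clonotype is the set of a cell's productive chains identified by V gene,
J gene and CDR3 sequence; only contigs called both productive and
high-confidence enter the analysis. For the invariant alpha chain of iNKT
cells, TRAV11 and TRAV11D are duplicated gene segments encoding the same
chain and are collapsed before comparison; allele suffixes (``*01``) are
stripped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

TR_CHAINS = ("TRA", "TRB", "TRG", "TRD")

TENX_COLUMNS = [
    "barcode",
    "is_cell",
    "high_confidence",
    "chain",
    "v_gene",
    "d_gene",
    "j_gene",
    "c_gene",
    "full_length",
    "productive",
    "cdr3",
    "cdr3_nt",
    "reads",
    "umis",
    "raw_clonotype_id",
]

MANDATORY_COLUMNS = (
    "barcode",
    "chain",
    "v_gene",
    "j_gene",
    "cdr3",
    "cdr3_nt",
    "productive",
    "high_confidence",
    "umis",
)

_BOOL_VALUES = {"true": True, "false": False, "none": False}


@dataclass(frozen=True)
class ContigRecord:
    """One TCR contig call for one cell barcode."""

    barcode: str
    chain: str
    v_gene: str
    j_gene: str
    cdr3_aa: str
    cdr3_nt: str
    productive: bool
    high_confidence: bool
    umis: int = 1


# A chain tuple is (v_gene, j_gene, cdr3_nt, cdr3_aa).
Chain = tuple[str, str, str, str]


@dataclass(frozen=True)
class CellChains:
    """Per-cell sets of usable chains, grouped by locus."""

    barcode: str
    chains: Mapping[str, frozenset[Chain]]

    def locus(self, chain: str) -> frozenset[Chain]:
        return self.chains.get(chain, frozenset())

    def has(self, chain: str) -> bool:
        return len(self.locus(chain)) > 0


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _BOOL_VALUES:
        return _BOOL_VALUES[s]
    raise ValueError(f"unparseable boolean {value!r}")


def read_contigs(path: str | Path) -> list[ContigRecord]:
    """Read a ``filtered_contig_annotations.csv`` in the 10x dialect.

    ``productive`` / ``high_confidence`` accept True/False/None spellings
    ("None" counts as False). Rows with a non-TR chain, empty mandatory
    fields, or unparseable values are dropped with a warning listing the
    offending 1-based data row numbers. A missing mandatory column raises.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"contig table {path} is missing mandatory columns: {missing}")
    records: list[ContigRecord] = []
    bad_rows: list[int] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            chain = str(getattr(row, "chain")).strip()
            if chain not in TR_CHAINS:
                raise ValueError(f"unknown chain {chain!r}")
            barcode = str(getattr(row, "barcode")).strip()
            v = str(getattr(row, "v_gene")).strip()
            j = str(getattr(row, "j_gene")).strip()
            if not barcode or not v or not j:
                raise ValueError("empty barcode or gene name")
            records.append(
                ContigRecord(
                    barcode=barcode,
                    chain=chain,
                    v_gene=v,
                    j_gene=j,
                    cdr3_aa=str(getattr(row, "cdr3")).strip(),
                    cdr3_nt=str(getattr(row, "cdr3_nt")).strip(),
                    productive=_parse_bool(getattr(row, "productive")),
                    high_confidence=_parse_bool(getattr(row, "high_confidence")),
                    umis=int(getattr(row, "umis") or 0),
                )
            )
        except (ValueError, TypeError):
            bad_rows.append(i)
    if bad_rows:
        warnings.warn(
            f"dropped {len(bad_rows)} malformed contig rows "
            f"(data rows {bad_rows[:20]}{'...' if len(bad_rows) > 20 else ''})"
        )
    return records


def write_contigs(records: Iterable[ContigRecord], path: str | Path) -> Path:
    """Write contigs with the full 10x column set and header order."""
    rows = []
    for r in records:
        rows.append(
            {
                "barcode": r.barcode,
                "is_cell": "True",
                "high_confidence": "True" if r.high_confidence else "False",
                "chain": r.chain,
                "v_gene": r.v_gene,
                "d_gene": "None",
                "j_gene": r.j_gene,
                "c_gene": "None",
                "full_length": "True",
                "productive": "True" if r.productive else "False",
                "cdr3": r.cdr3_aa,
                "cdr3_nt": r.cdr3_nt,
                "reads": r.umis * 10,
                "umis": r.umis,
                "raw_clonotype_id": "None",
            }
        )
    pd.DataFrame(rows, columns=TENX_COLUMNS).to_csv(path, index=False)
    return Path(path)


def usable_contigs(records: Iterable[ContigRecord]) -> list[ContigRecord]:
    """Keep exactly the contigs called both productive and high-confidence."""
    return [r for r in records if r.productive and r.high_confidence]


def normalize_gene(name: str) -> str:
    """Strip allele suffixes and collapse the TRAV11D duplicate onto TRAV11."""
    base = name.split("*", 1)[0].strip()
    if base == "TRAV11D":
        return "TRAV11"
    return base


def cell_chains(records: Iterable[ContigRecord]) -> dict[str, CellChains]:
    """Group usable contigs by barcode into per-locus chain sets.

    Identical (v, j, cdr3_nt, cdr3_aa) tuples collapse; distinct chains of
    the same locus are all retained.
    """
    grouped: dict[str, dict[str, set[Chain]]] = {}
    for r in records:
        loci = grouped.setdefault(r.barcode, {})
        loci.setdefault(r.chain, set()).add((r.v_gene, r.j_gene, r.cdr3_nt, r.cdr3_aa))
    return {
        bc: CellChains(bc, {ch: frozenset(s) for ch, s in loci.items()})
        for bc, loci in grouped.items()
    }


def clonotype_key(cell: CellChains, level: str = "nt") -> str:
    """Deterministic, order-invariant clonotype identifier for a cell.

    ``level`` selects whether CDR3 identity is at the nucleotide (default,
    the 10x convention) or amino-acid level.
    """
    if level not in ("nt", "aa"):
        raise ValueError(f"level must be 'nt' or 'aa', got {level!r}")
    parts = []
    for chain, chain_set in cell.chains.items():
        for v, j, nt, aa in chain_set:
            cdr3 = nt if level == "nt" else aa
            parts.append((chain, normalize_gene(v), normalize_gene(j), cdr3))
    if not parts:
        raise ValueError(f"cell {cell.barcode} has no usable chains")
    return ";".join(":".join(p) for p in sorted(parts))
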