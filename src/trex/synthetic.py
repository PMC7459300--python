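"""Synthetic pooled-cohort generator with known ground truth.

Emulates the pooling design the downstream stages assume: equal numbers of
sorted iNKT (male mice), MAIT (female mice) and gamma-delta T cells run
through one droplet experiment. Each generated cell carries

* negative-binomially distributed UMI counts with cluster-specific marker
  shifts (the standard droplet noise model),
* Y-chromosome marker genes expressed in male cells and structurally zero
  in female cells,
* a mitochondrial UMI share drawn so that a configurable fraction of cells
  violates the 10% QC rule,
* TCR contigs consistent with its type: a productive TRA (plus usually a
  TRB) for iNKT/MAIT, productive TRG + TRD for gamma-delta cells,
* a clone identity: clone sizes follow a truncated discrete power law, and
  all cells of a clone share one chain set (one clonotype).

Designed doublets are extra barcodes merging the counts and contigs of two
freshly drawn cells of different types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import brentq

from .tcr import ContigRecord, write_contigs
from .tenx import (
    DEFAULT_Y_GENES,
    LAYER_KEY,
    LAYER_RAW,
    annotate_genes,
    write_matrix_dir,
)

CELL_TYPES = ("iNKT", "MAIT", "gdT")

# Canonical invariant alpha rearrangements: Valpha14-Jalpha18 for iNKT and
# Valpha19-Jalpha33 for MAIT, with their near-invariant CDR3s.
CANONICAL_ALPHA = {
    "iNKT": ("TRAV11", "TRAJ18", "CVVGDRGSALGRLHF"),
    "MAIT": ("TRAV1", "TRAJ33", "CAVRDSNYQLIW"),
}

# Decoy V/J pool for non-canonical alpha chains; includes the
# Valpha10-Jalpha50 pair seen as the most frequent non-canonical iNKT TCR.
NONCANONICAL_ALPHA_POOL = (
    ("TRAV10", "TRAJ50"),
    ("TRAV9-1", "TRAJ31"),
    ("TRAV12-1", "TRAJ12"),
    ("TRAV6-5", "TRAJ27"),
    ("TRAV13-2", "TRAJ22"),
)

OLIGOCLONAL_VB = {
    "iNKT": ("TRBV13-1", "TRBV13-2", "TRBV13-3", "TRBV29", "TRBV1"),
    "MAIT": ("TRBV19", "TRBV13-1", "TRBV13-2", "TRBV13-3"),
}
NONOLIGO_VB = ("TRBV2", "TRBV3", "TRBV5", "TRBV12-1", "TRBV15", "TRBV16", "TRBV23")
TRBJ = ("TRBJ1-1", "TRBJ1-2", "TRBJ1-4", "TRBJ2-1", "TRBJ2-3", "TRBJ2-5", "TRBJ2-7")

TRGV = ("TRGV1", "TRGV4", "TRGV6", "TRGV7")
TRGV_WEIGHTS = (0.2, 0.4, 0.2, 0.2)
TRGJ = ("TRGJ1", "TRGJ2")
# CDR3gamma length window per Vgamma (narrow, Vgamma6 fetal-invariant).
TRGV_CDR3_LEN = {"TRGV1": (13, 15), "TRGV4": (13, 14), "TRGV6": (17, 17), "TRGV7": (12, 13)}
TRDV = ("TRDV1", "TRDV2-2", "TRDV4", "TRDV5", "TRDV6", "TRDV7")
TRDJ = ("TRDJ1", "TRDJ2")

AA_INNER = "ACDEFGHIKLMNPQRSTVWY"

MITO_GENE_NAMES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp8", "mt-Atp6", "mt-Co3",
    "mt-Nd3", "mt-Nd4l", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)

# Standard-code codons per amino acid (stop codons excluded).
_BASES = "TCAG"
_AA_ORDER = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODONS: dict[str, list[str]] = {}
for _i, (_b1, _b2, _b3) in enumerate(
    (b1, b2, b3) for b1 in _BASES for b2 in _BASES for b3 in _BASES
):
    _aa = _AA_ORDER[_i]
    if _aa != "*":
        CODONS.setdefault(_aa, []).append(_b1 + _b2 + _b3)


@dataclass(frozen=True)
class ClusterSpec:
    """One transcriptome cluster of one cell type."""

    cluster_id: str
    cell_type: str
    weight: float = 1.0
    n_marker_genes: int = 15
    marker_log2fc: float = 2.0


def default_cluster_spec() -> tuple[ClusterSpec, ...]:
    return tuple(
        ClusterSpec(cid, ct, 0.5)
        for ct, ids in (("iNKT", ("N1", "N2")), ("MAIT", ("M1", "M2")), ("gdT", ("G1", "G2")))
        for cid in ids
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator parameters; the defaults define the simulated conditions."""

    n_cells_per_type: int = 500
    doublet_fraction: float = 0.05
    noncanonical_alpha_rate: float = 0.10
    nonoligoclonal_beta_rate: float = 0.10
    beta_chain_rate: float = 0.90
    clonal_shape: float = 2.5
    max_clone_size: int = 150
    n_genes: int = 2000
    n_mito_genes: int = 10
    n_ygenes: int = 4
    cluster_spec: tuple[ClusterSpec, ...] = field(default_factory=default_cluster_spec)
    umi_depth_mean: float = 3000.0
    mito_mean_frac: float = 0.04
    mito_violation_rate: float = 0.05
    low_umi_rate: float = 0.0
    dispersion: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cells_per_type", "n_genes", "n_mito_genes", "n_ygenes", "max_clone_size"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive count")
        for name in (
            "doublet_fraction",
            "noncanonical_alpha_rate",
            "nonoligoclonal_beta_rate",
            "mito_violation_rate",
            "low_umi_rate",
        ):
            v = float(getattr(self, name))
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.clonal_shape <= 0:
            raise ValueError("clonal_shape must be positive")
        if self.umi_depth_mean <= 0:
            raise ValueError("umi_depth_mean must be positive")
        if self.n_ygenes > len(DEFAULT_Y_GENES):
            raise ValueError(
                f"n_ygenes must be at most {len(DEFAULT_Y_GENES)} (the default Y-gene list)"
            )


def clone_sizes(n_cells: int, shape: float, max_size: int, rng: np.random.Generator) -> list[int]:
    """Sample clone sizes s ~ s^(-shape) (truncated) until covering n_cells."""
    sizes = np.arange(1, min(max_size, n_cells) + 1)
    p = sizes.astype(float) ** (-shape)
    p /= p.sum()
    out: list[int] = []
    remaining = n_cells
    while remaining > 0:
        s = int(rng.choice(sizes, p=p))
        s = min(s, remaining)
        out.append(s)
        remaining -= s
    return out


def shape_for_singleton_cell_fraction(
    target: float, max_size: int = 150
) -> float:
    """Power-law exponent giving the requested expected singleton-cell share.

    For iid clone sizes with P(s) proportional to s^(-a), the expected
    fraction of cells sitting in singleton clones is 1 / sum_s s^(1-a).
    """
    if not (0 < target < 1):
        raise ValueError("target singleton cell fraction must lie in (0, 1)")
    s = np.arange(1, max_size + 1, dtype=float)

    def f(a: float) -> float:
        return 1.0 / np.sum(s ** (1.0 - a)) - target

    return float(brentq(f, 1.01, 25.0))


def _random_cdr3_aa(length: int, rng: np.random.Generator) -> str:
    inner = "".join(rng.choice(list(AA_INNER), size=max(length - 2, 0)))
    tail = "F" if rng.random() < 0.7 else "W"
    return ("C" + inner + tail)[:length]


def back_translate(aa: str, rng: np.random.Generator) -> str:
    """Random codon choice per residue; translates back to ``aa``."""
    return "".join(CODONS[r][int(rng.integers(len(CODONS[r])))] for r in aa)


def _make_clone_chain_sets(
    cell_type: str, n_clones: int, cfg: SyntheticConfig, rng: np.random.Generator
) -> list[dict]:
    """One chain set (clonotype) per clone, with canonical/oligoclonal flags."""
    clones = []
    for i in range(n_clones):
        chains: list[tuple[str, str, str, str]] = []  # (chain, v, j, cdr3_aa)
        if cell_type in ("iNKT", "MAIT"):
            canonical = rng.random() >= cfg.noncanonical_alpha_rate
            if canonical:
                v, j, aa = CANONICAL_ALPHA[cell_type]
            else:
                v, j = NONCANONICAL_ALPHA_POOL[int(rng.integers(len(NONCANONICAL_ALPHA_POOL)))]
                aa = _random_cdr3_aa(int(rng.integers(11, 17)), rng)
            chains.append(("TRA", v, j, aa))
            oligo = True
            if rng.random() < cfg.beta_chain_rate:
                oligo = rng.random() >= cfg.nonoligoclonal_beta_rate
                pool = OLIGOCLONAL_VB[cell_type] if oligo else NONOLIGO_VB
                vb = pool[int(rng.integers(len(pool)))]
                jb = TRBJ[int(rng.integers(len(TRBJ)))]
                chains.append(("TRB", vb, jb, _random_cdr3_aa(int(rng.integers(12, 17)), rng)))
            clones.append(
                {"clone_id": f"{cell_type}_c{i:04d}", "chains": chains,
                 "canonical_alpha": canonical, "oligoclonal_beta": oligo}
            )
        else:
            vg = str(rng.choice(TRGV, p=TRGV_WEIGHTS))
            lo, hi = TRGV_CDR3_LEN[vg]
            if vg == "TRGV6":
                gamma_aa = "CACWDSSGFHKVF"[:13] + "SGFH"  # fetal-invariant 17-mer
            else:
                gamma_aa = _random_cdr3_aa(int(rng.integers(lo, hi + 1)), rng)
            chains.append(("TRG", vg, TRGJ[int(rng.integers(len(TRGJ)))], gamma_aa))
            vd = TRDV[int(rng.integers(len(TRDV)))]
            chains.append(
                ("TRD", vd, TRDJ[int(rng.integers(len(TRDJ)))],
                 _random_cdr3_aa(int(rng.integers(10, 21)), rng))
            )
            clones.append(
                {"clone_id": f"{cell_type}_c{i:04d}", "chains": chains,
                 "canonical_alpha": True, "oligoclonal_beta": True}
            )
    return clones


def _unique_barcodes(n: int, rng: np.random.Generator) -> list[str]:
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        bc = "".join(rng.choice(list("ACGT"), size=16)) + "-1"
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def generate_cohort(
    config: SyntheticConfig,
) -> tuple[ad.AnnData, list[ContigRecord], pd.DataFrame]:
    """Generate (raw counts, contig records, ground-truth table).

    Deterministic for a fixed ``config.seed``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # --- gene space -------------------------------------------------------
    n_special = cfg.n_mito_genes + cfg.n_ygenes
    if cfg.n_genes <= n_special + 50:
        raise ValueError("n_genes too small for the mito/Y gene sets plus markers")
    mito_names = list(MITO_GENE_NAMES[: cfg.n_mito_genes])
    while len(mito_names) < cfg.n_mito_genes:
        mito_names.append(f"mt-Rnr{len(mito_names)}")
    y_names = list(DEFAULT_Y_GENES[: cfg.n_ygenes])
    n_body = cfg.n_genes - len(mito_names) - len(y_names)
    body_names = [f"Gene{i:04d}" for i in range(n_body)]
    gene_names = body_names + mito_names + y_names
    body_idx = np.arange(n_body)
    mito_idx = np.arange(n_body, n_body + len(mito_names))
    y_idx = np.arange(n_body + len(mito_names), cfg.n_genes)

    base = rng.lognormal(mean=0.0, sigma=1.2, size=n_body)
    base /= base.sum()

    # Cluster composition per type and disjoint marker blocks.
    specs_by_type = {t: [c for c in cfg.cluster_spec if c.cell_type == t] for t in CELL_TYPES}
    for t in CELL_TYPES:
        if not specs_by_type[t]:
            raise ValueError(f"cluster_spec has no cluster for cell type {t}")
    marker_order = rng.permutation(body_idx)
    marker_cursor = 0
    cluster_means: dict[str, np.ndarray] = {}
    cluster_markers: dict[str, np.ndarray] = {}
    for spec in cfg.cluster_spec:
        take = marker_order[marker_cursor : marker_cursor + spec.n_marker_genes]
        marker_cursor += spec.n_marker_genes
        m = base.copy()
        m[take] = m[take] * (2.0**spec.marker_log2fc)
        cluster_means[spec.cluster_id] = m / m.sum()
        cluster_markers[spec.cluster_id] = take
    if marker_cursor > n_body:
        raise ValueError("n_genes too small for the requested marker blocks")

    # --- cell roster ------------------------------------------------------
    n_singlets = cfg.n_cells_per_type * len(CELL_TYPES)
    n_doublets = int(round(cfg.doublet_fraction * n_singlets))

    draws: list[dict] = []  # one entry per simulated cell draw

    def _draw_cells(cell_type: str, n: int) -> list[int]:
        specs = specs_by_type[cell_type]
        w = np.array([s.weight for s in specs], dtype=float)
        w /= w.sum()
        idxs = []
        choice = rng.choice(len(specs), size=n, p=w)
        for ci in choice:
            spec = specs[int(ci)]
            sex = "male" if cell_type == "iNKT" else (
                "female" if cell_type == "MAIT" else ("male" if rng.random() < 0.5 else "female")
            )
            draws.append({"type": cell_type, "cluster": spec.cluster_id, "sex": sex})
            idxs.append(len(draws) - 1)
        return idxs

    singlet_draws = {t: _draw_cells(t, cfg.n_cells_per_type) for t in CELL_TYPES}
    doublet_pairs: list[tuple[int, int]] = []
    for _ in range(n_doublets):
        t1, t2 = rng.choice(len(CELL_TYPES), size=2, replace=False)
        d1 = _draw_cells(CELL_TYPES[int(t1)], 1)[0]
        d2 = _draw_cells(CELL_TYPES[int(t2)], 1)[0]
        doublet_pairs.append((d1, d2))

    n_draws = len(draws)

    # --- clone structure and contigs per draw -----------------------------
    draw_clone: dict[int, dict] = {}
    for t in CELL_TYPES:
        members = [i for i, d in enumerate(draws) if d["type"] == t]
        sizes = clone_sizes(len(members), cfg.clonal_shape, cfg.max_clone_size, rng)
        clones = _make_clone_chain_sets(t, len(sizes), cfg, rng)
        order = rng.permutation(len(members))
        pos = 0
        for size, clone in zip(sizes, clones):
            # Back-translate once per clone: one nucleotide clonotype.
            clone = dict(clone)
            clone["chains_nt"] = [
                (ch, v, j, aa, back_translate(aa, rng)) for ch, v, j, aa in clone["chains"]
            ]
            for m in order[pos : pos + size]:
                draw_clone[members[int(m)]] = clone
            pos += size

    # --- expression model -------------------------------------------------
    depth = rng.lognormal(np.log(cfg.umi_depth_mean) - 0.5 * 0.3**2, 0.3, size=n_draws)
    low_umi = rng.random(n_draws) < cfg.low_umi_rate
    depth[low_umi] = rng.uniform(100, 900, size=int(low_umi.sum()))
    mito_frac = rng.beta(4.0, 4.0 * (1 - cfg.mito_mean_frac) / cfg.mito_mean_frac, size=n_draws)
    mito_frac = np.clip(mito_frac, 0.0, 0.08)
    violators = rng.random(n_draws) < cfg.mito_violation_rate
    mito_frac[violators] = rng.uniform(0.15, 0.35, size=int(violators.sum()))

    y_frac = 0.004
    mu = np.zeros((n_draws, cfg.n_genes))
    is_male = np.array([d["sex"] == "male" for d in draws])
    for i, d in enumerate(draws):
        body_share = 1.0 - mito_frac[i] - (y_frac if is_male[i] else 0.0)
        mu[i, body_idx] = cluster_means[d["cluster"]] * body_share * depth[i]
        mu[i, mito_idx] = mito_frac[i] * depth[i] / len(mito_idx)
        if is_male[i]:
            mu[i, y_idx] = y_frac * depth[i] / len(y_idx)
    lam = rng.gamma(shape=1.0 / cfg.dispersion, scale=mu * cfg.dispersion)
    counts = rng.poisson(lam).astype(np.int64)

    # --- assemble barcodes: singlets then doublets ------------------------
    doublet_members = {i for pair in doublet_pairs for i in pair}
    singlet_ids = [i for t in CELL_TYPES for i in singlet_draws[t]]
    n_barcodes = len(singlet_ids) + len(doublet_pairs)
    barcodes = _unique_barcodes(n_barcodes, rng)

    x = np.zeros((n_barcodes, cfg.n_genes), dtype=np.int64)
    contigs: list[ContigRecord] = []
    truth_rows: list[dict] = []

    def _emit_contigs(bc: str, draw_id: int) -> None:
        clone = draw_clone[draw_id]
        for ch, v, j, aa, nt in clone["chains_nt"]:
            contigs.append(
                ContigRecord(
                    barcode=bc, chain=ch, v_gene=v, j_gene=j, cdr3_aa=aa, cdr3_nt=nt,
                    productive=True, high_confidence=True,
                    umis=int(rng.integers(2, 30)),
                )
            )

    row = 0
    for draw_id in singlet_ids:
        bc = barcodes[row]
        d = draws[draw_id]
        clone = draw_clone[draw_id]
        x[row] = counts[draw_id]
        _emit_contigs(bc, draw_id)
        truth_rows.append(
            {
                "barcode": bc, "true_type": d["type"], "sex": d["sex"],
                "is_doublet": False, "true_cluster": d["cluster"],
                "canonical_alpha": clone["canonical_alpha"],
                "oligoclonal_beta": clone["oligoclonal_beta"],
                "clone_id": clone["clone_id"],
            }
        )
        row += 1
    for d1, d2 in doublet_pairs:
        bc = barcodes[row]
        first = draws[d1]
        x[row] = counts[d1] + counts[d2]
        _emit_contigs(bc, d1)
        _emit_contigs(bc, d2)
        truth_rows.append(
            {
                "barcode": bc, "true_type": first["type"],
                "sex": "male" if (draws[d1]["sex"] == "male" or draws[d2]["sex"] == "male") else "female",
                "is_doublet": True, "true_cluster": first["cluster"],
                "canonical_alpha": draw_clone[d1]["canonical_alpha"],
                "oligoclonal_beta": draw_clone[d1]["oligoclonal_beta"],
                "clone_id": draw_clone[d1]["clone_id"] + "+" + draw_clone[d2]["clone_id"],
            }
        )
        row += 1

    adata = ad.AnnData(
        X=sp.csr_matrix(x),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(gene_names, name="gene")),
    )
    adata.uns[LAYER_KEY] = LAYER_RAW
    annotate_genes(adata, y_genes=y_names)
    truth = pd.DataFrame(truth_rows).set_index("barcode")
    return adata, contigs, truth


def write_cohort(
    adata: ad.AnnData,
    contigs: Sequence[ContigRecord],
    truth: pd.DataFrame,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write the 10x-style MTX trio, contig CSV and truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = write_matrix_dir(adata, out / "matrix")
    paths["contigs"] = write_contigs(contigs, out / "filtered_contig_annotations.csv")
    truth_path = out / "truth.tsv"
    truth.to_csv(truth_path, sep="\t")
    paths["truth"] = truth_path
    return paths


def truth_cluster_labels(truth: pd.DataFrame) -> dict[str, str]:
    """Barcode -> cluster mapping from a truth table."""
    return {bc: str(c) for bc, c in truth["true_cluster"].items()}
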