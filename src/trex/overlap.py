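"""Resampling test for DEG-set overlap between analogous cell subsets.

Whether two subsets share more differentially expressed genes than chance
is assessed by simulating random draws of gene sets of the observed sizes
from a common tested-gene universe. The empirical one-sided p-value is
accompanied by the analytic hypergeometric upper tail, and a
direction-consistent variant counts only genes up- or down-regulated in
the same direction in both subsets. A companion statistic compares
fold-change correlation inside a gene category (e.g. cytokines and
receptors) against the remaining genes via label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class OverlapTestResult:
    n_universe: int
    size_a: int
    size_b: int
    k: int
    r: int
    null_mean: float
    null_sd: float
    p_empirical: float
    p_hypergeom: float
    k_dir: int | None = None


@dataclass(frozen=True)
class CategoryCorrelationResult:
    r_in: float
    r_out: float
    delta_r: float
    p_permutation: float
    n_in: int
    n_out: int


def extract_degs(
    table: pd.DataFrame, padj_max: float = 0.05, min_abs_lfc: float = 0.0
) -> tuple[set[str], set[str]]:
    """Split a DEG table (gene, log2fc, padj) into up- and down-sets."""
    for col in ("gene", "log2fc", "padj"):
        if col not in table.columns:
            raise ValueError(f"DEG table is missing column {col!r}")
    if table["gene"].duplicated().any():
        dups = table.loc[table["gene"].duplicated(), "gene"].head(5).tolist()
        raise ValueError(f"duplicate genes in DEG table: {dups}")
    padj = table["padj"].astype(float)
    if ((padj < 0) | (padj > 1)).any():
        raise ValueError("padj values must lie in [0, 1]")
    lfc = table["log2fc"].astype(float)
    sig = padj <= padj_max
    if min_abs_lfc > 0:
        up = sig & (lfc >= min_abs_lfc)
        down = sig & (lfc <= -min_abs_lfc)
    else:
        up = sig & (lfc > 0)
        down = sig & (lfc < 0)
    return set(table.loc[up, "gene"]), set(table.loc[down, "gene"])


def _as_rng(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _check_subset(name: str, s: set, universe: set) -> None:
    extra = sorted(s - universe)
    if extra:
        raise ValueError(f"{name} contains genes outside the universe: {extra[:10]}")


def overlap_test(
    set_a: Iterable[str],
    set_b: Iterable[str],
    universe: Iterable[str],
    r: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> OverlapTestResult:
    """Monte-Carlo overlap test against independent uniform draws.

    The null resamples ``r`` independent pairs of without-replacement
    samples of the observed sizes from the universe. The empirical p is
    (1 + #{null >= k}) / (r + 1); the analytic tail is P(X >= k) for
    X ~ Hypergeometric(N, |A|, |B|).
    """
    a, b = set(set_a), set(set_b)
    uni = sorted(set(universe))
    _check_subset("set A", a, set(uni))
    _check_subset("set B", b, set(uni))
    if r < 100:
        raise ValueError("r must be at least 100")
    n = len(uni)
    k = len(a & b)
    rng = _as_rng(seed)
    null = np.empty(r, dtype=np.int64)
    mask = np.zeros(n, dtype=bool)
    for i in range(r):
        sa = rng.choice(n, size=len(a), replace=False)
        sb = rng.choice(n, size=len(b), replace=False)
        mask[sa] = True
        null[i] = int(mask[sb].sum())
        mask[sa] = False
    p_emp = (1 + int((null >= k).sum())) / (r + 1)
    p_hyp = float(stats.hypergeom.sf(k - 1, n, len(a), len(b)))
    return OverlapTestResult(
        n_universe=n,
        size_a=len(a),
        size_b=len(b),
        k=k,
        r=r,
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        p_empirical=p_emp,
        p_hypergeom=p_hyp,
    )


def direction_consistent_overlap(
    up_a: Iterable[str],
    down_a: Iterable[str],
    up_b: Iterable[str],
    down_b: Iterable[str],
    universe: Iterable[str],
    r: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> OverlapTestResult:
    """Overlap counting only same-direction genes: |upA&upB| + |downA&downB|.

    The null preserves all four set sizes: for each subset, a combined
    sample of |up|+|down| genes is drawn and split, keeping up/down
    disjoint within the subset as observed.
    """
    ua, da, ub, db = set(up_a), set(down_a), set(up_b), set(down_b)
    if ua & da or ub & db:
        raise ValueError("up and down sets overlap within a subset")
    uni = sorted(set(universe))
    uniset = set(uni)
    for nm, s in (("up A", ua), ("down A", da), ("up B", ub), ("down B", db)):
        _check_subset(nm, s, uniset)
    if r < 100:
        raise ValueError("r must be at least 100")
    n = len(uni)
    k_dir = len(ua & ub) + len(da & db)
    k_any = len((ua | da) & (ub | db))
    rng = _as_rng(seed)
    null = np.empty(r, dtype=np.int64)
    up_mask = np.zeros(n, dtype=np.int8)
    for i in range(r):
        sa = rng.choice(n, size=len(ua) + len(da), replace=False)
        sb = rng.choice(n, size=len(ub) + len(db), replace=False)
        up_mask[sa[: len(ua)]] = 1
        up_mask[sa[len(ua) :]] = -1
        vals = up_mask[sb]
        null[i] = int((vals[: len(ub)] == 1).sum() + (vals[len(ub) :] == -1).sum())
        up_mask[sa] = 0
    p_emp = (1 + int((null >= k_dir).sum())) / (r + 1)
    p_hyp = float(
        stats.hypergeom.sf(k_dir - 1, n, len(ua) + len(da), len(ub) + len(db))
    )
    return OverlapTestResult(
        n_universe=n,
        size_a=len(ua) + len(da),
        size_b=len(ub) + len(db),
        k=k_any,
        r=r,
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        p_empirical=p_emp,
        p_hypergeom=p_hyp,
        k_dir=k_dir,
    )


def category_correlation(
    lfc_a: pd.Series,
    lfc_b: pd.Series,
    categories: Mapping[str, str] | pd.Series,
    category_of_interest: str,
    r: int = 1000,
    seed: int | np.random.Generator | None = None,
    method: str = "spearman",
) -> CategoryCorrelationResult:
    """Is fold-change correlation stronger inside a gene category?

    Computes the rank (or Pearson) correlation of (lfc_a, lfc_b) within the
    category and outside it, and the one-sided permutation p for
    delta_r = r_in - r_out under random reassignment of category labels.
    """
    cats = pd.Series(dict(categories)) if not isinstance(categories, pd.Series) else categories
    genes = sorted(set(lfc_a.index) & set(lfc_b.index) & set(cats.index))
    if len(genes) < 6:
        raise ValueError("need at least 6 shared genes")
    a = lfc_a.loc[genes].to_numpy(dtype=float)
    b = lfc_b.loc[genes].to_numpy(dtype=float)
    mask = (cats.loc[genes] == category_of_interest).to_numpy()
    n_in, n_out = int(mask.sum()), int((~mask).sum())
    if n_in < 3 or n_out < 3:
        raise ValueError(
            f"degenerate stratum: {n_in} genes in category, {n_out} outside"
        )
    for vec in (a[mask], b[mask], a[~mask], b[~mask]):
        if np.unique(vec).size < 2:
            raise ValueError("correlation undefined (constant fold-change stratum)")
    corr = _corr_fn(method)

    def _delta(m: np.ndarray) -> tuple[float, float, float]:
        ri = corr(a[m], b[m])
        ro = corr(a[~m], b[~m])
        return ri, ro, ri - ro

    r_in, r_out, delta = _delta(mask)
    if not np.isfinite(delta):
        raise ValueError("correlation undefined (constant fold-change stratum)")
    rng = _as_rng(seed)
    hits = 0
    perm = mask.copy()
    for _ in range(r):
        rng.shuffle(perm)
        _, _, d = _delta(perm)
        if d >= delta:
            hits += 1
    return CategoryCorrelationResult(
        r_in=float(r_in),
        r_out=float(r_out),
        delta_r=float(delta),
        p_permutation=(1 + hits) / (r + 1),
        n_in=n_in,
        n_out=n_out,
    )


def _corr_fn(method: str):
    if method == "spearman":
        return lambda x, y: float(stats.spearmanr(x, y).statistic)
    if method == "pearson":
        return lambda x, y: float(stats.pearsonr(x, y).statistic)
    raise ValueError(f"unknown correlation method {method!r}")
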