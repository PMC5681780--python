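"""Cell-type-level monoallelic calling and specificity statistics.

A gene is monoallelic (MA) in a cell type of one individual when at least
``min_supporting_cells`` cells support it — the gene is MA in the cell *and*
ranks in that cell's top expression percentile — and no cell of the type
shows biallelic (BA) expression of the gene. Any BA cell makes the gene BA
for the whole type; everything else is undetermined.

The permutation utilities (within- vs between-type overlap, split-half
overlap, saturation and shared-allele curves) re-run this caller on sampled
cell subsets, so the caller is also exposed as boolean gene-by-cell matrix
operations.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import PipelineConfig
from .types import CellMetadata, ExpressionMatrix


# ---------------------------------------------------------------------------
# expression-percentile filter

def top_percentile_mask(
    expr: ExpressionMatrix, percentile: float
) -> tuple[dict[str, set[str]], pd.Series]:
    """Per-cell set of genes in the top expression percentile.

    Non-expressed genes (FPKM == 0) are excluded before ranking; the top
    ``ceil(percentile * n_expressed)`` genes are retained, breaking FPKM
    ties by gene_id lexicographic order. Also returns the per-cell FPKM
    cutoff (the smallest retained value; NaN for cells with nothing
    expressed).
    """
    if not (0.0 < percentile <= 1.0):
        raise ValueError("percentile must lie in (0, 1]")
    mask: dict[str, set[str]] = {}
    cutoffs: dict[str, float] = {}
    df = expr.df
    for cell in df.columns:
        col = df[cell]
        pos = col[col > 0]
        if pos.empty:
            mask[cell] = set()
            cutoffs[cell] = float("nan")
            continue
        k = math.ceil(percentile * len(pos))
        tie_sorted = (
            pos.rename("fpkm").rename_axis("gene_id").reset_index()
            .sort_values(["fpkm", "gene_id"], ascending=[False, True], kind="mergesort")
        )
        top = tie_sorted.head(k)
        mask[cell] = set(top.gene_id)
        cutoffs[cell] = float(top.fpkm.min())
    return mask, pd.Series(cutoffs, name="fpkm_cutoff")


# ---------------------------------------------------------------------------
# matrix form of the per-(gene, cell) evidence

class TypeMatrices:
    """Boolean gene-by-cell evidence used by the cell-type caller.

    ``supporting[i, j]`` — gene i is MA in cell j and passes the expression
    mask there; ``ba[i, j]`` — gene i is BA in cell j; ``covered[i, j]`` —
    gene i has any (even Unknown) call in cell j.
    """

    def __init__(
        self,
        gene_calls: pd.DataFrame,
        mask: Mapping[str, set[str]],
        cell_ids: Sequence[str],
    ):
        self.cell_ids = list(cell_ids)
        cset = set(self.cell_ids)
        sub = gene_calls[gene_calls.cell_id.isin(cset)]
        self.gene_ids = np.array(sorted(sub.gene_id.unique()))
        gi = {g: i for i, g in enumerate(self.gene_ids)}
        cj = {c: j for j, c in enumerate(self.cell_ids)}
        shape = (len(self.gene_ids), len(self.cell_ids))
        self.supporting = np.zeros(shape, dtype=bool)
        self.ba = np.zeros(shape, dtype=bool)
        self.covered = np.zeros(shape, dtype=bool)
        for r in sub.itertuples(index=False):
            i, j = gi[r.gene_id], cj[r.cell_id]
            self.covered[i, j] = True
            if r.status == "BA":
                self.ba[i, j] = True
            elif r.status == "MA" and r.gene_id in mask.get(r.cell_id, ()):
                self.supporting[i, j] = True

    def ma_mask(self, cols: np.ndarray, min_support: int) -> np.ndarray:
        """Boolean gene vector: cell-type MA over the given cell columns."""
        sup = self.supporting[:, cols].sum(axis=1)
        vetoed = self.ba[:, cols].any(axis=1)
        return (sup >= min_support) & ~vetoed

    def ma_genes(self, cols: np.ndarray, min_support: int) -> set[str]:
        return set(self.gene_ids[self.ma_mask(cols, min_support)])

    def columns_of(self, cells: Sequence[str]) -> np.ndarray:
        index = {c: j for j, c in enumerate(self.cell_ids)}
        return np.array([index[c] for c in cells], dtype=int)


# ---------------------------------------------------------------------------
# cell-type calls

def call_celltype_ma(
    gene_calls: pd.DataFrame,
    mask: Mapping[str, set[str]],
    cells: CellMetadata,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Cell-type MA/BA/undetermined status per (gene, individual, cell type).

    A supporting cell has the gene MA *and* in its top-percentile mask; MA
    requires >= ``min_supporting_cells`` supporting cells and no BA cell of
    the type (the BA veto applies regardless of the vetoing cell's
    expression rank). Unknown gene calls neither support nor veto.
    """
    rows = []
    with_meta = gene_calls.merge(cells.df, on="cell_id")
    for (ind, ct), grp in with_meta.groupby(["individual", "cell_type"], sort=True):
        type_cells = cells.cells_of(individual=ind, cell_type=ct)
        tm = TypeMatrices(grp, mask, type_cells)
        if len(tm.gene_ids) == 0:
            continue
        cols = np.arange(len(type_cells))
        sup_counts = tm.supporting.sum(axis=1)
        any_ba = tm.ba.any(axis=1)
        is_ma = tm.ma_mask(cols, config.min_supporting_cells)
        cell_arr = np.array(type_cells)
        for i, gene in enumerate(tm.gene_ids):
            if any_ba[i]:
                status = "BA"
            elif is_ma[i]:
                status = "MA"
            else:
                status = "undetermined"
            supp = cell_arr[tm.supporting[i]]
            rows.append(
                (gene, ind, ct, int(sup_counts[i]), ",".join(supp), status)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "individual",
            "cell_type",
            "n_supporting_cells",
            "supporting_cells",
            "status",
        ],
    )


def background_genes(
    gene_calls: pd.DataFrame,
    cells: CellMetadata,
    individual: str,
    cell_type: str,
    definition: str = "covered",
    expr: ExpressionMatrix | None = None,
    config: PipelineConfig | None = None,
) -> set[str]:
    """Background gene set for between-type comparisons.

    ``covered``: genes with >= 1 covered hetSNP in >= 1 cell of the type
    (Venn-style background). ``expressed``: genes among those whose mean
    FPKM over the type's cells reaches ``config.background_mean_fpkm``
    (Fisher-test background).
    """
    type_cells = cells.cells_of(individual=individual, cell_type=cell_type)
    sub = gene_calls[gene_calls.cell_id.isin(set(type_cells))]
    covered = set(sub.gene_id.unique())
    if definition == "covered":
        return covered
    if definition == "expressed":
        if expr is None or config is None:
            raise ValueError("'expressed' background needs expr and config")
        present = [c for c in type_cells if c in expr.df.columns]
        means = expr.df.loc[list(covered & set(expr.df.index)), present].mean(axis=1)
        return set(means[means >= config.background_mean_fpkm].index)
    raise ValueError(f"unknown background definition {definition!r}")


def ma_overlap_fisher(
    ma_a: set[str], ma_b: set[str], background: set[str]
) -> tuple[float, float]:
    """Fisher's exact test for association of two MA gene sets over a
    background. Returns (odds_ratio, p)."""
    a = ma_a & background
    b = ma_b & background
    both = len(a & b)
    only_a = len(a - b)
    only_b = len(b - a)
    neither = len(background) - both - only_a - only_b
    odds, p = sps.fisher_exact([[both, only_a], [only_b, neither]])
    return float(odds), float(p)


# ---------------------------------------------------------------------------
# permutation statistics

def _overlap_pct(a: set[str], b: set[str], denominator: str) -> float:
    inter = len(a & b)
    if denominator in ("union", "either"):
        denom = len(a | b)
    elif denominator == "min":
        denom = min(len(a), len(b))
    else:
        raise ValueError(f"unknown overlap denominator {denominator!r}")
    return 100.0 * inter / denom if denom else float("nan")


def between_vs_within_permutation(
    gene_calls: pd.DataFrame,
    mask: Mapping[str, set[str]],
    cells: CellMetadata,
    individual: str,
    type_a: str,
    type_b: str,
    config: PipelineConfig,
    n_iter: int | None = None,
    seed: int | None = None,
) -> dict:
    """Within- vs between-type overlap of MA gene sets by cell resampling.

    Per draw: *within* — two disjoint groups of k cells sampled from
    ``type_a`` (k = number of ``type_b`` cells), MA genes called in each,
    overlap counted; *between* — k cells sampled from ``type_a`` against all
    ``type_b`` cells. Overlap means are compared with a two-sample t-test.
    """
    n_iter = n_iter or config.n_permutations
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    a_cells = cells.cells_of(individual=individual, cell_type=type_a)
    b_cells = cells.cells_of(individual=individual, cell_type=type_b)
    k = len(b_cells)
    if len(a_cells) < 2 * k:
        raise ValueError(
            f"type {type_a!r} has {len(a_cells)} cells; needs >= {2 * k} "
            f"(two disjoint groups of k={k})"
        )
    tm = TypeMatrices(gene_calls, mask, a_cells + b_cells)
    a_cols = tm.columns_of(a_cells)
    b_cols = tm.columns_of(b_cells)
    ms = config.min_supporting_cells
    ma_b = tm.ma_mask(b_cols, ms)
    within = np.empty(n_iter)
    between = np.empty(n_iter)
    for it in range(n_iter):
        draw = rng.choice(a_cols, size=2 * k, replace=False)
        m1 = tm.ma_mask(draw[:k], ms)
        m2 = tm.ma_mask(draw[k:], ms)
        within[it] = int((m1 & m2).sum())
        draw_b = rng.choice(a_cols, size=k, replace=False)
        between[it] = int((tm.ma_mask(draw_b, ms) & ma_b).sum())
    t_stat, p = sps.ttest_ind(within, between)
    return {
        "within_overlaps": within,
        "between_overlaps": between,
        "within_mean": float(within.mean()),
        "between_mean": float(between.mean()),
        "t_statistic": float(t_stat),
        "p_value": float(p),
        "k": k,
        "n_iter": n_iter,
    }


def split_half_overlap(
    gene_calls: pd.DataFrame,
    mask: Mapping[str, set[str]],
    cells: CellMetadata,
    individual: str,
    cell_type: str,
    config: PipelineConfig,
    n_iter: int | None = None,
    seed: int | None = None,
) -> dict:
    """Overlap percentage of MA gene sets between random half-splits.

    The percentage is 100 * |intersection| / |union| by default
    (``config.overlap_denominator``); draws where both halves call no MA
    gene are reported as NaN and excluded from the summary.
    """
    n_iter = n_iter or config.n_permutations
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    type_cells = cells.cells_of(individual=individual, cell_type=cell_type)
    n = len(type_cells)
    if n < 2 * config.min_supporting_cells:
        raise ValueError(
            f"{cell_type!r} has {n} cells; split halves cannot both satisfy "
            f"the >={config.min_supporting_cells}-cell rule"
        )
    tm = TypeMatrices(gene_calls, mask, type_cells)
    cols = np.arange(n)
    ms = config.min_supporting_cells
    half = n // 2
    pcts = np.empty(n_iter)
    for it in range(n_iter):
        perm = rng.permutation(cols)
        g1 = tm.ma_genes(perm[:half], ms)
        g2 = tm.ma_genes(perm[half:], ms)
        pcts[it] = _overlap_pct(g1, g2, config.overlap_denominator)
    valid = pcts[~np.isnan(pcts)]
    return {
        "overlap_pcts": pcts,
        "mean": float(valid.mean()) if valid.size else float("nan"),
        "min": float(valid.min()) if valid.size else float("nan"),
        "max": float(valid.max()) if valid.size else float("nan"),
        "n_valid": int(valid.size),
    }


def saturation_curve(
    gene_calls: pd.DataFrame,
    mask: Mapping[str, set[str]],
    cells: CellMetadata,
    individual: str,
    cell_type: str,
    config: PipelineConfig,
    n_iter: int | None = None,
    seed: int | None = None,
    subset_sizes: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Mean number of cell-type MA genes vs number of cells subsampled.

    All C(n, k) subsets are enumerated when there are no more of them than
    ``n_iter``; otherwise ``n_iter`` random subsets are drawn.
    """
    n_iter = n_iter or config.n_permutations
    rng = np.random.default_rng(config.rng_seed if seed is None else seed)
    type_cells = cells.cells_of(individual=individual, cell_type=cell_type)
    n = len(type_cells)
    if n < 5:
        raise ValueError(f"{cell_type!r} has {n} cells; need >= 5")
    tm = TypeMatrices(gene_calls, mask, type_cells)
    ms = config.min_supporting_cells
    sizes = list(subset_sizes) if subset_sizes is not None else list(range(1, n + 1))
    rows = []
    for k in sizes:
        if math.comb(n, k) <= n_iter:
            counts = [
                int(tm.ma_mask(np.array(combo), ms).sum())
                for combo in itertools.combinations(range(n), k)
            ]
            exact = True
        else:
            counts = [
                int(tm.ma_mask(rng.choice(n, size=k, replace=False), ms).sum())
                for _ in range(n_iter)
            ]
            exact = False
        rows.append(
            {
                "n_cells": k,
                "mean_ma_genes": float(np.mean(counts)),
                "n_draws": len(counts),
                "exact": exact,
            }
        )
    return pd.DataFrame(rows)


def shared_ma_alleles_pairs(
    calls: pd.DataFrame,
    cells: CellMetadata,
    individual: str,
    cell_type: str,
    n_pairs: int = 1000,
    seed: int = 0,
    denominator: str = "union",
) -> dict:
    """Percentage of MA hetSNP alleles shared between random cell pairs.

    A site is shared when it is MA in both cells with the same expressed
    allele; the percentage divides by the number of sites MA in either cell
    (``union``), in both (``both``) or in the first (``either_cell_min`` =
    smaller MA set), per ``denominator``.
    """
    type_cells = cells.cells_of(individual=individual, cell_type=cell_type)
    if len(type_cells) < 2:
        raise ValueError(f"{cell_type!r} needs >= 2 cells")
    ma = calls[(calls.status == "MA") & calls.cell_id.isin(set(type_cells))]
    allele_of: dict[str, dict[str, str]] = {c: {} for c in type_cells}
    for r in ma.itertuples(index=False):
        allele_of[r.cell_id][r.site_id] = r.expressed_allele
    rng = np.random.default_rng(seed)
    pcts = np.empty(n_pairs)
    for it in range(n_pairs):
        c1, c2 = rng.choice(len(type_cells), size=2, replace=False)
        m1, m2 = allele_of[type_cells[c1]], allele_of[type_cells[c2]]
        shared = sum(1 for s, a in m1.items() if m2.get(s) == a)
        if denominator == "union":
            denom = len(set(m1) | set(m2))
        elif denominator == "both":
            denom = len(set(m1) & set(m2))
        elif denominator == "min":
            denom = min(len(m1), len(m2))
        else:
            raise ValueError(f"unknown denominator {denominator!r}")
        pcts[it] = 100.0 * shared / denom if denom else float("nan")
    valid = pcts[~np.isnan(pcts)]
    return {
        "shared_pcts": pcts,
        "mean": float(valid.mean()) if valid.size else float("nan"),
        "min": float(valid.min()) if valid.size else float("nan"),
        "max": float(valid.max()) if valid.size else float("nan"),
        "n_valid": int(valid.size),
    }


# ---------------------------------------------------------------------------
# parameter recovery against simulation ground truth

def evaluate_recovery(
    celltype_calls: pd.DataFrame,
    gene_calls: pd.DataFrame,
    mask: Mapping[str, set[str]],
    cells: CellMetadata,
    truth_labels: pd.DataFrame,
    config: PipelineConfig,
) -> dict:
    """Recall and false-call rate of the cell-type MA caller vs ground truth.

    ``truth_labels`` holds gene_id, cell_type, label (MA/BA) per the
    generator's modes. Recall is computed over *assessable* truth-MA
    (gene, cell type) pairs: the gene must sit in the expression mask with a
    covered hetSNP call in at least ``min_supporting_cells`` cells of the
    type — outside that set the expression-percentile filter makes the gene
    undetectable by design, for any caller. The false-MA rate is the
    fraction of truth-BA pairs (no assessability condition) called MA.
    """
    gm = gene_calls.merge(cells.df, on="cell_id")
    in_mask = np.array(
        [g in mask.get(c, ()) for g, c in zip(gm.gene_id, gm.cell_id)], dtype=bool
    )
    elig_counts = gm[in_mask].groupby(["gene_id", "individual", "cell_type"]).size()
    assessable = set(
        elig_counts[elig_counts >= config.min_supporting_cells].index
    )
    merged = celltype_calls.merge(truth_labels, on=["gene_id", "cell_type"])
    keys = list(zip(merged.gene_id, merged.individual, merged.cell_type))
    merged["assessable"] = [k in assessable for k in keys]
    truth_ma = merged[(merged.label == "MA") & merged.assessable]
    truth_ba = merged[merged.label == "BA"]
    recall = float((truth_ma.status == "MA").mean()) if len(truth_ma) else float("nan")
    false_ma = float((truth_ba.status == "MA").mean()) if len(truth_ba) else float("nan")
    return {
        "n_truth_ma_assessable": int(len(truth_ma)),
        "n_truth_ba": int(len(truth_ba)),
        "recall": recall,
        "false_ma_rate": false_ma,
    }
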