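"""Per-cell allelic classification and pseudo-bulk ratio analysis.

Each (hetSNP, cell) observation with at least one informative read receives
one of three verdicts:

* **MA** (monoallelic): BH-adjusted exact binomial p-value < ``ma_fdr`` and
  strictly more than ``ma_ratio`` (default 95%) of the ref+alt reads from
  one allele;
* **BA** (biallelic): not MA, and both alleles carry at least
  ``ba_min_allele_reads`` (default 2) reads;
* **Unknown**: covered but satisfying neither rule.

MA takes precedence over BA. Reads matching neither candidate allele are
ignored throughout. The BH family is, by default, all (site, cell) tests of
the table passed in (one individual); per-cell adjustment is available via
``config.bh_family``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .stats import bh_adjust, binom_test_one_sided, binom_test_two_sided
from .types import AllelicCountTable, CellMetadata, SnpSite

CALL_COLUMNS = [
    "site_id",
    "cell_id",
    "ref_depth",
    "alt_depth",
    "ref_ratio",
    "p_value",
    "fdr",
    "status",
    "expressed_allele",
]


def classify_cells(
    counts: AllelicCountTable,
    hetsnps: Iterable[str],
    config: PipelineConfig,
) -> pd.DataFrame:
    """Classify every covered (hetSNP, cell) observation.

    ``counts`` should hold the cells forming one BH family (typically one
    individual). Returns one row per observation with ref+alt >= 1.
    """
    het = set(hetsnps)
    df = counts.df[counts.df.site_id.isin(het)].copy()
    n = df.ref_depth + df.alt_depth
    df = df[n >= 1].reset_index(drop=True)
    if df.empty:
        return pd.DataFrame(columns=CALL_COLUMNS)
    n = (df.ref_depth + df.alt_depth).to_numpy()
    k = df.ref_depth.to_numpy()
    if config.binom_alternative == "two-sided":
        p = binom_test_two_sided(k, n)
    else:
        p = binom_test_one_sided(k, n)
    df["ref_ratio"] = k / n
    df["p_value"] = p
    if config.bh_family == "per_cell":
        df["fdr"] = df.groupby("cell_id").p_value.transform(lambda s: bh_adjust(s.to_numpy()))
    else:
        df["fdr"] = bh_adjust(p)
    major = np.maximum(df.ref_ratio, 1.0 - df.ref_ratio)
    is_ma = (major > config.ma_ratio) & (df.fdr < config.ma_fdr)
    is_ba = ~is_ma & (
        np.minimum(df.ref_depth, df.alt_depth) >= config.ba_min_allele_reads
    )
    df["status"] = np.where(is_ma, "MA", np.where(is_ba, "BA", "Unknown"))
    df["expressed_allele"] = np.where(
        is_ma, np.where(df.ref_depth > df.alt_depth, "ref", "alt"), "none"
    )
    return df[CALL_COLUMNS]


def pseudo_bulk_ratios(
    counts: AllelicCountTable,
    cells: CellMetadata,
    group_by: str = "individual",
) -> pd.DataFrame:
    """Reference-allele ratios after pooling reads per group.

    ``group_by``: "individual" or "individual×cell_type" (the ASCII form
    "individual x cell_type" is accepted). Ratios use pooled integer sums;
    sites with zero pooled ref+alt coverage in a group are omitted.
    """
    keys = {"individual": ["individual"],
            "individual×cell_type": ["individual", "cell_type"],
            "individual x cell_type": ["individual", "cell_type"]}
    if group_by not in keys:
        raise ValueError(f"unknown group_by {group_by!r}")
    merged = counts.df.merge(cells.df, on="cell_id")
    grouped = (
        merged.groupby(["site_id"] + keys[group_by], as_index=False)[["ref_depth", "alt_depth"]]
        .sum()
        .rename(columns={"ref_depth": "pooled_ref", "alt_depth": "pooled_alt"})
    )
    depth = grouped.pooled_ref + grouped.pooled_alt
    grouped = grouped[depth > 0].copy()
    grouped["pooled_depth"] = grouped.pooled_ref + grouped.pooled_alt
    grouped["ref_ratio"] = grouped.pooled_ref / grouped.pooled_depth
    group_cols = keys[group_by]
    grouped["group"] = grouped[group_cols].agg("|".join, axis=1)
    return grouped[["site_id", "group", "pooled_ref", "pooled_alt", "pooled_depth", "ref_ratio"]]


def ratio_band_histogram(ratios: pd.Series, width: float = 0.1) -> pd.DataFrame:
    """Histogram of reference-allele ratios in fixed-width bands.

    Bands are closed on the left, the last band closed on both sides; the
    band fraction in [0.4, 0.6] (boundaries included) is what grows as more
    cells are pooled for randomly monoallelic genes.
    """
    edges = np.round(np.arange(0.0, 1.0 + width / 2, width), 10)
    counts, _ = np.histogram(ratios, bins=edges)
    return pd.DataFrame(
        {"band_low": edges[:-1], "band_high": edges[1:], "n_sites": counts}
    )


def band_fraction(ratios: pd.Series, low: float = 0.4, high: float = 0.6) -> float:
    """Fraction of sites with pooled reference ratio in [low, high]."""
    r = np.asarray(ratios, dtype=float)
    if r.size == 0:
        return float("nan")
    return float(((r >= low) & (r <= high)).mean())


def imprinted_ratio_check(
    pseudo_bulk: pd.DataFrame,
    imprinted_genes: set[str],
    sites: Sequence[SnpSite],
) -> dict:
    """Do imprinted genes' pooled ratios deviate from 0.5 more than others'?

    Compares |ratio - 0.5| between sites of imprinted and non-imprinted
    genes with a one-sided rank-sum test (alternative: imprinted deviate
    more). Sites mapping to exactly one gene are used.
    """
    from .stats import rank_sum_test
    from .types import single_gene_map

    if not imprinted_genes:
        raise ValueError("imprinted gene set is empty")
    gene_of = single_gene_map(sites)
    df = pseudo_bulk.copy()
    df["gene_id"] = df.site_id.map(gene_of)
    df = df.dropna(subset=["gene_id"])
    df["deviation"] = (df.ref_ratio - 0.5).abs()
    imp = df[df.gene_id.isin(imprinted_genes)].deviation.to_numpy()
    rest = df[~df.gene_id.isin(imprinted_genes)].deviation.to_numpy()
    if imp.size == 0 or rest.size == 0:
        raise ValueError("need pseudo-bulk observations in both gene groups")
    med_imp, med_rest, stat, p = rank_sum_test(imp, rest, alternative="greater")
    return {
        "n_imprinted_obs": int(imp.size),
        "n_other_obs": int(rest.size),
        "median_deviation_imprinted": med_imp,
        "median_deviation_other": med_rest,
        "rank_sum_statistic": stat,
        "p_value": p,
    }
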