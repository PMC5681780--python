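"""SNP-level to gene-level mapping of allelic status.

A gene's per-cell status aggregates its hetSNP verdicts hierarchically:
biallelic evidence at any SNP makes the gene biallelic in that cell; a gene
with only monoallelic (and possibly Unknown) SNPs is monoallelic; genes with
only Unknown SNPs stay Unknown. SNPs mapping to more than one gene (or to
none) are excluded beforehand.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .types import SnpSite, single_gene_map

GENE_CALL_COLUMNS = ["gene_id", "cell_id", "n_snps_ma", "n_snps_ba", "n_snps_unknown", "status"]


def _with_gene(calls: pd.DataFrame, sites: Sequence[SnpSite]) -> pd.DataFrame:
    gene_of = single_gene_map(sites)
    df = calls.copy()
    df["gene_id"] = df.site_id.map(gene_of)
    return df.dropna(subset=["gene_id"])


def gene_status_per_cell(calls: pd.DataFrame, sites: Sequence[SnpSite]) -> pd.DataFrame:
    """Per (gene, cell) status from SNP-level calls (hierarchy BA > MA > Unknown)."""
    df = _with_gene(calls, sites)
    if df.empty:
        return pd.DataFrame(columns=GENE_CALL_COLUMNS)
    tally = (
        df.assign(
            n_snps_ma=(df.status == "MA").astype(int),
            n_snps_ba=(df.status == "BA").astype(int),
            n_snps_unknown=(df.status == "Unknown").astype(int),
        )
        .groupby(["gene_id", "cell_id"], as_index=False)[
            ["n_snps_ma", "n_snps_ba", "n_snps_unknown"]
        ]
        .sum()
    )
    tally["status"] = np.where(
        tally.n_snps_ba >= 1, "BA", np.where(tally.n_snps_ma >= 1, "MA", "Unknown")
    )
    return tally[GENE_CALL_COLUMNS]


def two_snp_consistency(calls: pd.DataFrame, sites: Sequence[SnpSite]) -> dict:
    """Status agreement between SNP pairs of genes with exactly two
    determinate (MA or BA) SNP calls in a cell."""
    df = _with_gene(calls, sites)
    det = df[df.status.isin(["MA", "BA"])]
    sizes = det.groupby(["gene_id", "cell_id"]).status
    n_ma = sizes.agg(lambda s: (s == "MA").sum())
    n_det = sizes.size()
    two = n_det == 2
    ma_counts = n_ma[two]
    n_ma_ma = int((ma_counts == 2).sum())
    n_ba_ba = int((ma_counts == 0).sum())
    n_ma_ba = int((ma_counts == 1).sum())
    total = n_ma_ma + n_ba_ba + n_ma_ba
    return {
        "n_gene_cell_pairs": total,
        "n_ma_ma": n_ma_ma,
        "n_ba_ba": n_ba_ba,
        "n_ma_ba": n_ma_ba,
        "consistency_pct": 100.0 * (n_ma_ma + n_ba_ba) / total if total else float("nan"),
    }


def snp_per_gene_histogram(calls: pd.DataFrame, sites: Sequence[SnpSite]) -> pd.DataFrame:
    """Distribution of covered hetSNPs per (gene, cell): bins 1, 2, >2."""
    df = _with_gene(calls, sites)
    n = df.groupby(["gene_id", "cell_id"]).size()
    bins = pd.Series(np.where(n == 1, "1", np.where(n == 2, "2", ">2")), index=n.index)
    out = bins.value_counts().reindex(["1", "2", ">2"], fill_value=0)
    total = int(out.sum())
    return pd.DataFrame(
        {
            "n_hetsnps": out.index,
            "n_gene_cell_obs": out.to_numpy(),
            "fraction": out.to_numpy() / total if total else np.nan,
        }
    )
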