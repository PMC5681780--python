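"""Expression of functionally disrupted alleles vs their counterparts.

Two complementary views per annotation scheme (SNV class, SIFT, PolyPhen
HDIV/HVAR):

* per hetSNP, the number of cells expressing each allele (an allele with
  >= 2 reads counts as expressed in a cell) — deleterious alternative
  alleles should be expressed in fewer cells;
* per qualifying (hetSNP, cell), the fraction of reads from the reference
  allele (both alleles >= 2 reads, total >= 10) — deleterious alternative
  alleles should pull the fraction above the synonymous baseline.

Class contrasts use one-sided Wilcoxon rank-sum tests.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .config import PipelineConfig
from .stats import rank_sum_test
from .types import AllelicCountTable, AnnotationTable


def expressing_cell_counts(
    counts: AllelicCountTable,
    annot: AnnotationTable,
    hetsnps: Iterable[str],
    scheme: str,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Cells expressing each allele per hetSNP, with annotation class.

    Returns site_id, annotation_class, n_cells_ref, n_cells_alt. Sites
    without a class label in the scheme are omitted.
    """
    config = config or PipelineConfig()
    classes = annot.classes(scheme)
    het = set(hetsnps)
    sub = counts.df[counts.df.site_id.isin(het)]
    thr = config.disruption_min_each
    agg = (
        sub.assign(
            ref_ok=(sub.ref_depth >= thr).astype(int),
            alt_ok=(sub.alt_depth >= thr).astype(int),
        )
        .groupby("site_id")[["ref_ok", "alt_ok"]]
        .sum()
        .rename(columns={"ref_ok": "n_cells_ref", "alt_ok": "n_cells_alt"})
    )
    agg = agg.reindex(sorted(het), fill_value=0)
    out = agg.reset_index()
    out["annotation_class"] = out.site_id.map(classes)
    out = out.dropna(subset=["annotation_class"])
    return out[["site_id", "annotation_class", "n_cells_ref", "n_cells_alt"]].reset_index(drop=True)


def ref_fraction_by_class(
    counts: AllelicCountTable,
    annot: AnnotationTable,
    hetsnps: Iterable[str],
    scheme: str,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Reference-read fractions at well-covered (hetSNP, cell) observations.

    Keeps observations with both alleles >= ``disruption_min_each`` reads
    and total ref+alt >= ``disruption_min_sum``; a SNP expressed in several
    cells contributes one observation per cell.
    """
    config = config or PipelineConfig()
    classes = annot.classes(scheme)
    het = set(hetsnps)
    sub = counts.df[counts.df.site_id.isin(het)].copy()
    each_ok = (sub.ref_depth >= config.disruption_min_each) & (
        sub.alt_depth >= config.disruption_min_each
    )
    sum_ok = (sub.ref_depth + sub.alt_depth) >= config.disruption_min_sum
    sub = sub[each_ok & sum_ok]
    sub["annotation_class"] = sub.site_id.map(classes)
    sub = sub.dropna(subset=["annotation_class"])
    sub["ref_fraction"] = sub.ref_depth / (sub.ref_depth + sub.alt_depth)
    return sub[["site_id", "cell_id", "annotation_class", "ref_fraction"]].reset_index(drop=True)


def class_comparison_tests(
    observations: pd.DataFrame,
    value_col: str,
    class_a: str,
    class_b: str,
    alternative: str,
) -> dict:
    """One-sided rank-sum contrast of one value column between two classes.

    ``alternative``: "greater" tests whether class_a values exceed class_b,
    "less" the reverse. Medians of both classes are reported alongside the
    statistic.
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    a = observations.loc[observations.annotation_class == class_a, value_col].to_numpy()
    b = observations.loc[observations.annotation_class == class_b, value_col].to_numpy()
    for name, vals in ((class_a, a), (class_b, b)):
        if vals.size == 0:
            raise ValueError(f"annotation class {name!r} has no observations")
    med_a, med_b, stat, p = rank_sum_test(a, b, alternative)
    return {
        "class_a": class_a,
        "class_b": class_b,
        "n_a": int(a.size),
        "n_b": int(b.size),
        "median_a": med_a,
        "median_b": med_b,
        "statistic": stat,
        "p_value": p,
        "alternative": alternative,
    }


def allele_count_long(counts_by_site: pd.DataFrame) -> pd.DataFrame:
    """Long form of expressing-cell counts: one row per (site, allele)."""
    ref = counts_by_site[["site_id", "annotation_class", "n_cells_ref"]].rename(
        columns={"n_cells_ref": "n_cells"}
    )
    ref["allele"] = "ref"
    alt = counts_by_site[["site_id", "annotation_class", "n_cells_alt"]].rename(
        columns={"n_cells_alt": "n_cells"}
    )
    alt["allele"] = "alt"
    return pd.concat([ref, alt], ignore_index=True)


def ref_vs_alt_cells_test(
    counts_by_site: pd.DataFrame, annotation_class: str
) -> dict:
    """Within one class: are alternative alleles expressed in fewer cells?

    One-sided rank-sum of per-site expressing-cell counts, reference vs
    alternative allele (alternative hypothesis: reference counts greater).
    """
    sub = counts_by_site[counts_by_site.annotation_class == annotation_class]
    if sub.empty:
        raise ValueError(f"annotation class {annotation_class!r} has no sites")
    med_r, med_a, stat, p = rank_sum_test(
        sub.n_cells_ref.to_numpy(), sub.n_cells_alt.to_numpy(), "greater"
    )
    return {
        "annotation_class": annotation_class,
        "n_sites": int(len(sub)),
        "median_ref_cells": med_r,
        "median_alt_cells": med_a,
        "statistic": stat,
        "p_value": p,
    }
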