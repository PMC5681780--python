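"""Genotype-free heterozygous-SNP calling from pooled allelic depths.

Reads from all cells of one individual are pooled per candidate site; a site
is called heterozygous when both candidate alleles reach the pooled read-
depth cutoff (default 20 reads each). Sites whose reference allele is absent
from the pooled pileup — i.e. dominated by two non-reference bases — are
excluded up front. With truth genotypes available (F1-cross style data or a
simulation), the cutoff sweep yields positive predictive value and true-
positive rate per cutoff.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .simulate import TruthSet
from .types import AllelicCountTable, CellMetadata, SnpSite


def pool_depths(
    counts: AllelicCountTable, cells: CellMetadata, individual: str
) -> pd.DataFrame:
    """Sum allelic depths over all cells of one individual.

    Returns a frame with site_id, pooled_ref, pooled_alt, pooled_other,
    omitting sites with zero pooled coverage.
    """
    if individual not in cells.df.individual.values:
        raise ValueError(f"unknown individual {individual!r}")
    member = counts.df.cell_id.isin(set(cells.cells_of(individual=individual)))
    sub = counts.df[member]
    pooled = (
        sub.groupby("site_id", as_index=False)[["ref_depth", "alt_depth", "other_depth"]]
        .sum()
        .rename(
            columns={
                "ref_depth": "pooled_ref",
                "alt_depth": "pooled_alt",
                "other_depth": "pooled_other",
            }
        )
    )
    total = pooled.pooled_ref + pooled.pooled_alt + pooled.pooled_other
    return pooled[total > 0].reset_index(drop=True)


def reference_absent(pooled: pd.DataFrame) -> pd.Series:
    """Boolean mask of sites whose reference allele is effectively absent.

    A site is dropped when the reference base is unobserved, or when both
    the alternative allele and reads matching neither candidate allele
    strictly out-support it (the two most-supported bases then both differ
    from the reference). Ties keep the site.
    """
    return (pooled.pooled_ref == 0) | (
        (pooled.pooled_alt > pooled.pooled_ref)
        & (pooled.pooled_other > pooled.pooled_ref)
    )


def call_hetsnps(
    pooled: pd.DataFrame, sites: Sequence[SnpSite] | None, cutoff: int
) -> list[str]:
    """Heterozygous sites at one pooled-depth cutoff.

    Both alleles must reach ``cutoff`` pooled reads; reference-absent sites
    are excluded first. ``sites`` restricts calls to the candidate list when
    given.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    keep = ~reference_absent(pooled)
    called = pooled[
        keep & (pooled.pooled_ref >= cutoff) & (pooled.pooled_alt >= cutoff)
    ].site_id
    if sites is not None:
        known = {s.site_id for s in sites}
        called = called[called.isin(known)]
    return sorted(called)


def calibrate_cutoff(
    pooled: pd.DataFrame, truth: TruthSet, cutoffs: Iterable[int]
) -> pd.DataFrame:
    """PPV/TPR of the het call against truth genotypes over a cutoff sweep.

    ppv(c) = |called(c) & truth_het| / |called(c)| — NaN when nothing is
    called; tpr(c) = |called(c) & truth_het| / |truth_het|.
    """
    het = truth.het_sites
    if not het:
        raise ValueError("truth set contains no heterozygous sites")
    rows = []
    for c in cutoffs:
        called = set(call_hetsnps(pooled, None, int(c)))
        tp = len(called & het)
        rows.append(
            {
                "cutoff": int(c),
                "n_called": len(called),
                "n_true_het": tp,
                "ppv": tp / len(called) if called else np.nan,
                "tpr": tp / len(het),
            }
        )
    return pd.DataFrame(rows)
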