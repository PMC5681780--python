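"""Pipeline configuration.

All thresholds of the allelic-expression pipeline live in one dataclass so
that every stage is driven by the same, serialisable set of parameters.
Defaults correspond to the published analysis protocol for SMART-seq style
single-cell RNA-seq of human brain: heterozygous sites require >=20 pooled
reads per allele; a site-in-cell is monoallelic when the BH-adjusted exact
binomial p-value (null: balanced expression) is < 0.05 and >95% of reads come
from one allele; biallelic when both alleles have >=2 reads; cell-type
monoallelic calls need >=4 supporting cells, each expressing the gene in its
top 30% of expressed genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml

DEFAULT_CELL_TYPES: tuple[str, ...] = (
    "astrocyte",
    "microglia",
    "neuron",
    "oligodendrocyte",
    "OPC",
)


@dataclass
class PipelineConfig:
    """Thresholds and switches for every pipeline stage.

    Parameters
    ----------
    pooled_depth_cutoff
        Minimum pooled read depth required for *each* allele to call a site
        heterozygous from pooled single-cell reads.
    ma_fdr
        BH-adjusted p-value threshold below which a site-in-cell may be
        called monoallelic.
    ma_ratio
        Majority-allele read fraction that must be *strictly exceeded* for a
        monoallelic call (ties at the threshold are not monoallelic).
    ba_min_allele_reads
        Reads required on each allele to confirm biallelic expression.
    min_supporting_cells
        Minimum number of supporting cells for a cell-type monoallelic gene.
    expr_percentile
        Fraction of expressed genes retained by the per-cell expression-rank
        filter (0.30 keeps the top 30%).
    disruption_min_each, disruption_min_sum
        Per-allele and total read-depth filters for the reference-read
        fraction analysis of disrupted alleles.
    background_mean_fpkm
        Mean-FPKM floor defining "expressed genes" used as the enrichment
        background in between-cell-type comparisons.
    n_permutations
        Draws used by permutation/subsampling analyses.
    bh_family
        "pooled": BH-adjust all (site, cell) tests of one individual jointly
        (default); "per_cell": adjust within each cell separately.
    binom_alternative
        "two-sided" (default) or "greater" (one-sided toward the majority
        allele).
    overlap_denominator
        Denominator of overlap percentages between monoallelic gene sets:
        "union" (Jaccard, default), "min", or "intersection-free" choices
        "either" (same as union) are accepted for clarity.
    """

    pooled_depth_cutoff: int = 20
    ma_fdr: float = 0.05
    ma_ratio: float = 0.95
    ba_min_allele_reads: int = 2
    min_supporting_cells: int = 4
    expr_percentile: float = 0.30
    disruption_min_each: int = 2
    disruption_min_sum: int = 10
    background_mean_fpkm: float = 1.0
    n_permutations: int = 1000
    rng_seed: int = 0
    bh_family: str = "pooled"
    binom_alternative: str = "two-sided"
    overlap_denominator: str = "union"
    cell_types: Sequence[str] = field(default_factory=lambda: list(DEFAULT_CELL_TYPES))

    def __post_init__(self) -> None:
        if not (0.0 < self.ma_ratio < 1.0):
            raise ValueError("ma_ratio must lie strictly between 0 and 1")
        if not (0.0 < self.expr_percentile <= 1.0):
            raise ValueError("expr_percentile must lie in (0, 1]")
        for name in (
            "pooled_depth_cutoff",
            "ba_min_allele_reads",
            "min_supporting_cells",
            "disruption_min_each",
            "disruption_min_sum",
            "n_permutations",
        ):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.bh_family not in ("pooled", "per_cell"):
            raise ValueError("bh_family must be 'pooled' or 'per_cell'")
        if self.binom_alternative not in ("two-sided", "greater"):
            raise ValueError("binom_alternative must be 'two-sided' or 'greater'")
        if self.overlap_denominator not in ("union", "min", "either"):
            raise ValueError("overlap_denominator must be 'union', 'min' or 'either'")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str) -> None:
        data = asdict(self)
        data["cell_types"] = list(self.cell_types)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
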