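"""Core domain containers.

Tabular objects are thin wrappers over pandas DataFrames with fixed schemas,
so that readers, writers and every analysis stage agree on column names.
Counts are sparse: a (site, cell) pair absent from the table means zero
coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

VALID_BASES = frozenset("ACGT")

COUNT_COLUMNS = ["site_id", "cell_id", "ref_depth", "alt_depth", "other_depth"]
METADATA_COLUMNS = ["cell_id", "individual", "cell_type"]


@dataclass(frozen=True)
class SnpSite:
    """A candidate SNV site with its gene assignment.

    Positions are 1-based. ``gene_ids`` holds *all* overlapping genes; sites
    mapping to more than one gene are excluded downstream, not here.
    """

    site_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene_ids: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"{self.site_id}: pos must be >= 1 (1-based)")
        if self.ref_allele not in VALID_BASES or self.alt_allele not in VALID_BASES:
            raise ValueError(f"{self.site_id}: alleles must be one of A/C/G/T")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.site_id}: ref and alt alleles are identical")
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))


def sites_to_frame(sites: Iterable[SnpSite]) -> pd.DataFrame:
    rows = [
        (s.site_id, s.chrom, s.pos, s.ref_allele, s.alt_allele, ",".join(s.gene_ids))
        for s in sites
    ]
    return pd.DataFrame(
        rows, columns=["site_id", "chrom", "pos", "ref_allele", "alt_allele", "gene_ids"]
    )


def validate_sites(sites: Iterable[SnpSite]) -> None:
    seen: set[str] = set()
    for s in sites:
        if s.site_id in seen:
            raise ValueError(f"duplicate site_id {s.site_id!r} in site list")
        seen.add(s.site_id)


def single_gene_map(sites: Iterable[SnpSite]) -> pd.Series:
    """site_id -> gene_id for sites mapped to exactly one gene.

    Multi-gene and intergenic sites are dropped here, implementing the rule
    that a SNP mapped to more than one gene is excluded from gene-level
    analysis.
    """
    data = {s.site_id: s.gene_ids[0] for s in sites if len(s.gene_ids) == 1}
    return pd.Series(data, name="gene_id", dtype=object)


class AllelicCountTable:
    """Sparse per-(site, cell) allelic read depths.

    ``other_depth`` (reads matching neither candidate allele) is carried
    through for diagnostics and the reference-absence exclusion, but never
    enters the binomial statistics.
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in COUNT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"count table missing columns {missing}")
        df = df.loc[:, COUNT_COLUMNS].copy()
        for col in ("ref_depth", "alt_depth", "other_depth"):
            if (df[col] < 0).any():
                raise ValueError(f"negative values in {col}")
            df[col] = df[col].astype(int)
        if df.duplicated(["site_id", "cell_id"]).any():
            dup = df[df.duplicated(["site_id", "cell_id"])].iloc[0]
            raise ValueError(
                f"duplicate count row for site {dup.site_id!r}, cell {dup.cell_id!r}"
            )
        self.df = df.reset_index(drop=True)

    def get(self, site_id: str, cell_id: str) -> tuple[int, int, int]:
        """Depths for one (site, cell); absent pairs are zero coverage."""
        m = self.df[(self.df.site_id == site_id) & (self.df.cell_id == cell_id)]
        if m.empty:
            return (0, 0, 0)
        r = m.iloc[0]
        return (int(r.ref_depth), int(r.alt_depth), int(r.other_depth))

    def restrict_cells(self, cell_ids: Iterable[str]) -> "AllelicCountTable":
        keep = self.df.cell_id.isin(set(cell_ids))
        return AllelicCountTable(self.df[keep])

    def restrict_sites(self, site_ids: Iterable[str]) -> "AllelicCountTable":
        keep = self.df.site_id.isin(set(site_ids))
        return AllelicCountTable(self.df[keep])

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AllelicCountTable):
            return NotImplemented
        a = self.df.sort_values(["site_id", "cell_id"]).reset_index(drop=True)
        b = other.df.sort_values(["site_id", "cell_id"]).reset_index(drop=True)
        return a.equals(b)


class CellMetadata:
    """Cell -> (individual, cell type) assignment."""

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"cell metadata missing columns {missing}")
        df = df.loc[:, METADATA_COLUMNS].copy()
        if df.cell_id.duplicated().any():
            raise ValueError("duplicate cell_id in metadata")
        self.df = df.reset_index(drop=True)

    @property
    def cell_ids(self) -> list[str]:
        return list(self.df.cell_id)

    def cells_of(self, individual: str | None = None, cell_type: str | None = None) -> list[str]:
        m = self.df
        if individual is not None:
            m = m[m.individual == individual]
        if cell_type is not None:
            m = m[m.cell_type == cell_type]
        return list(m.cell_id)

    @property
    def individuals(self) -> list[str]:
        return sorted(self.df.individual.unique())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CellMetadata):
            return NotImplemented
        a = self.df.sort_values("cell_id").reset_index(drop=True)
        b = other.df.sort_values("cell_id").reset_index(drop=True)
        return a.equals(b)


class ExpressionMatrix:
    """Gene x cell FPKM matrix (dense frame, genes as rows)."""

    def __init__(self, df: pd.DataFrame):
        if (df.values < 0).any():
            raise ValueError("FPKM values must be non-negative")
        self.df = df.astype(float)
        self.df.index.name = "gene_id"

    def fpkm(self, gene_id: str, cell_id: str) -> float:
        if gene_id not in self.df.index or cell_id not in self.df.columns:
            return 0.0
        return float(self.df.at[gene_id, cell_id])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        a = self.df.sort_index(axis=0).sort_index(axis=1)
        b = other.df.sort_index(axis=0).sort_index(axis=1)
        return a.shape == b.shape and bool(((a - b).abs() < 1e-9).all().all())


class AnnotationTable:
    """Functional annotation of candidate SNVs (wANNOVAR-style classes).

    snv_class: S (synonymous), N (non-synonymous), L (stoploss), G (stopgain).
    SIFT: S/T/D; PolyPhen (HDIV and HVAR): S/B/P/D. Synonymous sites carry
    class S consistently across all schemes.
    """

    SCHEMES = {
        "SNV": "snv_class",
        "SIFT": "sift_class",
        "PPH_HDIV": "pph_hdiv_class",
        "PPH_HVAR": "pph_hvar_class",
    }

    def __init__(self, df: pd.DataFrame):
        required = ["site_id", "snv_class"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"annotation table missing columns {missing}")
        df = df.copy()
        for col in ("sift_class", "pph_hdiv_class", "pph_hvar_class"):
            if col not in df.columns:
                df[col] = pd.NA
        if df.snv_class.isna().any():
            raise ValueError("snv_class must be present for every annotated site")
        syn = df.snv_class == "S"
        for col in ("sift_class", "pph_hdiv_class", "pph_hvar_class"):
            bad = syn & df[col].notna() & (df[col] != "S")
            if bad.any():
                raise ValueError("synonymous sites must carry class S in every scheme")
        self.df = df.reset_index(drop=True)

    def classes(self, scheme: str) -> pd.Series:
        """site_id -> class label for one scheme (NaN entries dropped)."""
        if scheme not in self.SCHEMES:
            raise ValueError(f"unknown scheme {scheme!r}; choose from {sorted(self.SCHEMES)}")
        col = self.SCHEMES[scheme]
        s = self.df.set_index("site_id")[col].dropna()
        return s

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        a = self.df.sort_values("site_id").reset_index(drop=True)
        b = other.df.sort_values("site_id").reset_index(drop=True)
        return a.equals(b)
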