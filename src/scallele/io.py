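"""Readers and writers for the external formats.

Formats
-------
* candidate sites: VCF-like text (CHROM POS ID REF ALT ...), 1-based
* gene model: BED (0-based half-open, name column = gene_id) or GTF-lite
  (1-based closed, ``gene_id "X"`` attribute); converted to 1-based closed
  intervals on read
* allelic counts: TSV with columns site_id, cell_id, ref_depth, alt_depth,
  other_depth (sparse; absent pair = zero coverage)
* cell metadata, annotation: TSV
* expression: TSV, genes as rows, cells as columns, FPKM

Every writer/reader pair round-trips its in-memory object exactly.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .types import (
    AllelicCountTable,
    AnnotationTable,
    CellMetadata,
    ExpressionMatrix,
    SnpSite,
    validate_sites,
)

log = logging.getLogger(__name__)


class ParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# gene model

def read_gene_model(path: str) -> dict[str, IntervalTree]:
    """Read gene intervals into per-chromosome interval trees.

    Returns trees keyed by chromosome holding 1-based *closed* gene intervals
    (stored internally as half-open [start, end+1) for the tree). BED input
    (0-based half-open) is converted on read; GTF-lite input is taken as
    1-based closed.
    """
    trees: dict[str, IntervalTree] = {}
    is_gtf = path.endswith((".gtf", ".gff", ".gff3"))
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if is_gtf:
                    chrom, start, end = fields[0], int(fields[3]), int(fields[4])
                    attrs = fields[8]
                    gene_id = None
                    for part in attrs.split(";"):
                        part = part.strip()
                        if part.startswith("gene_id"):
                            gene_id = part.split(None, 1)[1].strip('" ')
                    if gene_id is None:
                        raise ValueError("missing gene_id attribute")
                else:
                    chrom, gene_id = fields[0], fields[3]
                    start, end = int(fields[1]) + 1, int(fields[2])  # BED -> 1-based closed
            except (IndexError, ValueError) as exc:
                raise ParseError(f"{path}:{lineno}: malformed gene model line ({exc})")
            if end < start:
                raise ParseError(f"{path}:{lineno}: empty interval for {gene_id}")
            trees.setdefault(chrom, IntervalTree()).addi(start, end + 1, gene_id)
    return trees


def write_gene_model_bed(genes: pd.DataFrame, path: str) -> None:
    """Write a gene model BED from a frame with gene_id, chrom, start, end
    (1-based closed coordinates)."""
    with open(path, "w") as fh:
        for r in genes.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.gene_id}\n")


# ---------------------------------------------------------------------------
# candidate sites (VCF-like)

def read_snp_sites(path: str, gene_model: str | None = None) -> list[SnpSite]:
    """Read candidate SNV sites from a VCF-like file.

    With ``gene_model`` given, each site is annotated with *all* genes whose
    interval covers its position (exclusion of multi-gene sites happens
    downstream). Without one, gene assignments are taken from a
    ``GENES=a|b`` INFO entry if present.
    """
    trees = read_gene_model(gene_model) if gene_model else None
    sites: list[SnpSite] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ParseError(f"{path}:{lineno}: expected >=5 VCF columns")
            chrom, pos_s, site_id, ref, alt = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-integer POS {pos_s!r}")
            gene_ids: tuple[str, ...] = ()
            if trees is not None:
                tree = trees.get(chrom)
                if tree is not None:
                    gene_ids = tuple(sorted(iv.data for iv in tree.at(pos)))
            elif len(fields) >= 8:
                for entry in fields[7].split(";"):
                    if entry.startswith("GENES="):
                        value = entry[len("GENES="):]
                        gene_ids = tuple(value.split("|")) if value else ()
            try:
                sites.append(SnpSite(site_id, chrom, pos, ref, alt, gene_ids))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}")
    validate_sites(sites)
    log.info("read %d candidate sites from %s", len(sites), path)
    return sites


def write_snp_sites(sites: Sequence[SnpSite], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=GENES,Number=1,Type=String,Description="Overlapping genes">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sites:
            info = "GENES=" + "|".join(s.gene_ids) if s.gene_ids else "."
            fh.write(f"{s.chrom}\t{s.pos}\t{s.site_id}\t{s.ref_allele}\t{s.alt_allele}\t.\t.\t{info}\n")


# ---------------------------------------------------------------------------
# allelic counts

def read_allelic_counts(path: str, sites: Sequence[SnpSite] | None = None) -> AllelicCountTable:
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str, "cell_id": str})
    expected = {"site_id", "cell_id", "ref_depth", "alt_depth", "other_depth"}
    if not expected.issubset(df.columns):
        raise ParseError(f"{path}: count table must have columns {sorted(expected)}")
    if sites is not None:
        known = {s.site_id for s in sites}
        unknown = set(df.site_id) - known
        if unknown:
            raise ParseError(
                f"{path}: rows reference {len(unknown)} site_id(s) absent from the "
                f"site list, e.g. {sorted(unknown)[:3]}"
            )
    table = AllelicCountTable(df)
    log.info("read %d count rows from %s", len(table), path)
    return table


def write_allelic_counts(table: AllelicCountTable, path: str) -> None:
    df = table.df.sort_values(["site_id", "cell_id"])
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cell metadata / expression / annotation

def read_cell_metadata(path: str) -> CellMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return CellMetadata(df)


def write_cell_metadata(meta: CellMetadata, path: str) -> None:
    meta.df.sort_values("cell_id").to_csv(path, sep="\t", index=False)


def read_expression(path: str) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path: str) -> None:
    df = expr.df.sort_index(axis=0).sort_index(axis=1)
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_annotation(path: str) -> AnnotationTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return AnnotationTable(df)


def write_annotation(annot: AnnotationTable, path: str) -> None:
    annot.df.sort_values("site_id").to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# generic result tables

def write_table(df: pd.DataFrame, path: str) -> None:
    """Deterministic TSV writer used for all result tables."""
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# truth tables (simulation ground truth)

def write_truth(truth, prefix: str) -> None:
    """Write the three truth tables as <prefix>.{genotypes,modes,active}.tsv."""
    truth.genotypes.sort_values("site_id").to_csv(
        f"{prefix}.genotypes.tsv", sep="\t", index=False
    )
    truth.gene_modes.sort_values("gene_id").to_csv(
        f"{prefix}.modes.tsv", sep="\t", index=False
    )
    truth.active_alleles.sort_values(["gene_id", "cell_id"]).to_csv(
        f"{prefix}.active.tsv", sep="\t", index=False
    )


def read_truth(prefix: str):
    from .simulate import TruthSet

    genotypes = pd.read_csv(f"{prefix}.genotypes.tsv", sep="\t", dtype=str)
    modes = pd.read_csv(
        f"{prefix}.modes.tsv", sep="\t", dtype=str, keep_default_na=False
    )
    active = pd.read_csv(f"{prefix}.active.tsv", sep="\t", dtype=str)
    return TruthSet(genotypes=genotypes, gene_modes=modes, active_alleles=active)
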