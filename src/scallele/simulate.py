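"""Synthetic allelic-count generator.

Generates everything the pipeline consumes — candidate SNV sites, a gene
model, sparse allelic read counts per cell, an FPKM expression matrix, cell
metadata, a functional-annotation table — together with the ground truth
(genotypes, per-gene allelic modes, per-cell active alleles) needed for
calibration and parameter-recovery tests.

Generative model
----------------
Each gene carries 1-3 truly heterozygous exonic sites plus a Poisson number
of homozygous candidate sites (the candidate list mimics a dbSNP-derived
list, most of whose entries are not heterozygous in a given individual).
Per (gene, cell), allele activity follows the gene's mode:

* ``biallelic`` — each allele transcribes independently with probability
  ``burst_prob_active_allele`` (a Bernoulli stand-in for bursting kinetics);
* ``random_MA`` — one allele is chosen uniformly per cell and transcribes
  with the burst probability (random monoallelic expression);
* ``imprinted_ref`` / ``imprinted_alt`` — the same parental allele in every
  cell.

A ``random_MA`` gene may be cell-type specific: outside its assigned cell
types it behaves biallelically.

Per (gene, cell, allele) a transcript-pool depth is drawn from a negative
binomial; all heterozygous sites of the gene read from that shared pool, so
with no technical noise two SNPs of one gene always agree. Technical layers,
applied per site: allelic dropout (an allele's reads at a site are lost with
``dropout_prob``), reference mapping bias (each alternative read is kept
with probability ``ref_bias``), and sequencing error at homozygous sites
(each read miscalls with rate ``seq_error``, uniformly over the three
non-template bases, so only ~1/3 of errors match the site's recorded second
allele — the sole source of false heterozygous candidates). FPKM is transcript-depth-proportional
with a log-normal per-cell scaling factor, preserving within-cell ranks.

Alternative alleles flagged deleterious (stopgain, SIFT-D, PolyPhen-HDIV-D)
reduce the gene's alternative-allele transcript pool by
``deleterious_penalty``, emulating nonsense-mediated decay so disrupted-
allele comparisons have a recoverable signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .types import (
    AllelicCountTable,
    AnnotationTable,
    CellMetadata,
    ExpressionMatrix,
    SnpSite,
)

BASES = np.array(list("ACGT"))


@dataclass
class SimParams:
    """Knobs of the generator; defaults document the emulated conditions.

    ``n_cells_per_type`` applies per individual. ``frac_het_sites`` is the
    expected fraction of candidate sites that are truly heterozygous;
    ``hetsnps_per_gene`` gives the distribution of truly heterozygous sites
    per gene (default close to the 80/14/6 split of 1/2/>2 hetSNPs per gene
    seen in human brain cells). Depths are negative binomial with mean
    ``depth_mean * gene_scale`` and dispersion ``depth_dispersion`` (gamma
    shape; smaller = noisier). ``ref_bias`` < 1 removes alternative reads,
    emulating residual reference mapping bias.
    """

    n_individuals: int = 2
    n_cells_per_type: Mapping[str, int] = field(
        default_factory=lambda: {
            "astrocyte": 12,
            "microglia": 12,
            "neuron": 12,
            "oligodendrocyte": 12,
            "OPC": 12,
        }
    )
    n_genes: int = 300
    hetsnps_per_gene: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.80, 2: 0.14, 3: 0.06}
    )
    frac_het_sites: float = 0.5
    gene_mode_probs: Mapping[str, float] = field(
        default_factory=lambda: {"random_MA": 0.55, "biallelic": 0.35, "imprinted": 0.10}
    )
    burst_prob_active_allele: float = 0.9
    depth_mean: float = 30.0
    depth_dispersion: float = 2.0
    dropout_prob: float = 0.1
    seq_error: float = 0.002
    ref_bias: float = 1.0
    celltype_specific_ma_frac: float = 0.0
    deleterious_frac: float = 0.18
    deleterious_penalty: float = 4.0
    gene_scale_sigma: float = 1.5
    cell_scale_sigma: float = 0.3
    snv_class_probs: Mapping[str, float] = field(
        default_factory=lambda: {"S": 0.555, "N": 0.433, "L": 0.006, "G": 0.006}
    )
    other_error: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name, probs in (
            ("gene_mode_probs", self.gene_mode_probs),
            ("hetsnps_per_gene", self.hetsnps_per_gene),
            ("snv_class_probs", self.snv_class_probs),
        ):
            vals = np.asarray(list(probs.values()), dtype=float)
            if np.any(vals < 0) or np.any(vals > 1):
                raise ValueError(f"{name} entries must be probabilities in [0, 1]")
            if not np.isclose(vals.sum(), 1.0, atol=1e-9):
                raise ValueError(f"{name} must sum to 1 (got {vals.sum()})")
        for name in ("burst_prob_active_allele", "dropout_prob", "seq_error",
                     "celltype_specific_ma_frac", "deleterious_frac", "other_error"):
            v = float(getattr(self, name))
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not (0.0 < self.ref_bias <= 1.0):
            raise ValueError("ref_bias must lie in (0, 1]")
        if not (0.0 < self.frac_het_sites <= 1.0):
            raise ValueError("frac_het_sites must lie in (0, 1]")
        if self.depth_mean <= 0 or self.depth_dispersion <= 0:
            raise ValueError("depth model parameters must be positive")


@dataclass
class TruthSet:
    """Ground truth behind one simulated dataset.

    genotypes: site_id, gene_id, genotype in {hom_ref, het, hom_alt}
    gene_modes: gene_id, mode in {random_MA, biallelic, imprinted_ref,
        imprinted_alt}, ma_cell_types ("*" = all cell types, "" = n/a,
        otherwise comma-joined types in which the MA mode applies)
    active_alleles: gene_id, cell_id, active in {ref, alt, both, none}
    """

    genotypes: pd.DataFrame
    gene_modes: pd.DataFrame
    active_alleles: pd.DataFrame

    @property
    def het_sites(self) -> set[str]:
        g = self.genotypes
        return set(g.loc[g.genotype == "het", "site_id"])


GENE_SPAN = 1500
GENE_PITCH = 2000


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with given mean and gamma-shape dispersion."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if np.any(pos):
        p = dispersion / (dispersion + mean[pos])
        out[pos] = rng.negative_binomial(dispersion, p)
    return out


def simulate_dataset(
    params: SimParams,
) -> tuple[list[SnpSite], AllelicCountTable, ExpressionMatrix, CellMetadata, AnnotationTable, TruthSet]:
    """Generate one cohort; bit-reproducible for a fixed ``rng_seed``."""
    rng = np.random.default_rng(params.rng_seed)

    # --- genes and candidate sites -------------------------------------
    n_genes = params.n_genes
    gene_ids = np.array([f"g{i:04d}" for i in range(1, n_genes + 1)])
    gene_start = np.arange(n_genes, dtype=np.int64) * GENE_PITCH + 1
    het_counts_support = np.array(sorted(params.hetsnps_per_gene), dtype=int)
    het_counts_probs = np.array(
        [params.hetsnps_per_gene[k] for k in het_counts_support], dtype=float
    )
    n_het = rng.choice(het_counts_support, size=n_genes, p=het_counts_probs)
    mean_het = float((het_counts_support * het_counts_probs).sum())
    lam_hom = mean_het * (1.0 - params.frac_het_sites) / params.frac_het_sites
    n_hom = rng.poisson(lam_hom, size=n_genes)

    site_gene_idx: list[int] = []
    site_is_het: list[bool] = []
    for gi in range(n_genes):
        site_gene_idx.extend([gi] * (n_het[gi] + n_hom[gi]))
        site_is_het.extend([True] * n_het[gi] + [False] * n_hom[gi])
    site_gene_idx = np.array(site_gene_idx, dtype=np.int64)
    site_is_het = np.array(site_is_het, dtype=bool)
    n_sites = len(site_gene_idx)

    # unique positions inside each gene
    offset = np.zeros(n_sites, dtype=np.int64)
    for gi in range(n_genes):
        mask = site_gene_idx == gi
        k = int(mask.sum())
        if k:
            offset[mask] = rng.choice(GENE_SPAN, size=k, replace=False)
    pos = gene_start[site_gene_idx] + offset
    site_ids = np.array([f"s{i:06d}" for i in range(1, n_sites + 1)])
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    ref_allele = BASES[ref_idx]
    alt_allele = BASES[alt_idx]

    genotype = np.where(
        site_is_het, "het", np.where(rng.random(n_sites) < 0.5, "hom_ref", "hom_alt")
    )

    # --- annotation and deleterious flags ------------------------------
    # One SNV consequence class per gene's alternative haplotype: every site
    # of a gene inherits it. The NMD-style penalty then degrades whole
    # transcripts while synonymous sites never share a gene with a
    # penalised allele, keeping class S a clean negative control.
    snv_support = np.array(sorted(params.snv_class_probs))
    snv_probs = np.array([params.snv_class_probs[k] for k in snv_support], dtype=float)
    gene_snv = rng.choice(snv_support, size=n_genes, p=snv_probs)
    gene_sift = np.full(n_genes, None, dtype=object)
    gene_pph_hdiv = np.full(n_genes, None, dtype=object)
    gene_pph_hvar = np.full(n_genes, None, dtype=object)
    g_syn = gene_snv == "S"
    gene_sift[g_syn] = "S"
    gene_pph_hdiv[g_syn] = "S"
    gene_pph_hvar[g_syn] = "S"
    g_ns = gene_snv == "N"
    n_ns = int(g_ns.sum())
    if n_ns:
        gene_sift[g_ns] = np.where(rng.random(n_ns) < params.deleterious_frac, "D", "T")
        gene_pph_hdiv[g_ns] = rng.choice(["B", "P", "D"], size=n_ns, p=[0.76, 0.10, 0.14])
        # HVAR mostly agrees with HDIV, as the two PolyPhen models do in practice
        agree = rng.random(n_ns) < 0.8
        gene_pph_hvar[g_ns] = np.where(
            agree,
            gene_pph_hdiv[g_ns],
            rng.choice(["B", "P", "D"], size=n_ns, p=[0.77, 0.11, 0.12]),
        )
    gene_deleterious = (
        (gene_snv == "G") | (gene_sift == "D") | (gene_pph_hdiv == "D")
    )
    snv_class = gene_snv[site_gene_idx]
    sift = gene_sift[site_gene_idx]
    pph_hdiv = gene_pph_hdiv[site_gene_idx]
    pph_hvar = gene_pph_hvar[site_gene_idx]

    # --- gene modes -----------------------------------------------------
    mode_support = np.array(sorted(params.gene_mode_probs))
    mode_probs = np.array([params.gene_mode_probs[k] for k in mode_support], dtype=float)
    raw_mode = rng.choice(mode_support, size=n_genes, p=mode_probs)
    mode = raw_mode.astype(object)
    imp = raw_mode == "imprinted"
    if np.any(imp):
        mode[imp] = np.where(rng.random(int(imp.sum())) < 0.5, "imprinted_ref", "imprinted_alt")

    cell_types = sorted(params.n_cells_per_type)
    ma_cell_types = np.full(n_genes, "", dtype=object)
    is_random = mode == "random_MA"
    ma_cell_types[is_random | np.char.startswith(mode.astype(str), "imprinted")] = "*"
    specific = is_random & (rng.random(n_genes) < params.celltype_specific_ma_frac)
    if np.any(specific):
        chosen = rng.choice(cell_types, size=int(specific.sum()))
        ma_cell_types[specific] = chosen

    # --- cells ----------------------------------------------------------
    meta_rows = []
    for ind_i in range(1, params.n_individuals + 1):
        ind = f"ind{ind_i}"
        for ct in cell_types:
            for j in range(1, params.n_cells_per_type[ct] + 1):
                meta_rows.append((f"{ind}_{ct}_c{j:03d}", ind, ct))
    meta = pd.DataFrame(meta_rows, columns=["cell_id", "individual", "cell_type"])
    cell_ids = meta.cell_id.to_numpy()
    cell_type_arr = meta.cell_type.to_numpy()
    n_cells = len(cell_ids)

    # --- allele activity per (gene, cell) -------------------------------
    burst = params.burst_prob_active_allele
    ma_applies = np.zeros((n_genes, n_cells), dtype=bool)
    for gi in np.flatnonzero(is_random):
        tag = ma_cell_types[gi]
        ma_applies[gi] = True if tag == "*" else (cell_type_arr == tag)

    ref_active = np.zeros((n_genes, n_cells), dtype=bool)
    alt_active = np.zeros((n_genes, n_cells), dtype=bool)
    u_ref = rng.random((n_genes, n_cells))
    u_alt = rng.random((n_genes, n_cells))
    pick_ref = rng.random((n_genes, n_cells)) < 0.5

    ba_like = np.zeros((n_genes, n_cells), dtype=bool)
    ba_like[mode == "biallelic"] = True
    ba_like[is_random] |= ~ma_applies[is_random]
    rm_here = np.zeros((n_genes, n_cells), dtype=bool)
    rm_here[is_random] = ma_applies[is_random]

    ref_active |= ba_like & (u_ref < burst)
    alt_active |= ba_like & (u_alt < burst)
    ref_active |= rm_here & pick_ref & (u_ref < burst)
    alt_active |= rm_here & ~pick_ref & (u_alt < burst)
    ref_active[mode == "imprinted_ref"] = u_ref[mode == "imprinted_ref"] < burst
    alt_active[mode == "imprinted_alt"] = u_alt[mode == "imprinted_alt"] < burst

    # --- transcript pools ----------------------------------------------
    gene_scale = rng.lognormal(0.0, params.gene_scale_sigma, size=n_genes)
    mu_ref = params.depth_mean * gene_scale
    mu_alt = mu_ref / np.where(gene_deleterious, params.deleterious_penalty, 1.0)
    t_ref = _nb_draw(rng, np.where(ref_active, mu_ref[:, None], 0.0), params.depth_dispersion)
    t_alt = _nb_draw(rng, np.where(alt_active, mu_alt[:, None], 0.0), params.depth_dispersion)
    t_ref[~ref_active] = 0
    t_alt[~alt_active] = 0

    # --- per-site read depths -------------------------------------------
    s_ref = t_ref[site_gene_idx]  # (n_sites, n_cells) shared transcript pools
    s_alt = t_alt[site_gene_idx]

    het = site_is_het[:, None]
    hom_ref_site = (genotype == "hom_ref")[:, None]
    hom_alt_site = (genotype == "hom_alt")[:, None]
    total = s_ref + s_alt

    ref_reads = np.where(het, s_ref, 0)
    alt_reads = np.where(het, s_alt, 0)
    # homozygous sites: every transcript carries the homozygous base; a read
    # miscalls with rate seq_error, landing on each of the three non-template
    # bases uniformly, so only ~1/3 of errors match the recorded second
    # allele and the rest surface as "other" reads.
    err = rng.binomial(total, params.seq_error)
    err_match = rng.binomial(err, 1.0 / 3.0)
    err_other = err - err_match
    ref_reads = np.where(hom_ref_site, total - err, ref_reads)
    alt_reads = np.where(hom_ref_site, err_match, alt_reads)
    ref_reads = np.where(hom_alt_site, err_match, ref_reads)
    alt_reads = np.where(hom_alt_site, total - err, alt_reads)
    hom_any = hom_ref_site | hom_alt_site
    err_other = np.where(hom_any, err_other, 0)

    # site-level allelic dropout
    if params.dropout_prob > 0:
        ref_reads = np.where(rng.random(ref_reads.shape) < params.dropout_prob, 0, ref_reads)
        alt_reads = np.where(rng.random(alt_reads.shape) < params.dropout_prob, 0, alt_reads)
    # reference mapping bias removes alternative reads
    if params.ref_bias < 1.0:
        alt_reads = rng.binomial(alt_reads, params.ref_bias)
    other_reads = err_other
    if params.other_error > 0:
        other_reads = other_reads + rng.binomial(ref_reads + alt_reads, params.other_error)

    covered = (ref_reads + alt_reads + other_reads) >= 1
    si, ci = np.nonzero(covered)
    counts = AllelicCountTable(
        pd.DataFrame(
            {
                "site_id": site_ids[si],
                "cell_id": cell_ids[ci],
                "ref_depth": ref_reads[si, ci],
                "alt_depth": alt_reads[si, ci],
                "other_depth": other_reads[si, ci],
            }
        )
    )

    # --- expression matrix ----------------------------------------------
    cell_factor = rng.lognormal(0.0, params.cell_scale_sigma, size=n_cells)
    fpkm = (t_ref + t_alt) * cell_factor[None, :]
    expr = ExpressionMatrix(pd.DataFrame(fpkm, index=list(gene_ids), columns=list(cell_ids)))

    # --- assembled outputs ----------------------------------------------
    sites = [
        SnpSite(
            site_ids[i],
            "chr1",
            int(pos[i]),
            str(ref_allele[i]),
            str(alt_allele[i]),
            (str(gene_ids[site_gene_idx[i]]),),
        )
        for i in range(n_sites)
    ]
    annot = AnnotationTable(
        pd.DataFrame(
            {
                "site_id": site_ids,
                "snv_class": snv_class,
                "sift_class": sift,
                "pph_hdiv_class": pph_hdiv,
                "pph_hvar_class": pph_hvar,
            }
        )
    )
    active_label = np.full((n_genes, n_cells), "none", dtype=object)
    active_label[ref_active & ~alt_active] = "ref"
    active_label[~ref_active & alt_active] = "alt"
    active_label[ref_active & alt_active] = "both"
    gi_grid, ci_grid = np.meshgrid(np.arange(n_genes), np.arange(n_cells), indexing="ij")
    truth = TruthSet(
        genotypes=pd.DataFrame(
            {"site_id": site_ids, "gene_id": gene_ids[site_gene_idx], "genotype": genotype}
        ),
        gene_modes=pd.DataFrame(
            {"gene_id": gene_ids, "mode": mode, "ma_cell_types": ma_cell_types}
        ),
        active_alleles=pd.DataFrame(
            {
                "gene_id": gene_ids[gi_grid.ravel()],
                "cell_id": cell_ids[ci_grid.ravel()],
                "active": active_label.ravel(),
            }
        ),
    )
    return sites, counts, expr, CellMetadata(meta), annot, truth


def gene_model_frame(sites: list[SnpSite], params: SimParams) -> pd.DataFrame:
    """Gene intervals (1-based closed) matching :func:`simulate_dataset`."""
    gene_ids = sorted({g for s in sites for g in s.gene_ids})
    rows = []
    for gid in gene_ids:
        gi = int(gid[1:]) - 1
        start = gi * GENE_PITCH + 1
        rows.append((gid, "chr1", start, start + GENE_SPAN - 1))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def truth_ma_labels(truth: TruthSet, level: str) -> pd.DataFrame:
    """Ground-truth monoallelic/biallelic labels.

    ``site_cell``: per heterozygous site and cell with at least one active
    allele — MA when exactly one allele is active, BA when both.
    ``gene_celltype``: per gene and cell type — MA when the gene's mode
    forces single-allele expression in every cell of that type (imprinted
    everywhere; random_MA where its MA mode applies), BA otherwise.
    """
    if level == "site_cell":
        het = truth.genotypes[truth.genotypes.genotype == "het"][["site_id", "gene_id"]]
        merged = het.merge(truth.active_alleles, on="gene_id")
        merged = merged[merged.active != "none"]
        merged["label"] = np.where(merged.active == "both", "BA", "MA")
        return merged[["site_id", "cell_id", "label"]].reset_index(drop=True)
    if level == "gene_celltype":
        modes = truth.gene_modes
        cell_types = sorted(
            {ct for ct in modes.ma_cell_types if ct not in ("", "*")}
        ) or None
        # derive the full type list from the active-allele cell ids if needed
        all_types = sorted({c.split("_")[1] for c in truth.active_alleles.cell_id.unique()})
        rows = []
        for r in modes.itertuples(index=False):
            for ct in all_types:
                if r.mode.startswith("imprinted"):
                    label = "MA"
                elif r.mode == "random_MA" and (r.ma_cell_types == "*" or ct in r.ma_cell_types.split(",")):
                    label = "MA"
                else:
                    label = "BA"
                rows.append((r.gene_id, ct, label))
        return pd.DataFrame(rows, columns=["gene_id", "cell_type", "label"])
    raise ValueError(f"unknown level {level!r}; use 'site_cell' or 'gene_celltype'")
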