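"""Are cell-type MA gene sets specific to their cell type?

On the main cohort: overlap of MA genes between neurons and
oligodendrocytes over the covered-gene background, with a Fisher test. On a
dedicated simulation in which every random-MA gene is tied to one cell
type: the within- vs between-type cell-resampling permutation comparison.
Writes results/specificity_permutation.tsv.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, DATA, RESULTS, require

from scallele import io
from scallele.celltype import (
    background_genes,
    between_vs_within_permutation,
    call_celltype_ma,
    ma_overlap_fisher,
    top_percentile_mask,
)
from scallele.classify import classify_cells
from scallele.genes import gene_status_per_cell
from scallele.hetsnp import call_hetsnps, pool_depths
from scallele.simulate import SimParams, simulate_dataset


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    gene_calls = io.read_table(str(require(RESULTS / "gene_calls.tsv",
                                           "04_gene_level_consistency.py")))
    ctma = io.read_table(str(require(RESULTS / "celltype_ma.tsv",
                                     "05_celltype_ma_genes.py")))
    meta = io.read_cell_metadata(str(DATA / "cohort.metadata.tsv"))

    ma = ctma[ctma.status == "MA"]
    ma_neu = set(ma[ma.cell_type == "neuron"].gene_id)
    ma_oli = set(ma[ma.cell_type == "oligodendrocyte"].gene_id)
    bg = background_genes(gene_calls, meta, "ind1", "neuron") & background_genes(
        gene_calls, meta, "ind1", "oligodendrocyte"
    )
    odds, fisher_p = ma_overlap_fisher(ma_neu, ma_oli, bg)
    union = len(ma_neu | ma_oli)
    shared = len(ma_neu & ma_oli)
    print(
        f"cohort: {len(bg)} shared background genes; {len(ma_neu)} neuron MA and "
        f"{len(ma_oli)} oligodendrocyte MA genes, {shared} shared "
        f"({100 * shared / union if union else 0:.1f}% of the union); "
        f"Fisher OR {odds:.2f}, p={fisher_p:.3g}."
    )

    # permutation comparison on a fully type-specific simulation
    p = SimParams(
        rng_seed=args.seed * 13 + 6,
        n_individuals=1,
        n_genes=150,
        n_cells_per_type={"neuron": 24, "oligodendrocyte": 12},
        celltype_specific_ma_frac=1.0,
    )
    sites, counts, expr, meta2, _, truth = simulate_dataset(p)
    pooled = pool_depths(counts, meta2, "ind1")
    hetsnps = call_hetsnps(pooled, sites, CONFIG.pooled_depth_cutoff)
    calls = classify_cells(counts, hetsnps, CONFIG)
    gc2 = gene_status_per_cell(calls, sites)
    mask2, _ = top_percentile_mask(expr, CONFIG.expr_percentile)
    res = between_vs_within_permutation(
        gc2, mask2, meta2, "ind1", "neuron", "oligodendrocyte", CONFIG,
        n_iter=CONFIG.n_permutations, seed=args.seed * 13 + 7,
    )
    io.write_table(
        pd.DataFrame(
            {
                "iteration": range(res["n_iter"]),
                "within_overlap": res["within_overlaps"],
                "between_overlap": res["between_overlaps"],
            }
        ),
        str(RESULTS / "specificity_permutation.tsv"),
    )
    print(
        f"type-specific simulation: mean within-type MA overlap "
        f"{res['within_mean']:.2f} genes vs between-type {res['between_mean']:.2f} "
        f"(k={res['k']} cells, t={res['t_statistic']:.1f}, p={res['p_value']:.3g})."
    )


if __name__ == "__main__":
    main()
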