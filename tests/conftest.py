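"""Shared fixtures: one small simulated cohort pushed through the pipeline."""

from __future__ import annotations

import pytest

from scallele.classify import classify_cells
from scallele.celltype import top_percentile_mask
from scallele.config import PipelineConfig
from scallele.genes import gene_status_per_cell
from scallele.hetsnp import call_hetsnps, pool_depths
from scallele.simulate import SimParams, simulate_dataset


@pytest.fixture(scope="session")
def config() -> PipelineConfig:
    return PipelineConfig()


@pytest.fixture(scope="session")
def cohort():
    """Default-parameter cohort, one individual, three cell types."""
    params = SimParams(
        rng_seed=11,
        n_individuals=1,
        n_genes=150,
        n_cells_per_type={"neuron": 12, "astrocyte": 12, "oligodendrocyte": 12},
    )
    sites, counts, expr, meta, annot, truth = simulate_dataset(params)
    return {
        "params": params,
        "sites": sites,
        "counts": counts,
        "expr": expr,
        "meta": meta,
        "annot": annot,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def pipeline(cohort, config):
    """Cohort plus every derived pipeline product."""
    pooled = pool_depths(cohort["counts"], cohort["meta"], "ind1")
    hetsnps = call_hetsnps(pooled, cohort["sites"], config.pooled_depth_cutoff)
    calls = classify_cells(cohort["counts"], hetsnps, config)
    gene_calls = gene_status_per_cell(calls, cohort["sites"])
    mask, cutoffs = top_percentile_mask(cohort["expr"], config.expr_percentile)
    return {
        **cohort,
        "pooled": pooled,
        "hetsnps": hetsnps,
        "calls": calls,
        "gene_calls": gene_calls,
        "mask": mask,
        "mask_cutoffs": cutoffs,
    }
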