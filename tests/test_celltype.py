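"""Cell-type MA calling, expression masking and permutation statistics."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scallele.celltype import (
    between_vs_within_permutation,
    call_celltype_ma,
    evaluate_recovery,
    ma_overlap_fisher,
    saturation_curve,
    shared_ma_alleles_pairs,
    split_half_overlap,
    top_percentile_mask,
)
from scallele.config import PipelineConfig
from scallele.classify import classify_cells
from scallele.genes import gene_status_per_cell
from scallele.hetsnp import call_hetsnps, pool_depths
from scallele.simulate import SimParams, simulate_dataset, truth_ma_labels
from scallele.types import CellMetadata, ExpressionMatrix


def expr_of(columns: dict[str, dict[str, float]]) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(columns).fillna(0.0))


def meta_of(cells, individual="i1", cell_type="t"):
    return CellMetadata(
        pd.DataFrame(
            [[c, individual, cell_type] for c in cells],
            columns=["cell_id", "individual", "cell_type"],
        )
    )


def gene_calls_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "cell_id", "status"])


class TestTopPercentileMask:
    def test_ceiling_of_expressed_genes(self):
        expr = expr_of({"c1": {f"g{i}": float(10 - i) for i in range(10)}})
        mask, cutoffs = top_percentile_mask(expr, 0.30)
        assert mask["c1"] == {"g0", "g1", "g2"}
        assert cutoffs["c1"] == 8.0

    def test_ties_broken_lexicographically(self):
        expr = expr_of({"c1": {"gB": 5.0, "gA": 5.0, "gC": 5.0, "gD": 5.0}})
        mask, _ = top_percentile_mask(expr, 0.5)
        assert mask["c1"] == {"gA", "gB"}

    def test_zero_fpkm_never_included(self):
        expr = expr_of({"c1": {"g1": 3.0, "g2": 0.0, "g3": 0.0}})
        mask, _ = top_percentile_mask(expr, 1.0)
        assert mask["c1"] == {"g1"}

    def test_cell_with_no_expression(self):
        expr = expr_of({"c1": {"g1": 0.0}})
        mask, cutoffs = top_percentile_mask(expr, 0.3)
        assert mask["c1"] == set()
        assert np.isnan(cutoffs["c1"])


def permissive_mask(gene_calls, extra_cells=()):
    cells = set(gene_calls.cell_id) | set(extra_cells)
    genes = set(gene_calls.gene_id)
    return {c: genes for c in cells}


class TestCellTypeCall:
    def test_four_supporting_cells_make_ma(self, config):
        gc = gene_calls_frame([["g1", f"c{i}", "MA"] for i in range(4)])
        res = call_celltype_ma(gc, permissive_mask(gc), meta_of([f"c{i}" for i in range(6)]), config)
        assert res.status.tolist() == ["MA"]
        assert res.n_supporting_cells.tolist() == [4]

    def test_single_ba_cell_vetoes(self, config):
        gc = gene_calls_frame(
            [["g1", f"c{i}", "MA"] for i in range(5)] + [["g1", "c5", "BA"]]
        )
        res = call_celltype_ma(gc, permissive_mask(gc), meta_of([f"c{i}" for i in range(6)]), config)
        assert res.status.tolist() == ["BA"]

    def test_ba_veto_ignores_expression_mask(self, config):
        """The vetoing cell's gene need not pass the top-percentile filter."""
        gc = gene_calls_frame(
            [["g1", f"c{i}", "MA"] for i in range(5)] + [["g1", "c5", "BA"]]
        )
        mask = {c: {"g1"} for c in [f"c{i}" for i in range(5)]}
        mask["c5"] = set()  # BA cell: gene below the percentile
        res = call_celltype_ma(gc, mask, meta_of([f"c{i}" for i in range(6)]), config)
        assert res.status.tolist() == ["BA"]

    def test_three_cells_undetermined(self, config):
        gc = gene_calls_frame([["g1", f"c{i}", "MA"] for i in range(3)])
        res = call_celltype_ma(gc, permissive_mask(gc), meta_of([f"c{i}" for i in range(6)]), config)
        assert res.status.tolist() == ["undetermined"]

    def test_unmasked_ma_cells_do_not_support(self, config):
        gc = gene_calls_frame([["g1", f"c{i}", "MA"] for i in range(4)])
        mask = {c: set() for c in gc.cell_id}
        res = call_celltype_ma(gc, mask, meta_of(list(gc.cell_id)), config)
        assert res.status.tolist() == ["undetermined"]

    def test_ma_and_ba_mutually_exclusive(self, pipeline, config):
        res = call_celltype_ma(
            pipeline["gene_calls"], pipeline["mask"], pipeline["meta"], config
        )
        per_group = res.groupby(["gene_id", "individual", "cell_type"]).status.nunique()
        assert (per_group == 1).all()

    def test_removing_supporting_cell_never_creates_ma(self, pipeline, config):
        """Monotonicity of the >=min-cells rule under cell removal."""
        from scallele.celltype import TypeMatrices

        cells = pipeline["meta"].cells_of(individual="ind1", cell_type="neuron")
        tm = TypeMatrices(pipeline["gene_calls"], pipeline["mask"], cells)
        rng = np.random.default_rng(0)
        full = np.arange(len(cells))
        ma_full = tm.ma_mask(full, config.min_supporting_cells)
        for _ in range(20):
            subset = rng.choice(full, size=len(cells) - 1, replace=False)
            ma_sub = tm.ma_mask(subset, config.min_supporting_cells)
            newly_ma = ma_sub & ~ma_full
            # a gene MA in the subset but not in the full set can only arise
            # from dropping a BA-vetoing cell, never from dropping support
            for gi in np.flatnonzero(newly_ma):
                dropped = set(full) - set(subset)
                assert any(tm.ba[gi, j] for j in dropped)


class TestPermutations:
    def test_split_half_extremes(self, config):
        # 8 cells, gene MA and masked in all -> identical MA sets in halves
        gc = gene_calls_frame([["g1", f"c{i}", "MA"] for i in range(8)])
        res = split_half_overlap(
            gc, permissive_mask(gc), meta_of([f"c{i}" for i in range(8)]),
            "i1", "t", config, n_iter=50, seed=1,
        )
        assert res["mean"] == pytest.approx(100.0)
        # disjoint sets: g1 in cells 0-3, g2 in cells 4-7 can still overlap
        # under permutation, so use two genes never meeting the 4-cell rule
        gc2 = gene_calls_frame(
            [["g1", f"c{i}", "MA"] for i in range(4)]
            + [["g2", f"c{i}", "MA"] for i in range(4, 8)]
        )
        res2 = split_half_overlap(
            gc2, permissive_mask(gc2), meta_of([f"c{i}" for i in range(8)]),
            "i1", "t", config, n_iter=50, seed=1,
        )
        assert res2["max"] <= 100.0

    def test_split_half_needs_enough_cells(self, config):
        gc = gene_calls_frame([["g1", f"c{i}", "MA"] for i in range(7)])
        with pytest.raises(ValueError, match="cells"):
            split_half_overlap(
                gc, permissive_mask(gc), meta_of([f"c{i}" for i in range(7)]),
                "i1", "t", config,
            )

    def test_saturation_zero_below_min_cells(self, pipeline, config):
        curve = saturation_curve(
            pipeline["gene_calls"], pipeline["mask"], pipeline["meta"],
            "ind1", "neuron", config, n_iter=50, seed=2,
        )
        below = curve[curve.n_cells < config.min_supporting_cells]
        assert (below.mean_ma_genes == 0).all()
        full = curve[curve.n_cells == curve.n_cells.max()]
        assert full.n_draws.tolist() == [1]

    def test_saturation_is_monotone_in_expectation(self, pipeline, config):
        curve = saturation_curve(
            pipeline["gene_calls"], pipeline["mask"], pipeline["meta"],
            "ind1", "neuron", config, n_iter=200, seed=3,
        )
        y = curve.mean_ma_genes.to_numpy()
        # allow small sampling wiggles, require the broad trend upward
        assert y[-1] >= y[4]
        assert (np.diff(y) > -1.0).all()

    def test_between_needs_enough_type_a_cells(self, pipeline, config):
        with pytest.raises(ValueError, match="needs >="):
            between_vs_within_permutation(
                pipeline["gene_calls"], pipeline["mask"], pipeline["meta"],
                "ind1", "neuron", "astrocyte", config, n_iter=10, seed=1,
            )

    def test_type_specific_ma_genes_separate_within_from_between(self):
        res = run_specificity_sim(seed=1, specific=True)
        assert res["within_mean"] > res["between_mean"]
        assert res["p_value"] < 0.01

    def test_shared_null_direction_is_symmetric(self):
        """With MA genes shared between types, the within-minus-between
        difference has no consistent sign across simulated cohorts."""
        signs = [
            np.sign(run_specificity_sim(seed=s, specific=False, n_iter=200)["t_statistic"])
            for s in range(12)
        ]
        pos = sum(1 for s in signs if s > 0)
        # sign test: 12 fair coin flips are not all one-sided
        assert 1 <= pos <= 11


def run_specificity_sim(seed: int, specific: bool, n_iter: int = 1000) -> dict:
    cfg = PipelineConfig()
    p = SimParams(
        rng_seed=seed,
        n_individuals=1,
        n_genes=150,
        n_cells_per_type={"neuron": 24, "oligodendrocyte": 12},
        celltype_specific_ma_frac=1.0 if specific else 0.0,
    )
    sites, counts, expr, meta, _, truth = simulate_dataset(p)
    pooled = pool_depths(counts, meta, "ind1")
    hetsnps = call_hetsnps(pooled, sites, cfg.pooled_depth_cutoff)
    calls = classify_cells(counts, hetsnps, cfg)
    gc = gene_status_per_cell(calls, sites)
    mask, _ = top_percentile_mask(expr, cfg.expr_percentile)
    return between_vs_within_permutation(
        gc, mask, meta, "ind1", "neuron", "oligodendrocyte", cfg,
        n_iter=n_iter, seed=seed + 1000,
    )


class TestSharedAlleles:
    def test_identical_and_opposite_cells(self):
        calls = pd.DataFrame(
            {
                "site_id": ["s1", "s2", "s1", "s2"],
                "cell_id": ["c1", "c1", "c2", "c2"],
                "status": ["MA"] * 4,
                "expressed_allele": ["ref", "alt", "ref", "alt"],
            }
        )
        meta = meta_of(["c1", "c2"])
        res = shared_ma_alleles_pairs(calls, meta, "i1", "t", n_pairs=10, seed=0)
        assert res["mean"] == pytest.approx(100.0)
        flipped = calls.copy()
        flipped.loc[flipped.cell_id == "c2", "expressed_allele"] = ["alt", "ref"]
        res2 = shared_ma_alleles_pairs(flipped, meta, "i1", "t", n_pairs=10, seed=0)
        assert res2["mean"] == pytest.approx(0.0)

    def test_imprinted_cells_share_nearly_all_alleles(self):
        cfg = PipelineConfig()
        p = SimParams(
            rng_seed=21, n_individuals=1, n_genes=100,
            n_cells_per_type={"neuron": 10},
            gene_mode_probs={"random_MA": 0.0, "biallelic": 0.0, "imprinted": 1.0},
            dropout_prob=0.0, seq_error=0.0, burst_prob_active_allele=1.0,
        )
        sites, counts, expr, meta, _, truth = simulate_dataset(p)
        # pooled imprinted data is single-allelic, so the genotype-free het
        # caller (rightly) finds nothing; classify at the truth het sites
        calls = classify_cells(counts, truth.het_sites, cfg)
        # among sites confidently MA in both cells the allele always agrees
        res = shared_ma_alleles_pairs(
            calls, meta, "ind1", "neuron", n_pairs=100, seed=1, denominator="both"
        )
        assert res["mean"] == pytest.approx(100.0)
        # union denominator is diluted only by low-coverage Unknown calls
        res_union = shared_ma_alleles_pairs(calls, meta, "ind1", "neuron", n_pairs=100, seed=1)
        assert res_union["mean"] > 60.0


class TestRecoveryAndFisher:
    def test_fisher_counts(self):
        odds, p = ma_overlap_fisher({"a", "b"}, {"b", "c"}, {"a", "b", "c", "d", "e"})
        assert 0.0 <= p <= 1.0

    def test_recovery_on_default_cohort(self, pipeline, config):
        ctma = call_celltype_ma(
            pipeline["gene_calls"], pipeline["mask"], pipeline["meta"], config
        )
        labels = truth_ma_labels(pipeline["truth"], "gene_celltype")
        res = evaluate_recovery(
            ctma, pipeline["gene_calls"], pipeline["mask"], pipeline["meta"],
            labels, config,
        )
        assert res["n_truth_ma_assessable"] > 20
        assert res["recall"] > 0.8
        assert res["false_ma_rate"] <= 0.05
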