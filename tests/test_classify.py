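"""MA/BA/Unknown classification rules and pseudo-bulk pooling."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scallele.classify import (
    band_fraction,
    classify_cells,
    imprinted_ratio_check,
    pseudo_bulk_ratios,
    ratio_band_histogram,
)
from scallele.config import PipelineConfig
from scallele.simulate import SimParams, simulate_dataset
from scallele.types import AllelicCountTable, CellMetadata


def one_cell_counts(rows):
    return AllelicCountTable(
        pd.DataFrame(
            [[f"s{i}", "c1", r, a, 0] for i, (r, a) in enumerate(rows)],
            columns=["site_id", "cell_id", "ref_depth", "alt_depth", "other_depth"],
        )
    )


def classify_single(ref, alt, config=None):
    """Classify one observation as its own BH family."""
    config = config or PipelineConfig()
    calls = classify_cells(one_cell_counts([(ref, alt)]), ["s0"], config)
    return calls.iloc[0]


class TestSingleObservationRules:
    def test_strong_monoallelic(self):
        row = classify_single(20, 0)
        assert row.status == "MA"
        assert row.expressed_allele == "ref"
        assert row.fdr == pytest.approx(2 * 0.5**20)

    def test_balanced_is_biallelic(self):
        row = classify_single(10, 10)
        assert row.status == "BA"
        assert row.p_value == pytest.approx(1.0)

    def test_single_read_is_unknown(self):
        row = classify_single(1, 0)
        assert row.status == "Unknown"

    def test_ma_takes_precedence_over_ba(self):
        # alt has >= 2 reads, but ratio > 0.95 and FDR < 0.05 -> MA wins
        row = classify_single(100, 4)
        assert row.ref_ratio > 0.95
        assert row.fdr < 0.05
        assert row.status == "MA"

    def test_ratio_tie_at_threshold_is_not_ma(self):
        # exactly 95% from one allele: the strict inequality fails
        row = classify_single(95, 5)
        assert row.status == "BA"

    def test_uncovered_sites_never_classified(self):
        calls = classify_cells(one_cell_counts([(0, 0)]), ["s0"], PipelineConfig())
        assert calls.empty


def test_every_covered_observation_gets_exactly_one_status(pipeline, config):
    calls = pipeline["calls"]
    counts = pipeline["counts"]
    covered = counts.df[
        counts.df.site_id.isin(set(pipeline["hetsnps"]))
        & ((counts.df.ref_depth + counts.df.alt_depth) >= 1)
    ]
    assert len(calls) == len(covered)
    assert set(calls.status.unique()) <= {"MA", "BA", "Unknown"}


def test_bh_family_switch_changes_only_fdr(pipeline):
    cfg_pooled = PipelineConfig(bh_family="pooled")
    cfg_cell = PipelineConfig(bh_family="per_cell")
    pooled = classify_cells(pipeline["counts"], pipeline["hetsnps"], cfg_pooled)
    per_cell = classify_cells(pipeline["counts"], pipeline["hetsnps"], cfg_cell)
    assert np.allclose(pooled.p_value, per_cell.p_value)
    assert not np.allclose(pooled.fdr, per_cell.fdr)


def test_false_ma_rate_bounded_on_clean_biallelic_data():
    """High-depth, dropout-free biallelic data: MA calls are test false
    positives, so their rate stays below the FDR level."""
    p = SimParams(
        rng_seed=2,
        n_individuals=1,
        n_genes=200,
        n_cells_per_type={"neuron": 15},
        gene_mode_probs={"random_MA": 0.0, "biallelic": 1.0, "imprinted": 0.0},
        burst_prob_active_allele=1.0,
        dropout_prob=0.0,
        seq_error=0.0,
        depth_mean=60.0,
        deleterious_frac=0.0,
        snv_class_probs={"S": 1.0, "N": 0.0, "L": 0.0, "G": 0.0},
    )
    sites, counts, _, meta, _, truth = simulate_dataset(p)
    cfg = PipelineConfig()
    calls = classify_cells(counts, truth.het_sites, cfg)
    assert (calls.status == "MA").mean() <= cfg.ma_fdr


class TestPseudoBulk:
    def test_opposite_ma_cells_pool_to_half(self):
        counts = AllelicCountTable(
            pd.DataFrame(
                [["s1", "c1", 12, 0, 0], ["s1", "c2", 0, 12, 0]],
                columns=["site_id", "cell_id", "ref_depth", "alt_depth", "other_depth"],
            )
        )
        meta = CellMetadata(
            pd.DataFrame(
                [["c1", "i1", "t"], ["c2", "i1", "t"]],
                columns=["cell_id", "individual", "cell_type"],
            )
        )
        pb = pseudo_bulk_ratios(counts, meta, "individual")
        assert pb.ref_ratio.tolist() == [0.5]
        assert pb.pooled_depth.tolist() == [24]

    def test_imprinted_simulation_pools_to_extremes(self):
        p = SimParams(
            rng_seed=5, n_individuals=1, n_genes=60,
            n_cells_per_type={"neuron": 20},
            gene_mode_probs={"random_MA": 0.0, "biallelic": 0.0, "imprinted": 1.0},
            dropout_prob=0.0, seq_error=0.0,
        )
        sites, counts, _, meta, _, truth = simulate_dataset(p)
        pb = pseudo_bulk_ratios(counts.restrict_sites(truth.het_sites), meta, "individual")
        assert ((pb.ref_ratio < 0.05) | (pb.ref_ratio > 0.95)).all()

    def test_band_fraction_grows_with_pooled_cells(self):
        p = SimParams(
            rng_seed=6, n_individuals=1, n_genes=150,
            n_cells_per_type={"neuron": 50},
            gene_mode_probs={"random_MA": 1.0, "biallelic": 0.0, "imprinted": 0.0},
            deleterious_frac=0.0,
            snv_class_probs={"S": 1.0, "N": 0.0, "L": 0.0, "G": 0.0},
        )
        sites, counts, _, meta, _, truth = simulate_dataset(p)
        het = truth.het_sites
        cells = meta.cell_ids
        fracs = []
        for n in (5, 50):
            sub = counts.restrict_cells(cells[:n]).restrict_sites(het)
            pooled = sub.df.groupby("site_id")[["ref_depth", "alt_depth"]].sum()
            ratios = pooled.ref_depth / (pooled.ref_depth + pooled.alt_depth)
            fracs.append(band_fraction(ratios))
        assert fracs[1] > fracs[0]

    def test_band_histogram_counts_all_sites(self):
        ratios = pd.Series([0.0, 0.05, 0.45, 0.5, 0.55, 1.0])
        hist = ratio_band_histogram(ratios)
        assert hist.n_sites.sum() == len(ratios)
        assert len(hist) == 10


class TestImprintedCheck:
    def test_arithmetic_example(self):
        from scallele.types import SnpSite

        pb = pd.DataFrame(
            {
                "site_id": ["s_imp", "s_bi"],
                "group": ["i1", "i1"],
                "pooled_ref": [30, 15],
                "pooled_alt": [0, 15],
                "pooled_depth": [30, 30],
                "ref_ratio": [1.0, 0.5],
            }
        )
        sites = [
            SnpSite("s_imp", "chr1", 10, "A", "G", ("gi",)),
            SnpSite("s_bi", "chr1", 20, "A", "G", ("gb",)),
        ]
        res = imprinted_ratio_check(pb, {"gi"}, sites)
        assert res["median_deviation_imprinted"] == pytest.approx(0.5)
        assert res["median_deviation_other"] == pytest.approx(0.0)

    def test_simulated_imprinted_genes_deviate(self):
        p = SimParams(
            rng_seed=8, n_individuals=1, n_genes=150,
            n_cells_per_type={"neuron": 25},
            gene_mode_probs={"random_MA": 0.0, "biallelic": 0.7, "imprinted": 0.3},
            burst_prob_active_allele=1.0, dropout_prob=0.0,
        )
        sites, counts, _, meta, _, truth = simulate_dataset(p)
        pb = pseudo_bulk_ratios(counts.restrict_sites(truth.het_sites), meta, "individual")
        imprinted = set(
            truth.gene_modes.loc[
                truth.gene_modes["mode"].str.startswith("imprinted"), "gene_id"
            ]
        )
        res = imprinted_ratio_check(pb, imprinted, sites)
        assert res["p_value"] < 0.01
        assert res["median_deviation_imprinted"] > res["median_deviation_other"]

    def test_empty_imprinted_set_rejected(self, pipeline):
        with pytest.raises(ValueError):
            imprinted_ratio_check(pd.DataFrame(), set(), pipeline["sites"])
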