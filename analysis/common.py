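"""Shared settings for the numbered analysis drivers.

The cohort emulates one individual's brain scRNA-seq with five cell types;
the calibration cohort adds truth genotypes and a higher error rate for the
cutoff sweep. All drivers write under results/.
"""

from __future__ import annotations

from pathlib import Path

from scallele.config import PipelineConfig
from scallele.simulate import SimParams

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"

CONFIG = PipelineConfig()


def cohort_params(seed: int) -> SimParams:
    return SimParams(
        rng_seed=seed * 13 + 2,
        n_individuals=1,
        n_genes=300,
        n_cells_per_type={
            "astrocyte": 12, "microglia": 12, "neuron": 14,
            "oligodendrocyte": 12, "OPC": 12,
        },
    )


def calibration_params(seed: int) -> SimParams:
    return SimParams(
        rng_seed=seed * 13 + 1,
        n_individuals=1,
        n_genes=800,
        n_cells_per_type={"neuron": 8},
        seq_error=0.01,
        depth_mean=30.0,
    )


def require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise SystemExit(f"{path} missing — run analysis/{producer} first")
    return path
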