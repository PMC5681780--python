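"""Generate the synthetic cohorts every later driver consumes.

Writes, under results/data/: the main brain-like cohort (cohort.*) and the
truth-genotyped calibration cohort (calib.*), each as candidate-site VCF,
gene-model BED, allelic-count/expression/metadata/annotation TSVs, plus the
simulation ground truth.
"""

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import DATA, calibration_params, cohort_params

from scallele import io
from scallele.simulate import gene_model_frame, simulate_dataset


def write_cohort(params, prefix: str) -> None:
    sites, counts, expr, meta, annot, truth = simulate_dataset(params)
    io.write_snp_sites(sites, f"{prefix}.sites.vcf")
    io.write_gene_model_bed(gene_model_frame(sites, params), f"{prefix}.genes.bed")
    io.write_allelic_counts(counts, f"{prefix}.counts.tsv")
    io.write_expression(expr, f"{prefix}.expression.tsv")
    io.write_cell_metadata(meta, f"{prefix}.metadata.tsv")
    io.write_annotation(annot, f"{prefix}.annotation.tsv")
    io.write_truth(truth, f"{prefix}.truth")
    het = len(truth.het_sites)
    print(
        f"{prefix}: {len(sites)} candidate sites ({het} truly heterozygous), "
        f"{len(meta.cell_ids)} cells, {len(counts)} covered (site, cell) pairs"
    )


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    DATA.mkdir(parents=True, exist_ok=True)
    write_cohort(cohort_params(args.seed), str(DATA / "cohort"))
    write_cohort(calibration_params(args.seed), str(DATA / "calib"))


if __name__ == "__main__":
    main()
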