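"""Do functionally disrupted alternative alleles show reduced expression?

For each annotation scheme (SNV class, SIFT, PolyPhen HDIV/HVAR): counts of
cells expressing each allele per hetSNP, reference-read fractions at
well-covered observations, and one-sided rank-sum contrasts of the
deleterious class against the synonymous control. Writes per-scheme tables
plus results/disruption_tests.tsv.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import CONFIG, DATA, RESULTS, require

from scallele import io
from scallele.disruption import (
    class_comparison_tests,
    expressing_cell_counts,
    ref_fraction_by_class,
    ref_vs_alt_cells_test,
)

DELETERIOUS = {"SNV": "G", "SIFT": "D", "PPH_HDIV": "D", "PPH_HVAR": "D"}


def main() -> None:
    argparse.ArgumentParser().parse_args()
    counts = io.read_allelic_counts(str(DATA / "cohort.counts.tsv"))
    annot = io.read_annotation(str(DATA / "cohort.annotation.tsv"))
    hetsnps = io.read_table(
        str(require(RESULTS / "hetsnps.tsv", "03_classify_allelic_expression.py"))
    ).site_id
    rows = []
    for scheme, bad in DELETERIOUS.items():
        by_site = expressing_cell_counts(counts, annot, hetsnps, scheme, CONFIG)
        fracs = ref_fraction_by_class(counts, annot, hetsnps, scheme, CONFIG)
        io.write_table(by_site, str(RESULTS / f"disruption_{scheme}_cells.tsv"))
        io.write_table(fracs, str(RESULTS / f"disruption_{scheme}_fracs.tsv"))
        if (by_site.annotation_class == bad).sum() >= 3:
            cells_test = ref_vs_alt_cells_test(by_site, bad)
            frac_test = class_comparison_tests(fracs, "ref_fraction", bad, "S", "greater")
            rows.append(
                {
                    "scheme": scheme,
                    "class": bad,
                    "n_sites": cells_test["n_sites"],
                    "median_cells_ref": cells_test["median_ref_cells"],
                    "median_cells_alt": cells_test["median_alt_cells"],
                    "cells_p": cells_test["p_value"],
                    "median_ref_frac_deleterious": frac_test["median_a"],
                    "median_ref_frac_synonymous": frac_test["median_b"],
                    "frac_p": frac_test["p_value"],
                }
            )
            print(
                f"{scheme}/{bad}: alt allele expressed in fewer cells "
                f"(median {cells_test['median_ref_cells']:.1f} ref vs "
                f"{cells_test['median_alt_cells']:.1f} alt, p={cells_test['p_value']:.2g}); "
                f"reference-read fraction {100 * frac_test['median_a']:.1f}% vs "
                f"{100 * frac_test['median_b']:.1f}% at synonymous sites "
                f"(p={frac_test['p_value']:.2g})."
            )
    io.write_table(pd.DataFrame(rows), str(RESULTS / "disruption_tests.tsv"))


if __name__ == "__main__":
    main()
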