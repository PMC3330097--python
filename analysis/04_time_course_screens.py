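"""Per-gene significance screens: factorial ANOVA and the spline test.

The ANOVA partitions each gene's variation into accession, flowering status
and their interaction; the spline time-course test asks whether a gene's
trajectory deviates from flat, with a permutation null. Both screens attach
BH q-values; the q<0.01 spline set feeds the clustering and the q<0.05
vegetative-stage screens feed the PCA.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import SEED, TABLES, ensure_dirs, load_inputs

from fieldexpr import core_data, timecourse


def main() -> None:
    ensure_dirs()
    matrix, _, samples, env, pheno = load_inputs()
    design = core_data.join_design(samples, env, pheno)

    anova = timecourse.anova_per_gene(matrix, design)
    anova.to_csv(TABLES / "anova.tsv", sep="\t", index=False)
    for term, grp in anova.groupby("term"):
        n = (grp["q"] <= 0.05).sum()
        print(f"ANOVA {term}: {n} genes at q<=0.05 ({100 * n / len(grp):.0f}%)")

    out = []
    for acc, rows in design.groupby("accession", sort=False):
        sub = matrix.subset(samples=list(rows["sample_id"]))
        tc = timecourse.spline_timecourse_test(sub, rows, n_perm=499, seed=SEED + 1)
        tc.insert(0, "accession", acc)
        out.append(tc)
        strong = len(timecourse.select_significant(tc, 0.01))
        loose = len(timecourse.select_significant(tc, 0.05))
        print(f"spline {acc}: {loose} time-varying genes at q<0.05, {strong} at q<0.01")
    pd.concat(out, ignore_index=True).to_csv(TABLES / "timecourse.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
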