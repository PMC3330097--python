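"""Expressed-gene census: the all-replicates detection rule per timepoint.

A gene counts as expressed at a timepoint only if called present on every
available replicate array of that (accession, day) sample. Reports the
per-timepoint detection rates, the accession-level unions and overlap, and
the never-detected fraction of the array.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import TABLES, ensure_dirs, load_inputs

from fieldexpr import detection


def main() -> None:
    ensure_dirs()
    matrix, flags, samples, _, _ = load_inputs()
    census = detection.call_expressed(flags, samples)

    tp = census.timepoint_counts()
    tp["pct_of_array"] = (100 * tp["n_expressed"] / matrix.shape[0]).round(1)
    tp.to_csv(TABLES / "census_timepoints.tsv", sep="\t", index=False)
    venn = detection.venn_counts(dict(census.per_accession))
    venn.to_csv(TABLES / "census_venn.tsv", sep="\t", index=False)
    absent = detection.absent_everywhere(census, matrix.gene_ids)

    for acc, grp in tp.groupby("accession"):
        print(f"{acc}: {grp['pct_of_array'].min():.0f}%-{grp['pct_of_array'].max():.0f}% "
              f"of genes expressed per timepoint, union {len(census.per_accession[acc])}")
    pct = 100 * len(census.overall) / matrix.shape[0]
    print(f"expressed in >=1 accession at >=1 timepoint: {len(census.overall)} ({pct:.0f}%)")
    print(f"never detected anywhere: {len(absent)} ({100 - pct:.0f}%)")


if __name__ == "__main__":
    main()
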