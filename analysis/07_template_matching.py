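"""Template matching: genes co-regulated with a chosen driver gene.

Takes the extreme-loading gene most correlated with PC1 of the vegetative
PCA as the temperature-axis template (standing in for a known
thermoregulatory driver), then finds all genes whose per-timepoint mean
profile matches it at |r| >= sqrt(0.47) — the r-squared-derived threshold —
and, separately, at the conventional |r| >= 0.7.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import TABLES, ensure_dirs, load_inputs

from fieldexpr import cluster_enrich as ce
from fieldexpr import core_data, pvca, vegpca


def main() -> None:
    ensure_dirs()
    matrix, _, samples, env, pheno = load_inputs()
    scores = pd.read_csv(TABLES / "vegpca_scores.tsv", sep="\t", index_col=0)
    loadings = pd.read_csv(TABLES / "vegpca_loadings.tsv", sep="\t", index_col=0)
    veg_matrix = matrix.subset(genes=list(loadings.index), samples=list(scores.index))
    pcm = pvca.fit_pca(veg_matrix)

    candidates = vegpca.extreme_loading_genes(pcm.loadings["PC1"], 0.025)[:25]
    template = max(candidates, key=lambda g: abs(
        vegpca.gene_pc_correlation(veg_matrix, pcm, g, "PC1")["r"]))
    stats = vegpca.gene_pc_correlation(veg_matrix, pcm, template, "PC1")
    print(f"template gene {template}: r2 with PC1 = {stats['r2']:.2f} (p = {stats['p']:.1e})")

    design = core_data.join_design(
        core_data.SampleTable(samples.data[samples.data["sample_id"].isin(scores.index)]
                              .reset_index(drop=True)))
    out = []
    for acc, rows in design.groupby("accession", sort=False):
        sub = veg_matrix.subset(samples=list(rows["sample_id"]))
        profiles = ce.profile_matrix(sub, core_data.SampleTable(rows.reset_index(drop=True)))
        for label, thr, is_r2 in [("r2_0.47", 0.47, True), ("r_0.70", 0.70, False)]:
            tm = vegpca.template_match(profiles, template, thr, threshold_is_r2=is_r2)
            m = tm.matches.copy()
            m.insert(0, "accession", acc)
            m.insert(1, "threshold", label)
            out.append(m)
            pct = 100 * len(m) / len(profiles)
            print(f"{acc} @ {label}: {len(m)} genes match ({pct:.0f}%)")
    pd.concat(out, ignore_index=True).to_csv(TABLES / "template_matches.tsv",
                                             sep="\t", index=False)


if __name__ == "__main__":
    main()
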