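"""Vegetative-stage PCA and its environmental/developmental regression.

Restricts to pre-bolting samples and genes time-varying in both accessions
(spline q<0.05 on vegetative samples), fits the PCA, plots-in-tables the
per-day mean PC trajectories, regresses the first five axes on
TMAX + PPT + RLN + RD + age with VIF screening and BH FDR, and extracts the
extreme-loading gene lists (2.5% per tail) for each axis.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import SEED, TABLES, ensure_dirs, load_inputs

from fieldexpr import core_data, pvca, timecourse, vegpca


def main() -> None:
    ensure_dirs()
    matrix, _, samples, env, pheno = load_inputs()
    design = core_data.join_design(samples, env, pheno)

    sig = {}
    for acc, rows in design.groupby("accession", sort=False):
        veg_rows = rows[rows["flowering_status"] == "vegetative"]
        sub = matrix.subset(samples=list(veg_rows["sample_id"]))
        # the q<0.05 screen needs permutation resolution well below 0.05/frac-at-floor
        tc = timecourse.spline_timecourse_test(sub, veg_rows, n_perm=1999, seed=SEED + 1)
        sig[acc] = timecourse.select_significant(tc, 0.05)
        print(f"{acc}: {len(sig[acc])} vegetative-stage time-varying genes at q<0.05")

    veg_matrix, veg_samples = vegpca.vegetative_subset(matrix, samples, sig)
    print(f"vegetative PCA substrate: {veg_matrix.shape[0]} shared genes x "
          f"{veg_matrix.shape[1]} vegetative arrays")
    pcm = pvca.fit_pca(veg_matrix)
    axes = [f"PC{i + 1}" for i in range(min(5, pcm.n_components))]
    print("variance captured:",
          {a: f"{100 * p:.1f}%" for a, p in zip(axes, pcm.proportions)})

    pcm.scores[axes].to_csv(TABLES / "vegpca_scores.tsv", sep="\t")
    pcm.loadings[axes].to_csv(TABLES / "vegpca_loadings.tsv", sep="\t")
    vegpca.pc_trajectories(pcm, veg_samples, axes).to_csv(
        TABLES / "vegpca_trajectories.tsv", sep="\t", index=False)

    veg_design = core_data.join_design(veg_samples, env, pheno)
    fits = vegpca.regress_pc_on_covariates(pcm, veg_design, axes=axes)
    rows = []
    for axis, fit in fits.items():
        tab = fit.table.copy()
        tab.insert(0, "axis", axis)
        tab["adjusted_r2"] = fit.adjusted_r2
        rows.append(tab)
        hits = tab.loc[tab["significant"], "covariate"].tolist()
        print(f"{axis}: adj r2 = {fit.adjusted_r2:.2f}; significant: {hits or 'none'}")
    pd.concat(rows, ignore_index=True).to_csv(TABLES / "vegpca_regression.tsv",
                                              sep="\t", index=False)

    tails = [{"axis": a, "gene_id": g}
             for a in axes for g in vegpca.extreme_loading_genes(pcm.loadings[a], 0.025)]
    pd.DataFrame(tails).to_csv(TABLES / "vegpca_extreme_genes.tsv", sep="\t", index=False)
    per_axis = len(tails) // len(axes)
    print(f"extreme-loading lists: {per_axis} genes per axis")


if __name__ == "__main__":
    main()
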