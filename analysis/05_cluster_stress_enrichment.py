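"""Co-expression clusters, their drivers, and stress-set enrichment.

Per accession: cluster the standardized mean profiles of the strongly
time-varying genes (spline q<0.01) with K-means, choosing K by the
silhouette stopping rule; decompose each cluster's variance with the
environmental PVCA model; and test every cluster against the stress
gene-set collection (hypergeometric, BH across all cluster x set pairs).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from _common import DATA, SEED, TABLES, ensure_dirs, load_inputs

from fieldexpr import cluster_enrich as ce
from fieldexpr import core_data, timecourse


def main() -> None:
    ensure_dirs()
    matrix, _, samples, env, pheno = load_inputs()
    design = core_data.join_design(samples, env, pheno)
    tc = pd.read_csv(TABLES / "timecourse.tsv", sep="\t")
    sets = core_data.read_gene_sets(DATA / "stress_sets.gmt")
    cats = pd.read_csv(DATA / "set_categories.tsv", sep="\t")
    cat_map = dict(zip(cats["set"], cats["category"]))

    all_labels, all_cpv, all_enr = [], [], []
    for acc, rows in design.groupby("accession", sort=False):
        sig = timecourse.select_significant(tc[tc["accession"] == acc], 0.01)
        sub = matrix.subset(samples=list(rows["sample_id"]))
        st = core_data.SampleTable(rows.reset_index(drop=True))
        profiles = ce.profile_matrix(sub, st, sig)
        k_max = min(15, len(profiles) // 2)
        k_star, diag = ce.select_cluster_number(profiles, 2, k_max, seed=SEED + 2)
        diag.insert(0, "accession", acc)
        diag.to_csv(TABLES / f"cluster_diagnostics_{acc}.tsv", sep="\t", index=False)
        cl = ce.kmeans_cluster(profiles, k_star, seed=SEED + 2)
        print(f"{acc}: {len(profiles)} genes -> K*={k_star} clusters "
              f"(worst-cluster silhouette {cl.worst_cluster_silhouette:.2f})")

        all_labels.append(pd.DataFrame({
            "accession": acc, "gene_id": cl.labels.index,
            "cluster": cl.labels.values, "silhouette": cl.silhouettes.values}))
        cpv, _ = ce.cluster_pvca(sub, cl, rows.reset_index(drop=True))
        cpv.insert(0, "accession", acc)
        all_cpv.append(cpv)
        flow50 = cpv[(cpv["factor"] == "flowering_status") & (cpv["proportion"] > 0.5)]
        print(f"  {flow50['cluster'].nunique()} clusters with >50% variance from flowering")

        table, binary, summary = ce.stress_annotation(cl, sets, alpha=0.01,
                                                      category_map=cat_map)
        table.insert(0, "accession", acc)
        all_enr.append(table)
        print(f"  enrichment: {int(table['enriched'].sum())} cluster x set pairs; "
              f"both={summary['both']} abiotic-only={summary['abiotic_only']} "
              f"biotic-only={summary['biotic_only']}")

    pd.concat(all_labels, ignore_index=True).to_csv(TABLES / "cluster_labels.tsv",
                                                    sep="\t", index=False)
    pd.concat(all_cpv, ignore_index=True).to_csv(TABLES / "cluster_pvca.tsv",
                                                 sep="\t", index=False)
    pd.concat(all_enr, ignore_index=True).to_csv(TABLES / "enrichment.tsv",
                                                 sep="\t", index=False)


if __name__ == "__main__":
    main()
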