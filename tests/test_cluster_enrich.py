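import itertools
import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from fieldexpr import cluster_enrich as ce
from fieldexpr import core_data, synthgen
from fieldexpr.core_data import GeneSet, GeneSetCollection, ValidationError


def _cluster_exp(n_genes=250, seed=51, cluster_var=0.85):
    cfg = synthgen.SimulationConfig(
        n_genes=n_genes, seed=seed, null_fraction=0.0,
        variance_fractions={"accession": 0.0, "flowering": 0.0,
                            "environment": 0.0, "cluster": cluster_var},
        n_clusters=5,
    )
    return synthgen.simulate_experiment(cfg)


def _profiles(exp, genes=None):
    return ce.profile_matrix(exp.matrix, exp.samples, genes)


class TestProfileMatrix:
    def test_replicate_means_before_standardization(self):
        samples = core_data.SampleTable(pd.DataFrame([
            {"sample_id": f"a_d1_r{r}", "accession": "a", "day": 1,
             "flowering_status": "vegetative", "replicate": r} for r in (1, 2, 3)
        ] + [
            {"sample_id": f"a_d4_r{r}", "accession": "a", "day": 4,
             "flowering_status": "vegetative", "replicate": r} for r in (1, 2, 3)
        ]))
        m = core_data.ExpressionMatrix(pd.DataFrame(
            [[1.0, 2.0, 3.0, 5.0, 5.0, 5.0]],
            index=["g1"], columns=samples.sample_ids,
        ))
        # raw means are (2, 5); the standardized profile is their z-score
        prof = ce.profile_matrix(m, samples)
        np.testing.assert_allclose(prof.loc["g1"].to_numpy(), [-1.0, 1.0])

    def test_constant_gene_dropped(self, default_exp):
        data = default_exp.matrix.data.copy()
        data.iloc[0] = 1.0
        m = core_data.ExpressionMatrix(data)
        prof = ce.profile_matrix(m, default_exp.samples)
        assert data.index[0] not in prof.index
        assert len(prof) == len(data) - 1

    def test_within_cluster_correlation_exceeds_between(self):
        exp = _cluster_exp()
        prof = _profiles(exp)
        lab = exp.truth.cluster_labels.loc[prof.index]
        corr = np.corrcoef(prof.to_numpy())
        same = lab.to_numpy()[:, None] == lab.to_numpy()[None, :]
        off_diag = ~np.eye(len(prof), dtype=bool)
        assert corr[same & off_diag].mean() > corr[~same].mean() + 0.5


class TestKmeans:
    def test_two_tight_clouds_recovered(self, rng):
        a = rng.normal(0, 0.05, size=(20, 3)) + [5, 0, 0]
        b = rng.normal(0, 0.05, size=(20, 3)) - [5, 0, 0]
        prof = pd.DataFrame(np.vstack([a, b]), index=[f"g{i}" for i in range(40)])
        cl = ce.kmeans_cluster(prof, 2, seed=1)
        lab = cl.labels.to_numpy()
        assert adjusted_rand_score([0] * 20 + [1] * 20, lab) == 1.0

    def test_seed_determinism(self):
        exp = _cluster_exp(n_genes=120)
        prof = _profiles(exp)
        c1 = ce.kmeans_cluster(prof, 5, seed=9)
        c2 = ce.kmeans_cluster(prof, 5, seed=9)
        pd.testing.assert_series_equal(c1.labels, c2.labels)

    def test_planted_templates_recovered(self):
        exp = _cluster_exp()
        prof = _profiles(exp)
        cl = ce.kmeans_cluster(prof, 5, seed=2)
        truth = exp.truth.cluster_labels.loc[prof.index]
        assert adjusted_rand_score(truth, cl.labels) > 0.95

    def test_k_bounds(self):
        prof = pd.DataFrame(np.eye(4), index=list("abcd"))
        with pytest.raises(ValidationError):
            ce.kmeans_cluster(prof, 1)
        with pytest.raises(ValidationError):
            ce.kmeans_cluster(prof, 5)


def brute_force_silhouette(x: np.ndarray, lab: np.ndarray) -> np.ndarray:
    """O(n^2) double-loop reference implementation of s(i)."""
    n = len(lab)
    d = np.sqrt(((x[:, None, :] - x[None, :, :]) ** 2).sum(-1))
    s = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if lab[j] == lab[i] and j != i]
        if not own:
            continue
        a = np.mean([d[i, j] for j in own])
        b = math.inf
        for k in set(lab) - {lab[i]}:
            b = min(b, np.mean([d[i, j] for j in range(n) if lab[j] == k]))
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return s


class TestSilhouette:
    def test_well_separated_clusters_near_one(self, rng):
        x = np.vstack([rng.normal(0, 0.01, (10, 2)) + [10, 0],
                       rng.normal(0, 0.01, (10, 2)) - [10, 0]])
        prof = pd.DataFrame(x, index=[f"g{i}" for i in range(20)])
        lab = pd.Series([1] * 10 + [2] * 10, index=prof.index)
        s = ce.silhouette_widths(prof, lab)
        assert (s > 0.99).all()

    def test_equidistant_point_scores_zero(self):
        # g0 sits exactly between its own mate and the other cluster's point
        prof = pd.DataFrame([[0.0], [2.0], [-2.0]], index=["g0", "g1", "g2"])
        lab = pd.Series([1, 1, 2], index=prof.index)
        s = ce.silhouette_widths(prof, lab)
        assert s["g0"] == pytest.approx(0.0, abs=1e-12)

    def test_singleton_cluster_gets_zero(self):
        prof = pd.DataFrame([[0.0], [1.0], [5.0]], index=["a", "b", "c"])
        lab = pd.Series([1, 1, 2], index=prof.index)
        s = ce.silhouette_widths(prof, lab)
        assert s["c"] == 0.0

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(5):
            x = rng.normal(size=(40, 4))
            lab = rng.integers(1, 5, size=40)
            prof = pd.DataFrame(x, index=[f"g{i}" for i in range(40)])
            s = ce.silhouette_widths(prof, pd.Series(lab, index=prof.index))
            np.testing.assert_allclose(s.to_numpy(), brute_force_silhouette(x, lab), atol=1e-10)


class TestSelectClusterNumber:
    def test_planted_templates_keep_positive_silhouette(self):
        exp = _cluster_exp()
        prof = _profiles(exp)
        k_star, diag = ce.select_cluster_number(prof, 2, 10, seed=3)
        worst = diag.set_index("K")["worst_cluster_silhouette"]
        assert (worst.loc[2:5] > 0).all()
        assert k_star > 5

    def test_single_blob_triggers_before_kmax(self, rng):
        # unstructured data in profile-like dimension: the rule fires well
        # before K_max and the worst cluster's silhouette is <= 0 there
        prof = pd.DataFrame(rng.normal(size=(80, 18)), index=[f"g{i}" for i in range(80)])
        k_star, diag = ce.select_cluster_number(prof, 2, 14, seed=4)
        worst = diag.set_index("K")["worst_cluster_silhouette"]
        assert k_star < 14
        assert worst[k_star] <= 0

    def test_zero_persistence_is_first_crossing(self, rng):
        prof = pd.DataFrame(rng.normal(size=(80, 18)), index=[f"g{i}" for i in range(80)])
        k_star, diag = ce.select_cluster_number(prof, 2, 14, persistence_window=0, seed=4)
        worst = diag.set_index("K")["worst_cluster_silhouette"]
        first = next((k for k in worst.index if worst[k] <= 0), 14)
        assert k_star == first


class TestClusterPvca:
    def test_bin_edges(self):
        assert [ce.proportion_bin(p) for p in (0.10, 0.30, 0.60, 0.80)] == [
            "<25%", "25-50%", "50-75%", ">75%"
        ]

    def test_flowering_template_cluster_attributed_to_flowering(self):
        cfg = synthgen.SimulationConfig(
            n_genes=150, seed=55, null_fraction=0.0,
            variance_fractions={"accession": 0.0, "flowering": 0.8,
                                "environment": 0.0, "cluster": 0.0},
            n_clusters=2,
        )
        exp = synthgen.simulate_experiment(cfg)
        design = core_data.join_design(exp.samples, exp.environment)
        # treat all genes as one cluster plus a random split for the second
        prof = _profiles(exp)
        cl = ce.kmeans_cluster(prof, 2, seed=5)
        table, decomps = ce.cluster_pvca(exp.matrix, cl, design)
        flow = table[(table["factor"] == "flowering_status")]
        assert (flow["proportion"] > 0.5).all()
        assert set(flow["bin"]) <= {"50-75%", ">75%"}

    def test_small_clusters_skipped(self, default_exp, default_design):
        prof = _profiles(default_exp).iloc[:20]
        cl = ce.kmeans_cluster(prof, 4, seed=6)
        table, decomps = ce.cluster_pvca(
            default_exp.matrix, cl, default_design, min_cluster_size=10
        )
        small = [k for k in range(1, 5) if len(cl.members(k)) < 10]
        for k in small:
            assert decomps[k] is None
            assert (table.loc[table["cluster"] == k, "bin"] == "skipped").all()


def brute_force_hypergeom_tail(N, K, n, k):
    """P(X >= k) by exhaustive enumeration of all n-draws from N."""
    universe = range(N)
    hits = 0
    total = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if sum(1 for x in draw if x < K) >= k:
            hits += 1
    return hits / total


class TestHypergeom:
    def test_matches_enumeration_on_small_universes(self):
        cases = [(10, 5, 4, 4), (10, 5, 4, 0), (12, 6, 5, 3), (15, 7, 6, 2), (8, 3, 3, 1)]
        for N, K, n, k in cases:
            universe = [f"g{i}" for i in range(N)]
            members = universe[:n]
            # put k of the set inside the cluster, rest outside
            gene_set = universe[:k] + universe[n : n + (K - k)]
            got_k, p = ce.hypergeom_enrichment(members, gene_set, universe)
            assert got_k == k
            assert p == pytest.approx(brute_force_hypergeom_tail(N, K, n, k), abs=1e-12)

    def test_zero_overlap_gives_one(self):
        universe = [f"g{i}" for i in range(10)]
        k, p = ce.hypergeom_enrichment(universe[:3], universe[5:], universe)
        assert p == pytest.approx(1.0)

    def test_set_equals_universe_gives_one(self):
        universe = [f"g{i}" for i in range(10)]
        k, p = ce.hypergeom_enrichment(universe[:4], universe, universe)
        assert k == 4 and p == pytest.approx(1.0)

    def test_members_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            ce.hypergeom_enrichment(["x"], ["a"], ["a", "b"])


class TestStressAnnotation:
    def test_planted_sets_and_only_them_flagged(self):
        exp = _cluster_exp()
        prof = _profiles(exp)
        cl = ce.kmeans_cluster(prof, 5, seed=7)
        sets, cats = synthgen.synthetic_stress_sets(exp.truth, seed=8)
        table, binary, summary = ce.stress_annotation(
            cl, sets, alpha=0.01, category_map=cats
        )
        enriched = table[table["enriched"]]
        # every planted stress set flags exactly one cluster, no random set flags any
        planted = {s for s in sets.names if s.startswith("stress_")}
        assert set(enriched["set"]) == planted
        assert enriched.groupby("set").size().eq(1).all()

    def test_verbatim_cluster_floors_p(self):
        universe = [f"g{i}" for i in range(200)]
        lab = pd.Series([1] * 30 + [2] * 170, index=universe)
        cl = ce.Clustering(labels=lab, K=2,
                           silhouettes=pd.Series(0.5, index=universe), inertia=0.0)
        sets = GeneSetCollection((GeneSet("exact", tuple(universe[:30])),))
        table, _, _ = ce.stress_annotation(cl, sets, alpha=0.01)
        p = table.loc[(table["cluster"] == 1) & (table["set"] == "exact"), "p"].iloc[0]
        assert p < 1e-30

    def test_null_clusters_flag_near_alpha_rate(self, rng):
        """Random clusters vs random sets: raw-p flags come at ~alpha rate."""
        universe = [f"g{i}" for i in range(400)]
        lab = pd.Series(rng.integers(1, 11, size=400), index=universe)
        cl = ce.Clustering(labels=lab, K=10,
                           silhouettes=pd.Series(0.0, index=universe), inertia=0.0)
        sets = GeneSetCollection(tuple(
            GeneSet(f"s{j}", tuple(rng.choice(universe, 60, replace=False)))
            for j in range(30)
        ))
        table, _, _ = ce.stress_annotation(cl, sets, alpha=0.05, correction="raw")
        n_pairs = len(table)
        rate = table["enriched"].mean()
        sd = math.sqrt(0.05 * 0.95 / n_pairs)
        assert abs(rate - 0.05) < 4 * sd

    def test_invariant_to_gene_order_and_outside_genes(self):
        universe = [f"g{i}" for i in range(50)]
        lab = pd.Series([1] * 25 + [2] * 25, index=universe)
        cl = ce.Clustering(labels=lab, K=2,
                           silhouettes=pd.Series(0.0, index=universe), inertia=0.0)
        base = GeneSetCollection((GeneSet("s", tuple(universe[:20])),))
        noisy = GeneSetCollection((GeneSet("s", tuple(universe[:20][::-1]) + ("zz1", "zz2")),))
        t1, _, _ = ce.stress_annotation(cl, base)
        t2, _, _ = ce.stress_annotation(cl, noisy)
        pd.testing.assert_frame_equal(t1, t2)
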