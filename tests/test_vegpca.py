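import math

import numpy as np
import pandas as pd
import pytest

from fieldexpr import core_data, pvca, vegpca
from fieldexpr.cluster_enrich import profile_matrix
from fieldexpr.core_data import ExpressionMatrix, SampleTable, ValidationError


class TestVegetativeSubset:
    def test_flowering_samples_and_nonshared_genes_removed(self, default_exp):
        genes = default_exp.matrix.gene_ids
        sig = {"acc1": genes[:60], "acc2": genes[30:90]}
        sub, samples = vegpca.vegetative_subset(default_exp.matrix, default_exp.samples, sig)
        assert (samples.data["flowering_status"] == "vegetative").all()
        assert sub.gene_ids == genes[30:60]
        assert set(sub.sample_ids) == set(samples.data["sample_id"])

    def test_disjoint_lists_error(self, default_exp):
        genes = default_exp.matrix.gene_ids
        with pytest.raises(ValidationError, match="empty"):
            vegpca.vegetative_subset(
                default_exp.matrix, default_exp.samples,
                {"acc1": genes[:10], "acc2": genes[10:20]},
            )

    def test_size_matches_set_oracle(self, default_exp, rng):
        genes = default_exp.matrix.gene_ids
        sig = {a: list(rng.choice(genes, 120, replace=False)) for a in ("acc1", "acc2")}
        sub, _ = vegpca.vegetative_subset(default_exp.matrix, default_exp.samples, sig)
        assert len(sub.gene_ids) == len(set(sig["acc1"]) & set(sig["acc2"]))


def _dummy_pcmodel(scores: pd.DataFrame) -> pvca.PCModel:
    k = scores.shape[1]
    return pvca.PCModel(
        loadings=pd.DataFrame(np.zeros((1, k)), columns=scores.columns),
        scores=scores,
        eigenvalues=np.ones(k),
        proportions=np.full(k, 1.0 / k),
        centered=pd.DataFrame(),
    )


class TestTrajectories:
    def test_mean_and_se_hand_values(self):
        samples = SampleTable(pd.DataFrame([
            {"sample_id": f"a_d1_r{r}", "accession": "a", "day": 1,
             "flowering_status": "vegetative", "replicate": r} for r in (1, 2, 3)
        ] + [{"sample_id": "a_d4_r1", "accession": "a", "day": 4,
              "flowering_status": "vegetative", "replicate": 1}]))
        scores = pd.DataFrame(
            {"PC1": [1.0, 2.0, 3.0, 9.0]},
            index=["a_d1_r1", "a_d1_r2", "a_d1_r3", "a_d4_r1"],
        )
        out = vegpca.pc_trajectories(_dummy_pcmodel(scores), samples, axes=("PC1",))
        d1 = out[(out["day"] == 1)].iloc[0]
        assert d1["mean"] == pytest.approx(2.0)
        assert d1["se"] == pytest.approx(0.577, abs=1e-3)
        d4 = out[(out["day"] == 4)].iloc[0]
        assert np.isnan(d4["se"])  # single replicate

    def test_temperature_driven_pc_tracks_tmax(self, rng):
        """A score vector built from tmax has a trajectory correlated with
        the weather series (up to PC sign)."""
        from fieldexpr import synthgen
        env = synthgen.simulate_environment(40, seed=1)
        days = np.repeat(np.arange(18, 40, 3), 3)
        ids = [f"a_d{d}_r{r}" for d, r in zip(days, [1, 2, 3] * (len(days) // 3))]
        samples = SampleTable(pd.DataFrame({
            "sample_id": ids, "accession": "a", "day": days,
            "flowering_status": "vegetative",
            "replicate": [1, 2, 3] * (len(days) // 3),
        }))
        tmax = env.data.set_index("day").loc[days, "tmax"].to_numpy()
        scores = pd.DataFrame({"PC1": tmax + rng.normal(0, 0.3, len(days))}, index=ids)
        out = vegpca.pc_trajectories(_dummy_pcmodel(scores), samples, axes=("PC1",))
        daily_tmax = env.data.set_index("day").loc[out["day"], "tmax"]
        r = np.corrcoef(out["mean"], daily_tmax)[0, 1]
        assert abs(r) > 0.9


class TestRegression:
    def test_orthonormal_covariates_unit_vif(self, rng):
        n = 40
        # orthonormal columns, also orthogonal to the intercept
        q, _ = np.linalg.qr(np.hstack([np.ones((n, 1)), rng.normal(size=(n, 4))]))
        q = q[:, 1:]
        design = pd.DataFrame(q, columns=["tmax", "precipitation", "rln", "rd"])
        design["day"] = q[:, 0] * 0  # drop day from model instead
        design["sample_id"] = [f"s{i}" for i in range(n)]
        scores = pd.DataFrame({"PC1": rng.normal(size=n)}, index=design["sample_id"])
        fits = vegpca.regress_pc_on_covariates(
            _dummy_pcmodel(scores), design,
            covariates=("tmax", "precipitation", "rln", "rd"), axes=("PC1",),
        )
        np.testing.assert_allclose(fits["PC1"].table["vif"], 1.0, atol=1e-10)

    def test_duplicate_covariate_flagged(self, rng):
        n = 30
        design = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "tmax": rng.normal(size=n),
        })
        design["rln"] = design["tmax"]  # exact duplicate
        design["rd"] = rng.normal(size=n)
        scores = pd.DataFrame({"PC1": rng.normal(size=n)}, index=design["sample_id"])
        fits = vegpca.regress_pc_on_covariates(
            _dummy_pcmodel(scores), design, covariates=("tmax", "rln", "rd"), axes=("PC1",),
        )
        tab = fits["PC1"].table.set_index("covariate")
        assert tab.loc["tmax", "high_vif"] and tab.loc["rln", "high_vif"]
        assert not tab.loc["rd", "high_vif"]

    def test_planted_tmax_effect_recovered(self, rng):
        n = 42
        design = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(n)],
            "tmax": rng.normal(20, 4, n),
            "precipitation": rng.exponential(5, n),
            "rln": rng.normal(10, 2, n),
            "rd": rng.normal(5, 1, n),
            "day": rng.integers(18, 45, n).astype(float),
        })
        signal = 2.0 * design["tmax"]
        noise_sd = signal.std() / 3  # planted R2 ~ 0.9
        scores = pd.DataFrame(
            {"PC1": (signal + rng.normal(0, noise_sd, n)).to_numpy()},
            index=design["sample_id"],
        )
        fits = vegpca.regress_pc_on_covariates(_dummy_pcmodel(scores), design, axes=("PC1",))
        tab = fits["PC1"].table.set_index("covariate")
        assert tab.loc["tmax", "significant"]
        assert abs(tab.loc["tmax", "beta"] - 2.0) < 3 * tab.loc["tmax", "se"]
        assert abs(fits["PC1"].adjusted_r2 - 0.9) < 0.1

    def test_too_few_samples_error(self, rng):
        design = pd.DataFrame({
            "sample_id": ["s0", "s1", "s2"],
            "tmax": [1.0, 2.0, 3.0], "precipitation": [0.0, 1.0, 0.0],
            "rln": [1.0, 2.0, 1.0], "rd": [1.0, 1.0, 2.0], "day": [1.0, 2.0, 3.0],
        })
        scores = pd.DataFrame({"PC1": [0.0, 1.0, 2.0]}, index=design["sample_id"])
        with pytest.raises(ValidationError, match="fewer"):
            vegpca.regress_pc_on_covariates(_dummy_pcmodel(scores), design, axes=("PC1",))


class TestExtremeLoadings:
    def test_published_tail_count(self, rng):
        loadings = pd.Series(rng.normal(size=8954),
                             index=[f"g{i}" for i in range(8954)])
        assert len(vegpca.extreme_loading_genes(loadings, 0.025)) == 448

    def test_small_n_ceiling(self, rng):
        loadings = pd.Series(rng.normal(size=100), index=[f"g{i}" for i in range(100)])
        assert len(vegpca.extreme_loading_genes(loadings, 0.025)) == 6

    def test_matches_sort_and_slice_oracle(self, rng):
        for n in (37, 200, 1001):
            loadings = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
            k = math.ceil(0.03 * n)
            got = set(vegpca.extreme_loading_genes(loadings, 0.03))
            ranked = loadings.sort_values()
            want = set(ranked.index[:k]) | set(ranked.index[-k:])
            assert got == want
            assert len(got) == 2 * k

    def test_alpha_bounds(self, rng):
        loadings = pd.Series(rng.normal(size=10))
        with pytest.raises(ValidationError):
            vegpca.extreme_loading_genes(loadings, 0.6)


class TestGenePcCorrelation:
    def test_gene_equal_to_scores(self, default_exp):
        pcm = pvca.fit_pca(default_exp.matrix)
        data = default_exp.matrix.data.copy()
        data.loc["g_pc"] = pcm.scores["PC1"].to_numpy()
        m = ExpressionMatrix(data)
        out = vegpca.gene_pc_correlation(m, pcm, "g_pc", "PC1")
        assert out["r"] == pytest.approx(1.0)
        assert out["p"] < 1e-10

    def test_zero_variance_gene_is_nan(self, default_exp):
        pcm = pvca.fit_pca(default_exp.matrix)
        data = default_exp.matrix.data.copy()
        data.loc["flatgene"] = 2.0
        out = vegpca.gene_pc_correlation(ExpressionMatrix(data), pcm, "flatgene", "PC1")
        assert np.isnan(out["r"])

    def test_planted_r2_recovered(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(10):
            n = 42
            s = rng.normal(size=n)
            y = s + rng.normal(0, 1.0, n)  # planted r2 = 0.5
            r = np.corrcoef(y, s)[0, 1]
            hits += abs(r**2 - 0.5) < 0.15
        scores = None
        assert hits >= 8  # the estimator concentrates near the planted value


def _profile_fixture(rng, n_genes=200, n_cols=12):
    base = rng.normal(size=(n_genes, n_cols))
    return pd.DataFrame(base, index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"c{j}" for j in range(n_cols)])


class TestTemplateMatch:
    def test_self_match_and_anticorrelation(self, rng):
        prof = _profile_fixture(rng, 5)
        prof.loc["g1"] = -prof.loc["g0"]
        tm = vegpca.template_match(prof, "g0", 0.9)
        got = dict(zip(tm.matches["gene_id"], tm.matches["r"]))
        assert got["g0"] == pytest.approx(1.0)
        assert got["g1"] == pytest.approx(-1.0)

    def test_matches_bruteforce_scan(self, rng):
        prof = _profile_fixture(rng)
        thr = 0.4
        tm = vegpca.template_match(prof, "g3", thr)
        t = prof.loc["g3"]
        brute = {
            g for g in prof.index
            if abs(np.corrcoef(prof.loc[g], t)[0, 1]) >= thr - 1e-12
        }
        assert set(tm.gene_ids) == brute

    def test_two_gene_symmetry(self, rng):
        prof = _profile_fixture(rng, 2)
        a_matches_b = "g1" in vegpca.template_match(prof, "g0", 0.3).gene_ids
        b_matches_a = "g0" in vegpca.template_match(prof, "g1", 0.3).gene_ids
        assert a_matches_b == b_matches_a

    def test_r2_threshold_mode(self, rng):
        prof = _profile_fixture(rng)
        tm = vegpca.template_match(prof, "g0", 0.47, threshold_is_r2=True)
        assert tm.threshold == pytest.approx(math.sqrt(0.47))
        assert (tm.matches["r"].abs() >= math.sqrt(0.47) - 1e-12).all()

    def test_threshold_bounds(self, rng):
        prof = _profile_fixture(rng, 5)
        with pytest.raises(ValidationError):
            vegpca.template_match(prof, "g0", 1.5)
        with pytest.raises(ValidationError):
            vegpca.template_match(prof, "g0", 0.0)
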