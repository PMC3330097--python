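"""Synthetic field-expression experiments with planted, recoverable structure.

The generator emulates a two-accession outdoor time course: shoots sampled
every three days through the vegetative stage and into flowering (the two
accessions bolt on different days), three replicate arrays per sample with
one late replicate optionally lost, daily weather with spring-like
temperatures and intermittent rain, and per-sample rosette phenotypes.

Each gene's log2 expression is an additive model

    y[g, s] = mu_g + a_g * I[accession] + f_g * I[flowering]
              + cT_g * zTMAX(day_s) + cP_g * zPPT(day_s)
              + sqrt(v_clust) * tau_{k(g)}(day_s) + eps,   eps ~ N(0, v_resid)

where the indicator/covariate columns are scaled so that each term
contributes its configured fraction of per-gene variance across the realized
design, tau_k are orthonormal smooth (natural cubic spline) temporal
templates shared by cluster members, and null genes carry no effects at all.
Detection flags derive from each gene's baseline mu_g exceeding a background
quantile, then flip with a configured noise rate. Everything planted is
returned as a `SyntheticTruth` so downstream stages can be scored against
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._basis import natural_spline_basis
from .core_data import (
    DetectionFlags,
    EnvironmentSeries,
    ExpressionMatrix,
    PhenotypeTable,
    SampleTable,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "SimulatedExperiment",
    "simulate_environment",
    "simulate_experiment",
    "synthetic_stress_sets",
]

EFFECT_FACTORS = ("accession", "flowering", "environment", "cluster")


@dataclass
class SimulationConfig:
    """Knobs for one synthetic experiment.

    Defaults mirror the emulated field design: 2 accessions with 6 and 8
    vegetative timepoints plus 2 flowering timepoints each, sampled every
    3 days from day 18, triplicate arrays with one lost replicate, bolting
    at days 34 and 40.
    """

    n_genes: int = 2000
    accessions: tuple[str, ...] = ("acc1", "acc2")
    vegetative_timepoints: tuple[int, ...] = (6, 8)
    flowering_timepoints: int = 2
    replicates: int = 3
    sampling_interval: int = 3
    first_sample_day: int = 18
    bolting_days: tuple[int, ...] = (34, 40)
    # fraction of per-gene variance contributed by each planted term;
    # the residual absorbs the remainder
    variance_fractions: dict = field(
        default_factory=lambda: {
            "accession": 0.30,
            "flowering": 0.30,
            "environment": 0.10,
            "cluster": 0.10,
        }
    )
    env_tmax_share: float = 0.5  # of the environment fraction; rest is precipitation
    n_clusters: int = 5
    null_fraction: float = 0.30
    never_expressed_fraction: float = 0.33
    detection_flip_rate: float = 0.01
    drop_one_replicate: bool = True
    baseline_mean: float = 9.5
    baseline_sd: float = 2.5
    absent_baseline_mean: float = 4.0
    absent_baseline_sd: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 1 or self.replicates < 1 or self.n_clusters < 1:
            raise ValidationError("counts must be positive")
        if len(self.vegetative_timepoints) != len(self.accessions):
            raise ValidationError("one vegetative timepoint count per accession required")
        if len(self.bolting_days) != len(self.accessions):
            raise ValidationError("one bolting day per accession required")
        if self.flowering_timepoints < 0 or min(self.vegetative_timepoints) < 1:
            raise ValidationError("timepoint counts must be positive")
        unknown = set(self.variance_fractions) - set(EFFECT_FACTORS)
        if unknown:
            raise ValidationError(f"unknown variance fraction keys: {sorted(unknown)}")
        fr = [self.variance_fractions.get(k, 0.0) for k in EFFECT_FACTORS]
        if any(v < 0 for v in fr):
            raise ValidationError("variance fractions must be >= 0")
        if sum(fr) > 1.0 + 1e-12:
            raise ValidationError("variance fractions sum to more than 1")
        for name in ("null_fraction", "never_expressed_fraction", "detection_flip_rate",
                     "env_tmax_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")

    @property
    def residual_fraction(self) -> float:
        return 1.0 - sum(self.variance_fractions.get(k, 0.0) for k in EFFECT_FACTORS)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["accessions"] = list(self.accessions)
        d["vegetative_timepoints"] = list(self.vegetative_timepoints)
        d["bolting_days"] = list(self.bolting_days)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("accessions", "vegetative_timepoints", "bolting_days"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth: per-gene effects and realized variance fractions."""

    effects: pd.DataFrame  # index gene id; accession_effect, flowering_effect,
    # tmax_coef, precip_coef, cluster (0 = none), is_null, present
    realized_fractions: dict  # factor -> realized share of total variance

    @property
    def cluster_labels(self) -> pd.Series:
        return self.effects["cluster"]

    @property
    def present_genes(self) -> list[str]:
        return list(self.effects.index[self.effects["present"]])


@dataclass(frozen=True)
class SimulatedExperiment:
    matrix: ExpressionMatrix
    flags: DetectionFlags
    samples: SampleTable
    environment: EnvironmentSeries
    phenotypes: PhenotypeTable
    truth: SyntheticTruth


def simulate_environment(
    n_days: int,
    seed: int | np.random.Generator | None = 0,
    *,
    tmin_mean: float = 8.7,
    tmax_mean: float = 23.7,
    temp_sd: float = 2.5,
    ar_coef: float = 0.5,
    rain_prob: float = 8.0 / 30.0,
    rain_range: tuple[float, float] = (2.5, 31.8),
    start_day: int = 1,
) -> EnvironmentSeries:
    """Simulate a daily weather series.

    Minimum temperature follows an AR(1) process with stationary mean
    `tmin_mean`; the tmax-tmin spread follows an independent AR(1) around
    `tmax_mean - tmin_mean`, floored at 0.5 deg C so tmax > tmin always.
    Rain falls on a Bernoulli(`rain_prob`) subset of days with amounts
    uniform over `rain_range` mm.
    """
    if n_days < 1:
        raise ValidationError("n_days must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    innov_sd = temp_sd * np.sqrt(1.0 - ar_coef**2)

    def ar1(mean: float) -> np.ndarray:
        x = np.empty(n_days)
        x[0] = rng.normal(mean, temp_sd)
        for t in range(1, n_days):
            x[t] = mean + ar_coef * (x[t - 1] - mean) + rng.normal(0.0, innov_sd)
        return x

    tmin = ar1(tmin_mean)
    spread = np.clip(ar1(tmax_mean - tmin_mean), 0.5, None)
    rain = rng.random(n_days) < rain_prob
    amounts = rng.uniform(*rain_range, size=n_days)
    df = pd.DataFrame(
        {
            "day": np.arange(start_day, start_day + n_days),
            "tmax": tmin + spread,
            "tmin": tmin,
            "precipitation": np.where(rain, amounts, 0.0),
        }
    )
    return EnvironmentSeries(df)


def _build_design(config: SimulationConfig) -> pd.DataFrame:
    """One row per array: sample_id, accession, day, flowering_status, replicate."""
    rows = []
    for a_idx, acc in enumerate(config.accessions):
        n_veg = config.vegetative_timepoints[a_idx]
        n_tp = n_veg + config.flowering_timepoints
        for t in range(n_tp):
            day = config.first_sample_day + t * config.sampling_interval
            status = "vegetative" if t < n_veg else "flowering"
            for rep in range(1, config.replicates + 1):
                rows.append(
                    {
                        "sample_id": f"{acc}_d{day:02d}_r{rep}",
                        "accession": acc,
                        "day": day,
                        "flowering_status": status,
                        "replicate": rep,
                        "timepoint": t,
                    }
                )
    df = pd.DataFrame(rows)
    if config.drop_one_replicate and config.replicates > 1:
        # mirrors the lost late-vegetative replicate of the second accession
        acc = config.accessions[-1]
        n_veg = config.vegetative_timepoints[-1]
        tp = min(5, n_veg - 1)
        mask = (df["accession"] == acc) & (df["timepoint"] == tp) & (df["replicate"] == config.replicates)
        df = df.loc[~mask]
    return df.drop(columns="timepoint").reset_index(drop=True)


def _cluster_templates(days: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k orthonormal smooth temporal templates evaluated at `days` (len-n rows).

    Random rotations of a natural-spline basis, centered and orthonormalized
    across the realized samples, then scaled to unit population variance.
    """
    df_basis = max(3, k)
    basis = natural_spline_basis(days.astype(float), df_basis)
    basis = basis - basis.mean(axis=0)
    rot = rng.normal(size=(basis.shape[1], k))
    raw = basis @ rot
    q, _ = np.linalg.qr(raw)
    q = q[:, :k]
    # unit variance across samples so the planted fraction is exact
    return q * np.sqrt(len(days))


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Draw one full synthetic experiment plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    design = _build_design(config)
    n_samples = len(design)
    last_day = int(design["day"].max())
    env = simulate_environment(last_day, rng)
    env_by_day = env.data.set_index("day")

    n = config.n_genes
    genes = [f"G{i:05d}" for i in range(1, n + 1)]

    # --- baselines and detection truth -------------------------------------
    n_absent = int(round(config.never_expressed_fraction * n))
    absent_idx = rng.choice(n, size=n_absent, replace=False)
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    baseline[absent_idx] = rng.normal(
        config.absent_baseline_mean, config.absent_baseline_sd, size=n_absent
    )
    order = np.argsort(baseline, kind="stable")
    present = np.ones(n, dtype=bool)
    if n_absent > 0:
        present[order[:n_absent]] = False

    # --- per-sample covariate columns, scaled to unit variance -------------
    def std(col: np.ndarray) -> np.ndarray:
        sd = col.std()
        return (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)

    acc_col = std((design["accession"] == config.accessions[-1]).to_numpy(float))
    flow_col = std((design["flowering_status"] == "flowering").to_numpy(float))
    tmax_col = std(env_by_day.loc[design["day"], "tmax"].to_numpy())
    ppt_col = std(env_by_day.loc[design["day"], "precipitation"].to_numpy())

    fr = {k: config.variance_fractions.get(k, 0.0) for k in EFFECT_FACTORS}
    v_resid = config.residual_fraction

    # --- per-gene effects ---------------------------------------------------
    is_null = rng.random(n) < config.null_fraction
    # independent signs so cross-covariances cancel over genes
    signs = rng.choice([-1.0, 1.0], size=(n, 4))
    a = np.where(is_null, 0.0, signs[:, 0] * np.sqrt(fr["accession"]))
    f = np.where(is_null, 0.0, signs[:, 1] * np.sqrt(fr["flowering"]))
    c_t = np.where(is_null, 0.0, signs[:, 2] * np.sqrt(fr["environment"] * config.env_tmax_share))
    c_p = np.where(
        is_null, 0.0, signs[:, 3] * np.sqrt(fr["environment"] * (1.0 - config.env_tmax_share))
    )

    labels = np.zeros(n, dtype=int)  # 0 = no cluster
    non_null = np.flatnonzero(~is_null)
    if fr["cluster"] > 0 and non_null.size:
        labels[non_null] = rng.integers(1, config.n_clusters + 1, size=non_null.size)

    templates = _cluster_templates(design["day"].to_numpy(), config.n_clusters, rng)
    cluster_comp = np.zeros((n, n_samples))
    mask = labels > 0
    if mask.any():
        cluster_comp[mask] = np.sqrt(fr["cluster"]) * templates[:, labels[mask] - 1].T

    # --- assemble the matrix ------------------------------------------------
    systematic = (
        baseline[:, None]
        + np.outer(a, acc_col)
        + np.outer(f, flow_col)
        + np.outer(c_t, tmax_col)
        + np.outer(c_p, ppt_col)
        + cluster_comp
    )
    noise = rng.normal(0.0, np.sqrt(v_resid), size=(n, n_samples))
    values = systematic + noise

    matrix = ExpressionMatrix(
        pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=design["sample_id"])
    )

    # --- detection flags ----------------------------------------------------
    flag_values = np.repeat(present[:, None], n_samples, axis=1)
    if config.detection_flip_rate > 0:
        flips = rng.random((n, n_samples)) < config.detection_flip_rate
        flag_values = flag_values ^ flips
    flags = DetectionFlags(
        pd.DataFrame(flag_values, index=pd.Index(genes, name="gene_id"), columns=design["sample_id"])
    )

    # --- phenotypes: rosettes grow with age, replicate-level noise ----------
    day = design["day"].to_numpy(float)
    rln = np.maximum(2, np.round(0.5 * day - 4.0 + rng.normal(0.0, 1.0, n_samples)))
    rd = np.maximum(0.5, 0.30 * day - 2.0 + rng.normal(0.0, 0.5, n_samples))
    pheno = PhenotypeTable(
        pd.DataFrame({"sample_id": design["sample_id"], "rln": rln, "rd": rd})
    )

    # --- realized fractions (population variance of each planted component) -
    comps = {
        "accession": np.outer(a, acc_col),
        "flowering": np.outer(f, flow_col),
        "environment": np.outer(c_t, tmax_col) + np.outer(c_p, ppt_col),
        "cluster": cluster_comp,
        "residual": noise,
    }
    per_factor = {k: float(v.var(axis=1).mean()) for k, v in comps.items()}
    total = sum(per_factor.values())
    realized = {k: v / total for k, v in per_factor.items()}

    effects = pd.DataFrame(
        {
            "accession_effect": a,
            "flowering_effect": f,
            "tmax_coef": c_t,
            "precip_coef": c_p,
            "cluster": labels,
            "is_null": is_null,
            "present": present,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    truth = SyntheticTruth(effects=effects, realized_fractions=realized)
    samples = SampleTable(design)
    return SimulatedExperiment(matrix, flags, samples, env, pheno, truth)


def synthetic_stress_sets(
    truth: SyntheticTruth,
    seed: int = 0,
    *,
    coverage: float = 0.8,
    padding: float = 1.0,
    n_random_sets: int = 2,
    random_set_size: int = 50,
) -> tuple["GeneSetCollection", dict]:
    """Stress-annotation gene sets planted on the simulated clusters.

    One set per planted cluster, containing a `coverage` fraction of its
    members plus `padding` x cluster-size random other genes (so enrichment
    is strong but not degenerate), and `n_random_sets` unrelated random
    sets. Categories alternate abiotic/biotic per cluster set; random sets
    get no category. Returns (collection, set -> category map).
    """
    from .core_data import GeneSet, GeneSetCollection

    rng = np.random.default_rng(seed)
    genes = np.array(truth.effects.index)
    labels = truth.effects["cluster"].to_numpy()
    sets = []
    categories: dict = {}
    for k in sorted(set(labels) - {0}):
        members = genes[labels == k]
        n_core = max(1, int(round(coverage * len(members))))
        core = rng.choice(members, size=n_core, replace=False)
        pool = genes[labels != k]
        n_pad = min(len(pool), int(round(padding * len(members))))
        pad = rng.choice(pool, size=n_pad, replace=False)
        name = f"stress_cluster{k}"
        categories[name] = "abiotic" if k % 2 == 1 else "biotic"
        sets.append(
            GeneSet(name=name, genes=tuple(np.concatenate([core, pad])),
                    description=f"planted on cluster {k}")
        )
    for j in range(n_random_sets):
        pick = rng.choice(genes, size=min(random_set_size, len(genes)), replace=False)
        sets.append(GeneSet(name=f"random{j + 1}", genes=tuple(pick), description="random background set"))
    return GeneSetCollection(tuple(sets)), categories
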