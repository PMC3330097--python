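"""Co-expression clustering and gene-set enrichment.

The clustering substrate is the per-(accession, day) replicate-mean profile
of each significantly time-varying gene, standardized per gene, so Euclidean
distance is (up to scale) correlation distance. K-means partitions the
profiles; cluster number is chosen by the silhouette stopping rule: the
smallest K at which the worst cluster's mean silhouette drops to <= 0 and
stays there for a persistence window of successive K values. Each cluster
can then be decomposed with environmental PVCA and tested for
over-representation of stress/GO gene sets with the upper-tail
hypergeometric probability, BH-corrected across all cluster x set pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform, pdist
from sklearn.cluster import KMeans

from .core_data import ExpressionMatrix, GeneSetCollection, SampleTable, ValidationError
from .pvca import VarianceDecomposition, pvca_environmental, ENVIRONMENTAL_MODEL
from .timecourse import bh_fdr

logger = logging.getLogger(__name__)

__all__ = [
    "Clustering",
    "profile_matrix",
    "kmeans_cluster",
    "silhouette_widths",
    "select_cluster_number",
    "cluster_pvca",
    "proportion_bin",
    "hypergeom_enrichment",
    "stress_annotation",
]

#: Fig-5-style colour bins for variance proportions
_BIN_EDGES = (0.25, 0.50, 0.75)
_BIN_LABELS = ("<25%", "25-50%", "50-75%", ">75%")


@dataclass(frozen=True)
class Clustering:
    """K-means assignment with silhouette diagnostics."""

    labels: pd.Series  # gene id -> cluster label in 1..K
    K: int
    silhouettes: pd.Series  # per-gene s(i) in [-1, 1]
    inertia: float

    def __post_init__(self) -> None:
        lab = set(self.labels)
        if not lab <= set(range(1, self.K + 1)):
            raise ValidationError("cluster labels outside 1..K")
        if len(lab) < self.K:
            raise ValidationError("empty cluster in assignment")

    def cluster_mean_silhouette(self) -> pd.Series:
        return self.silhouettes.groupby(self.labels).mean()

    @property
    def worst_cluster_silhouette(self) -> float:
        return float(self.cluster_mean_silhouette().min())

    def members(self, k: int) -> list[str]:
        return list(self.labels.index[self.labels == k])


def profile_matrix(
    matrix: ExpressionMatrix, samples: SampleTable, gene_list=None
) -> pd.DataFrame:
    """Per-gene vector of replicate-mean expression per (accession, day),
    standardized to mean 0 / sd 1 per gene. Zero-variance genes are dropped
    (their ids are logged)."""
    genes = list(gene_list) if gene_list is not None else matrix.gene_ids
    sub = matrix.subset(genes=genes)
    design = samples.data.set_index("sample_id").loc[sub.sample_ids]
    cols = pd.MultiIndex.from_frame(design[["accession", "day"]])
    means = sub.data.T.groupby(cols).mean().T  # genes x (accession, day)
    sd = means.std(axis=1, ddof=0)
    flat = sd <= 1e-12
    if flat.any():
        logger.info("dropping %d zero-variance genes: %s", flat.sum(), list(means.index[flat])[:10])
        means = means.loc[~flat]
        sd = sd[~flat]
    return means.sub(means.mean(axis=1), axis=0).div(sd, axis=0)


def kmeans_cluster(
    profiles: pd.DataFrame, K: int, n_restarts: int = 10, seed: int = 0
) -> Clustering:
    """Best-of-restarts K-means (within-cluster sum of squares criterion)."""
    if K < 2:
        raise ValidationError("K must be >= 2")
    if K > len(profiles):
        raise ValidationError(f"K={K} exceeds the number of genes ({len(profiles)})")
    km = KMeans(n_clusters=K, n_init=n_restarts, random_state=int(seed) % (2**32))
    raw = km.fit_predict(profiles.to_numpy())
    labels = pd.Series(raw + 1, index=profiles.index, name="cluster")
    sil = silhouette_widths(profiles, labels)
    return Clustering(labels=labels, K=K, silhouettes=sil, inertia=float(km.inertia_))


def silhouette_widths(profiles: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Silhouette width s(i) = (b - a)/max(a, b) with Euclidean distances.

    a(i): mean distance to the other members of i's cluster; b(i): smallest
    mean distance to another cluster. Members of singleton clusters get 0.
    """
    lab = np.asarray(labels.loc[profiles.index])
    uniq = np.unique(lab)
    if uniq.size < 2:
        raise ValidationError("silhouettes need at least 2 clusters")
    d = squareform(pdist(profiles.to_numpy()))
    n = len(lab)
    sizes = {k: int((lab == k).sum()) for k in uniq}
    # mean distance from every point to every cluster
    mean_to = np.column_stack([d[:, lab == k].sum(axis=1) / sizes[k] for k in uniq])
    col_of = {k: j for j, k in enumerate(uniq)}
    s = np.zeros(n)
    for i in range(n):
        k = lab[i]
        if sizes[k] == 1:
            continue
        a = d[i, lab == k].sum() / (sizes[k] - 1)
        others = [mean_to[i, col_of[m]] for m in uniq if m != k]
        b = min(others)
        denom = max(a, b)
        s[i] = (b - a) / denom if denom > 0 else 0.0
    return pd.Series(s, index=profiles.index, name="silhouette")


def select_cluster_number(
    profiles: pd.DataFrame,
    K_min: int = 2,
    K_max: int = 30,
    persistence_window: int = 3,
    seed: int = 0,
    n_restarts: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Silhouette stopping rule for the number of clusters.

    Scanning K upward, K* is the smallest K whose worst-cluster mean
    silhouette is <= 0 at K and at every one of the next
    `persistence_window` values of K. If the rule never fires by K_max,
    K_max is returned with a warning. Also returns the per-K diagnostics
    (worst-cluster and overall mean silhouette).
    """
    if K_min < 2:
        raise ValidationError("K_min must be >= 2")
    if K_max > len(profiles) // 2:
        raise ValidationError("K_max must be at most n_genes / 2")
    rows = []
    worst = {}
    for K in range(K_min, K_max + 1):
        cl = kmeans_cluster(profiles, K, n_restarts=n_restarts, seed=seed)
        worst[K] = cl.worst_cluster_silhouette
        rows.append(
            {
                "K": K,
                "worst_cluster_silhouette": worst[K],
                "mean_silhouette": float(cl.silhouettes.mean()),
            }
        )
    diagnostics = pd.DataFrame(rows)
    for K in range(K_min, K_max + 1):
        window = range(K, min(K + persistence_window, K_max) + 1)
        if all(worst[j] <= 0 for j in window):
            return K, diagnostics
    warnings.warn(f"silhouette stopping rule never fired by K_max={K_max}; returning K_max")
    return K_max, diagnostics


def proportion_bin(p: float) -> str:
    """Map a variance proportion to its Fig-5-style colour bin."""
    for edge, label in zip(_BIN_EDGES, _BIN_LABELS):
        if p < edge:
            return label
    return _BIN_LABELS[-1]


def cluster_pvca(
    matrix: ExpressionMatrix,
    clustering: Clustering,
    design: pd.DataFrame,
    env_model: str = ENVIRONMENTAL_MODEL,
    *,
    min_cluster_size: int = 5,
    **pvca_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Environmental PVCA per cluster (on each cluster's member submatrix).

    Returns a long table (cluster, factor, proportion, bin) and the raw
    per-cluster decompositions. Clusters below `min_cluster_size` are
    skipped and flagged with a NaN row.
    """
    rows = []
    decomps: dict[int, VarianceDecomposition | None] = {}
    for k in range(1, clustering.K + 1):
        members = clustering.members(k)
        if len(members) < min_cluster_size:
            decomps[k] = None
            rows.append({"cluster": k, "factor": "(skipped)", "proportion": np.nan, "bin": "skipped"})
            continue
        sub = matrix.subset(genes=members)
        decomp = pvca_environmental(sub, design, env_model, **pvca_kwargs)
        decomps[k] = decomp
        for factor, prop in decomp.proportions.items():
            rows.append(
                {"cluster": k, "factor": factor, "proportion": prop, "bin": proportion_bin(prop)}
            )
    return pd.DataFrame(rows), decomps


def hypergeom_enrichment(member_genes, gene_set, universe) -> tuple[int, float]:
    """Upper-tail hypergeometric probability of >= k set members in a cluster.

    The gene set is intersected with the universe before testing; member
    genes must already lie inside the universe. Returns (overlap, p).
    """
    universe = set(universe)
    members = set(member_genes)
    if not members <= universe:
        raise ValidationError("cluster members must be a subset of the universe")
    in_set = set(gene_set) & universe
    if not universe or not in_set:
        warnings.warn("empty universe or gene set after intersection; p = 1")
        return 0, 1.0
    k = len(members & in_set)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(in_set), len(members)))
    return k, min(p, 1.0)


def stress_annotation(
    clustering: Clustering,
    gene_sets: GeneSetCollection,
    universe=None,
    alpha: float = 0.05,
    *,
    correction: str = "bh",
    category_map: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Test every (cluster, gene set) pair for over-representation.

    `universe` defaults to the clustered genes (the conservative
    background). `correction='bh'` flags pairs at q <= alpha after BH across
    all pairs; `correction='raw'` uses unadjusted p <= alpha. With a
    set -> {'abiotic', 'biotic'} `category_map`, per-cluster enrichment is
    summarized into both / abiotic-only / biotic-only counts.

    Returns (long results table, binary cluster x set matrix, summary dict).
    """
    if universe is None:
        universe = list(clustering.labels.index)
    universe = list(universe)
    rows = []
    for k in range(1, clustering.K + 1):
        members = clustering.members(k)
        for gs in gene_sets:
            kk, p = hypergeom_enrichment(members, gs.genes, universe)
            rows.append(
                {
                    "cluster": k,
                    "set": gs.name,
                    "overlap": kk,
                    "cluster_size": len(members),
                    "set_size": len(set(gs.genes) & set(universe)),
                    "universe_size": len(universe),
                    "p": p,
                }
            )
    table = pd.DataFrame(rows)
    table["q"] = bh_fdr(table["p"].to_numpy())
    if correction == "bh":
        table["enriched"] = table["q"] <= alpha
    elif correction == "raw":
        table["enriched"] = table["p"] <= alpha
    else:
        raise ValidationError(f"unknown correction {correction!r}")

    binary = (
        table.pivot(index="cluster", columns="set", values="enriched")
        .astype(int)
        .sort_index()
    )

    summary: dict = {}
    if category_map is not None:
        counts = {"both": 0, "abiotic_only": 0, "biotic_only": 0, "none": 0}
        for k, grp in table.groupby("cluster"):
            cats = {category_map.get(s) for s in grp.loc[grp["enriched"], "set"]} - {None}
            if {"abiotic", "biotic"} <= cats:
                counts["both"] += 1
            elif cats == {"abiotic"}:
                counts["abiotic_only"] += 1
            elif cats == {"biotic"}:
                counts["biotic_only"] += 1
            else:
                counts["none"] += 1
        summary = counts
    return table, binary, summary
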