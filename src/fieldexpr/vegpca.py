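"""Vegetative-stage PCA and expression-environment regression.

After restricting to pre-bolting samples and to genes significantly
time-varying in *both* accessions, a PCA of the submatrix yields axes whose
scores are regressed on weather and development:

    PC = TMAX + PPT + RLN + RD + age + error

by ordinary least squares per axis, with variance-inflation-factor (VIF)
screening for collinearity and BH correction across the tested axes'
covariate p-values. Minimum temperature is excluded from the default model
because it tracks maximum temperature too closely; it can be re-included.

Genes driving an axis are picked from the extreme tails of the loading
distribution (ceil(alpha * n) per tail), and co-regulated genes are found by
template matching: all genes whose per-(accession, day) mean profile has
absolute Pearson correlation with a chosen template gene's profile at or
above a threshold. The threshold can be given on the r scale (default) or
as an r-squared to convert.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .core_data import ExpressionMatrix, SampleTable, ValidationError
from .pvca import PCModel, fit_pca
from .timecourse import bh_fdr

__all__ = [
    "RegressionFit",
    "TemplateMatch",
    "DEFAULT_COVARIATES",
    "vegetative_subset",
    "pc_trajectories",
    "regress_pc_on_covariates",
    "extreme_loading_genes",
    "gene_pc_correlation",
    "template_match",
]

#: tmin is dropped by default (collinear with tmax); `day` is plant age
DEFAULT_COVARIATES = ("tmax", "precipitation", "rln", "rd", "day")


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of one PC axis on environment/development covariates."""

    axis: str
    table: pd.DataFrame  # per covariate: beta, se, p, vif, significant
    adjusted_r2: float
    n_obs: int
    n_dropped: int  # rows lost to missing covariates


@dataclass(frozen=True)
class TemplateMatch:
    template: str
    threshold: float  # on the |r| scale
    matches: pd.DataFrame  # gene_id, r (signed), sorted by |r| descending

    def __post_init__(self) -> None:
        if len(self.matches) and (self.matches["r"].abs() < self.threshold - 1e-12).any():
            raise ValidationError("match below threshold")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.matches["gene_id"])


def vegetative_subset(
    matrix: ExpressionMatrix,
    samples: SampleTable,
    sig_genes_by_accession: dict,
) -> tuple[ExpressionMatrix, SampleTable]:
    """Restrict to vegetative samples and genes significant in every accession.

    `sig_genes_by_accession` maps accession name to its screened gene list
    (e.g. from the spline test at q < 0.05); the gene axis of the result is
    their intersection, in matrix order.
    """
    lists = list(sig_genes_by_accession.values())
    if not lists:
        raise ValidationError("no significant gene lists supplied")
    common = set(lists[0]).intersection(*map(set, lists[1:]))
    genes = [g for g in matrix.gene_ids if g in common]
    if not genes:
        raise ValidationError("intersection of significant gene lists is empty")
    veg = samples.data[samples.data["flowering_status"] == "vegetative"]
    sub = matrix.subset(genes=genes, samples=list(veg["sample_id"]))
    return sub, SampleTable(veg.reset_index(drop=True))


def pc_trajectories(pcm: PCModel, samples: SampleTable, axes=("PC1", "PC2")) -> pd.DataFrame:
    """Mean and standard error of replicate PC scores per (accession, day).

    SE is reported as NaN for single-replicate groups.
    """
    design = samples.data.set_index("sample_id").loc[pcm.scores.index]
    out = []
    for axis in axes:
        sc = pcm.scores[axis]
        grp = sc.groupby([design["accession"], design["day"]])
        agg = grp.agg(["mean", "sem", "count"])
        agg.columns = ["mean", "se", "n"]
        agg.loc[agg["n"] == 1, "se"] = np.nan
        agg = agg.reset_index()
        agg.insert(0, "axis", axis)
        out.append(agg)
    return pd.concat(out, ignore_index=True)


def _vif(x: np.ndarray) -> np.ndarray:
    """VIF_j = 1/(1 - R2_j) from regressing covariate j on the others."""
    n, k = x.shape
    out = np.empty(k)
    for j in range(k):
        yj = x[:, j]
        others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        tss = ((yj - yj.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / tss if tss > 0 else 0.0
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def regress_pc_on_covariates(
    pcm: PCModel,
    design: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
    axes=("PC1", "PC2", "PC3", "PC4", "PC5"),
    *,
    vif_threshold: float = 10.0,
    drop_high_vif: bool = False,
    fdr: float = 0.05,
) -> dict:
    """OLS of each PC axis on the covariates, with VIF screening and BH FDR.

    Rows with missing covariates are dropped (count recorded). Covariates
    with VIF >= `vif_threshold` are flagged, and removed from the fit when
    `drop_high_vif` is set. BH correction runs across all covariate p-values
    of all requested axes; `significant` flags q <= fdr.

    Returns axis -> RegressionFit.
    """
    design = design.set_index("sample_id").loc[pcm.scores.index]
    covs = list(covariates)
    missing = [c for c in covs if c not in design.columns]
    if missing:
        raise ValidationError(f"covariates not in design: {missing}")
    sub = design[covs].astype(float)
    ok = sub.notna().all(axis=1)
    n_dropped = int((~ok).sum())
    sub = sub[ok]
    if len(sub) < len(covs) + 2:
        raise ValidationError("fewer complete samples than covariates + intercept")

    x = sub.to_numpy()
    vif = _vif(x)
    kept = covs
    if drop_high_vif and (vif >= vif_threshold).any():
        kept = [c for c, v in zip(covs, vif) if v < vif_threshold]
        x = sub[kept].to_numpy()
        vif = _vif(x) if len(kept) > 1 else np.ones(len(kept))
    flagged = dict(zip(kept, vif))

    fits = {}
    all_p = []
    for axis in axes:
        y = pcm.scores.loc[sub.index, axis].to_numpy()
        model = sm.OLS(y, sm.add_constant(x)).fit()
        tab = pd.DataFrame(
            {
                "covariate": kept,
                "beta": model.params[1:],
                "se": model.bse[1:],
                "p": model.pvalues[1:],
                "vif": [flagged[c] for c in kept],
            }
        )
        tab["high_vif"] = tab["vif"] >= vif_threshold
        fits[axis] = RegressionFit(
            axis=axis,
            table=tab,
            adjusted_r2=float(model.rsquared_adj),
            n_obs=int(model.nobs),
            n_dropped=n_dropped,
        )
        all_p.append(tab["p"].to_numpy())
    q = bh_fdr(np.concatenate(all_p))
    offset = 0
    for axis in axes:
        tab = fits[axis].table
        tab["q"] = q[offset : offset + len(tab)]
        tab["significant"] = tab["q"] <= fdr
        offset += len(tab)
    return fits


def extreme_loading_genes(loadings_axis: pd.Series, alpha_per_tail: float = 0.025) -> list[str]:
    """Genes in the upper and lower `alpha_per_tail` loading tails.

    Takes ceil(alpha * n) genes per tail (so n = 8954, alpha = 0.025 gives
    224 + 224 = 448). Ties broken by stable rank order.
    """
    if not 0.0 < alpha_per_tail < 0.5:
        raise ValidationError("alpha_per_tail must lie in (0, 0.5)")
    n = len(loadings_axis)
    k = math.ceil(alpha_per_tail * n)
    order = loadings_axis.sort_values(kind="stable")
    low = list(order.index[:k])
    high = list(order.index[-k:][::-1])
    return high + [g for g in low if g not in high]


def gene_pc_correlation(
    matrix: ExpressionMatrix, pcm: PCModel, gene: str, axis: str
) -> dict:
    """Pearson correlation of one gene's per-sample expression with PC scores.

    Returns {'r', 'r2', 'p'}; all NaN for a zero-variance gene.
    """
    if gene not in matrix.data.index:
        raise ValidationError(f"gene {gene!r} not in matrix")
    y = matrix.data.loc[gene, pcm.scores.index].to_numpy(dtype=float)
    s = pcm.scores[axis].to_numpy()
    if np.std(y) <= 1e-12 or np.std(s) <= 1e-12:
        return {"r": np.nan, "r2": np.nan, "p": np.nan}
    r, p = stats.pearsonr(y, s)
    return {"r": float(r), "r2": float(r**2), "p": float(p)}


def template_match(
    profiles: pd.DataFrame,
    template_gene: str,
    min_abs_r: float = 0.7,
    *,
    threshold_is_r2: bool = False,
) -> TemplateMatch:
    """All genes whose mean profile matches a template gene's profile.

    `profiles` holds per-(accession, day) mean expression, one row per gene.
    A gene matches when |Pearson r| with the template row is >= the
    threshold; anti-correlated genes match too, with r reported signed. When
    `threshold_is_r2` is set the supplied value is an r-squared and the
    comparison runs at sqrt of it (0.47 -> |r| >= 0.6856).
    """
    thr = math.sqrt(min_abs_r) if threshold_is_r2 else float(min_abs_r)
    if not 0.0 < thr <= 1.0:
        raise ValidationError("threshold must lie in (0, 1]")
    if template_gene not in profiles.index:
        raise ValidationError(f"template gene {template_gene!r} not in profiles")
    x = profiles.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(xc, axis=1)
    t = xc[profiles.index.get_loc(template_gene)]
    tnorm = np.linalg.norm(t)
    if tnorm <= 1e-12:
        raise ValidationError("template profile has zero variance")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ t) / (norm * tnorm)
    r = np.where(norm <= 1e-12, np.nan, np.clip(r, -1.0, 1.0))
    hit = np.abs(r) >= thr - 1e-12
    hit &= np.isfinite(r)
    matches = pd.DataFrame({"gene_id": profiles.index[hit], "r": r[hit]})
    matches = matches.reindex(matches["r"].abs().sort_values(ascending=False).index).reset_index(drop=True)
    return TemplateMatch(template=template_gene, threshold=thr, matches=matches)
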