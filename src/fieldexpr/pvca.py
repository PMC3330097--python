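"""Principal variance components analysis (PVCA).

PVCA first reduces the expression matrix by PCA, then fits a
variance-components (random-effects intercept) model to each retained
principal component's score vector, treating every design factor —
including binned continuous covariates — as random. Per-factor variance
components are aggregated across components with eigenvalue weights,
yielding the share of total transcriptional variance attributable to each
factor (plus residual).

Two estimation backends are provided: an ANOVA-type method-of-moments
estimator (Henderson III, via sequential projection quadratic forms, valid
on unbalanced designs) and REML by bounded likelihood maximization. Negative
component estimates are truncated at zero before aggregation, the standard
PVCA convention, so reported proportions lie in [0, 1] and sum to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .core_data import ExpressionMatrix, ValidationError

__all__ = [
    "PCModel",
    "VarianceDecomposition",
    "fit_pca",
    "estimate_components",
    "pvca",
    "pvca_environmental",
    "parse_model",
    "ENVIRONMENTAL_MODEL",
]

# age + flowering status + min/max temperature + precipitation
ENVIRONMENTAL_MODEL = "day + flowering_status + tmin + tmax + precipitation"


@dataclass(frozen=True)
class PCModel:
    """PCA of a genes x samples matrix; samples are the observations."""

    loadings: pd.DataFrame  # genes x components
    scores: pd.DataFrame  # samples x components
    eigenvalues: np.ndarray  # non-increasing, >= 0
    proportions: np.ndarray  # eigenvalue share of total variance
    centered: pd.DataFrame  # the centered (and optionally scaled) matrix

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)


@dataclass(frozen=True)
class VarianceDecomposition:
    """Factor name (incl. 'residual') -> weighted share of total variance."""

    proportions: dict
    method: str = ""
    details: pd.DataFrame | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        vals = np.array(list(self.proportions.values()))
        if len(vals) and (vals < -1e-12).any():
            raise ValidationError("negative variance proportion")
        if len(vals) and abs(vals.sum() - 1.0) > 1e-8:
            raise ValidationError(f"proportions sum to {vals.sum()}, not 1")

    def as_series(self) -> pd.Series:
        return pd.Series(self.proportions, name="proportion")


def fit_pca(matrix: ExpressionMatrix, center: bool = True, scale: bool = False) -> PCModel:
    """PCA by SVD of the gene-centered matrix. Components are ordered by
    eigenvalue; a constant matrix yields all-zero eigenvalues, not an error."""
    X = matrix.data
    if X.shape[1] < 2:
        raise ValidationError("PCA needs at least 2 samples")
    vals = X.to_numpy(dtype=float)
    if center:
        vals = vals - vals.mean(axis=1, keepdims=True)
    if scale:
        sd = vals.std(axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = 1.0
        vals = vals / sd
    n = vals.shape[1]
    # samples x genes; left singular vectors live in sample space
    u, s, vt = np.linalg.svd(vals.T, full_matrices=False)
    k = min(vals.shape)
    eig = s[:k] ** 2 / (n - 1)
    total = eig.sum()
    props = eig / total if total > 0 else np.zeros_like(eig)
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u[:, :k] * s[:k], index=X.columns, columns=comp_names)
    loadings = pd.DataFrame(vt[:k].T, index=X.index, columns=comp_names)
    centered = pd.DataFrame(vals, index=X.index, columns=X.columns)
    return PCModel(loadings, scores, eig, props, centered)


# ---------------------------------------------------------------------------
# model parsing and design helpers


def parse_model(model_spec) -> list[str]:
    """'a + b + a:b' -> ['a', 'b', 'a:b'] (whitespace-insensitive)."""
    if isinstance(model_spec, str):
        terms = [t.strip() for t in model_spec.split("+")]
    else:
        terms = [str(t).strip() for t in model_spec]
    terms = [t for t in terms if t]
    if not terms:
        raise ValidationError("empty model specification")
    return terms


def _term_labels(design: pd.DataFrame, term: str) -> pd.Series:
    parts = [p.strip() for p in term.split(":")]
    missing = [p for p in parts if p not in design.columns]
    if missing:
        raise ValidationError(f"model term {term!r}: columns {missing} not in design")
    if len(parts) == 1:
        return design[parts[0]].astype(str)
    return design[parts].astype(str).agg(":".join, axis=1)


def _same_partition(a: pd.Series, b: pd.Series) -> bool:
    ca = pd.factorize(a)[0]
    cb = pd.factorize(b)[0]
    pairs = len(set(zip(ca, cb)))
    return pairs == len(set(ca)) == len(set(cb))


def _is_balanced(labels: list[pd.Series]) -> bool:
    combo = pd.concat(labels, axis=1).astype(str).agg("|".join, axis=1)
    return combo.value_counts().nunique() == 1


def _incidence(labels: pd.Series) -> np.ndarray:
    codes, _ = pd.factorize(labels)
    z = np.zeros((len(codes), codes.max() + 1))
    z[np.arange(len(codes)), codes] = 1.0
    return z


# ---------------------------------------------------------------------------
# variance-component estimation


def _mom_components(y: np.ndarray, zs: dict) -> dict:
    """Henderson III: sequential projection quadratic forms, solved against
    their expectations (linear in the variance components), truncated at 0."""
    n = len(y)
    names = list(zs)
    ones = np.ones((n, 1))
    ws = [ones]
    for name in names:
        ws.append(np.hstack([ws[-1], zs[name]]))
    projs = [w @ np.linalg.pinv(w) for w in ws]
    quads = [projs[j + 1] - projs[j] for j in range(len(names))]
    quads.append(np.eye(n) - projs[-1])  # residual

    gs = {name: z @ z.T for name, z in zs.items()}
    k = len(names)
    coef = np.zeros((k + 1, k + 1))
    ss = np.zeros(k + 1)
    for i, a in enumerate(quads):
        ss[i] = y @ a @ y
        for j, name in enumerate(names):
            coef[i, j] = np.trace(a @ gs[name])
        coef[i, k] = np.trace(a)
    est, *_ = np.linalg.lstsq(coef, ss, rcond=None)
    est = np.clip(est, 0.0, None)
    out = {name: float(est[j]) for j, name in enumerate(names)}
    out["residual"] = float(est[k])
    return out


def _reml_components(y: np.ndarray, zs: dict) -> dict:
    """REML for y = mu + sum_f Z_f u_f + e with crossed random factors,
    by bounded minimization of the restricted negative log-likelihood."""
    n = len(y)
    names = list(zs)
    gs = [z @ z.T for z in zs.values()]
    x = np.ones((n, 1))
    vy = float(np.var(y, ddof=1))
    if vy == 0:
        return {**{name: 0.0 for name in names}, "residual": 0.0}

    def nll(theta: np.ndarray) -> float:
        v = theta[-1] * np.eye(n)
        for t, g in zip(theta[:-1], gs):
            v = v + t * g
        v += 1e-10 * vy * np.eye(n)
        try:
            cho = np.linalg.cholesky(v)
        except np.linalg.LinAlgError:
            return 1e12
        logdet_v = 2.0 * np.log(np.diag(cho)).sum()
        vinv_x = np.linalg.solve(v, x)
        xtvx = x.T @ vinv_x
        vinv_y = np.linalg.solve(v, y)
        beta = (vinv_x.T @ y) / xtvx[0, 0]
        resid = y - x[:, 0] * beta[0]
        quad = resid @ np.linalg.solve(v, resid)
        return float(logdet_v + np.log(xtvx[0, 0]) + quad)

    start = _mom_components(y, zs)
    theta0 = np.array([max(start[name], 0.05 * vy) for name in names] + [max(start["residual"], 0.05 * vy)])
    bounds = [(0.0, 10.0 * vy)] * len(names) + [(1e-8 * vy, 10.0 * vy)]
    res = optimize.minimize(nll, theta0, method="L-BFGS-B", bounds=bounds)
    theta = res.x if res.success else theta0
    out = {name: float(max(t, 0.0)) for name, t in zip(names, theta[:-1])}
    out["residual"] = float(theta[-1])
    return out


def estimate_components(
    score_vector,
    design: pd.DataFrame,
    factors,
    method: str = "auto",
) -> dict:
    """Variance components for one PC score vector, all factors random.

    `factors` are term strings over design columns ('a', 'a:b'). Continuous
    covariates must be binned into categories before calling (see
    `pvca_environmental`). `method` is 'anova' (Henderson III
    method-of-moments), 'reml', or 'auto' (REML on unbalanced designs,
    method-of-moments on balanced ones). Estimates are truncated at zero.
    """
    y = np.asarray(score_vector, dtype=float)
    if len(y) != len(design):
        raise ValidationError("score vector length does not match design rows")
    factors = parse_model(factors)
    labels = {term: _term_labels(design, term) for term in factors}
    for i, a in enumerate(factors):
        for b in factors[i + 1 :]:
            if _same_partition(labels[a], labels[b]):
                raise ValidationError(f"factors {a!r} and {b!r} are confounded (identical grouping)")
    zs = {term: _incidence(lab) for term, lab in labels.items()}
    if method == "auto":
        base = [lab for term, lab in labels.items() if ":" not in term]
        method = "anova" if _is_balanced(base or list(labels.values())) else "reml"
    if method == "anova":
        return _mom_components(y, zs)
    if method == "reml":
        return _reml_components(y, zs)
    raise ValidationError(f"unknown estimation method {method!r}")


# ---------------------------------------------------------------------------
# aggregation


def _aggregate(
    comp_table: pd.DataFrame, eigenvalues: np.ndarray, weighting: str
) -> dict:
    lam = np.asarray(eigenvalues, dtype=float)
    if weighting == "pooled":
        weighted = comp_table.mul(lam, axis=0).sum(axis=0)
        total = weighted.sum()
        if total <= 0:
            raise ValidationError("all variance components are zero")
        props = weighted / total
    elif weighting == "per_pc":
        row_tot = comp_table.sum(axis=1)
        keep = row_tot > 0
        shares = comp_table.loc[keep].div(row_tot[keep], axis=0)
        w = lam[keep.to_numpy()]
        props = shares.mul(w, axis=0).sum(axis=0) / w.sum()
    else:
        raise ValidationError(f"unknown weighting {weighting!r}")
    return {k: float(v) for k, v in props.items()}


def pvca(
    matrix: ExpressionMatrix,
    design: pd.DataFrame,
    model_spec="accession + flowering_status + accession:flowering_status",
    *,
    retain_threshold: float = 1e-6,
    max_components: int | None = None,
    method: str = "auto",
    weighting: str = "per_pc",
) -> VarianceDecomposition:
    """Full PVCA: PCA, per-PC variance components, eigenvalue-weighted shares.

    Retains every component whose eigenvalue share is >= `retain_threshold`
    (optionally capped at `max_components` for speed). `weighting='pooled'`
    divides eigenvalue-weighted component sums by the weighted total;
    'per_pc' averages each component's per-PC shares with eigenvalue weights.
    """
    factors = parse_model(model_spec)
    if list(matrix.sample_ids) != list(design["sample_id"]):
        design = design.set_index("sample_id").loc[matrix.sample_ids].reset_index()
    pcm = fit_pca(matrix)
    keep = pcm.proportions >= retain_threshold
    if max_components is not None:
        keep &= np.arange(pcm.n_components) < max_components
    idx = np.flatnonzero(keep)
    if idx.size == 0:
        raise ValidationError("no principal components retained")
    rows = []
    for i in idx:
        comps = estimate_components(pcm.scores.iloc[:, i], design, factors, method=method)
        rows.append(comps)
    comp_table = pd.DataFrame(rows, index=[f"PC{i + 1}" for i in idx])
    props = _aggregate(comp_table, pcm.eigenvalues[idx], weighting)
    details = comp_table.assign(eigenvalue=pcm.eigenvalues[idx])
    return VarianceDecomposition(props, method=f"pvca/{method}/{weighting}", details=details)


def _bin_continuous(design: pd.DataFrame, terms: list[str], n_bins: int) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Discretize continuous model columns into quantile bins; returns the
    augmented design, usable terms, and terms constant in this stratum."""
    design = design.copy()
    usable, constant = [], []
    for term in terms:
        if ":" in term or design[term].dtype == object or design[term].dtype.name == "category":
            if _term_labels(design, term).nunique() < 2:
                constant.append(term)
            else:
                usable.append(term)
            continue
        col = design[term].astype(float)
        if col.nunique() < 2:
            constant.append(term)
            continue
        binned = pd.qcut(col, q=n_bins, duplicates="drop")
        if binned.nunique() < 2:
            # semi-continuous covariates (e.g. precipitation, mostly zero):
            # quantile bins collapse, so fall back to a low/high split
            lo = col.min()
            binned = pd.Series(np.where(col > lo, "high", "low"), index=col.index)
            if binned.nunique() < 2:
                constant.append(term)
                continue
        design[term + "_bin"] = binned.astype(str)
        usable.append(term + "_bin")
    return design, usable, constant


def pvca_environmental(
    matrix: ExpressionMatrix,
    design: pd.DataFrame,
    env_model: str = ENVIRONMENTAL_MODEL,
    *,
    n_bins: int = 3,
    by_accession: bool = False,
    retain_threshold: float = 1e-6,
    max_components: int | None = None,
    method: str = "auto",
    weighting: str = "per_pc",
):
    """PVCA under the environmental/developmental model
    (age + flowering status + tmin + tmax + precipitation by default).

    Continuous covariates are discretized into `n_bins` quantile bins and
    treated as random factors. A covariate constant within a stratum gets a
    zero component and a warning. With `by_accession=True` one decomposition
    is returned per accession (dict keyed by accession name).
    """
    terms = parse_model(env_model)
    if by_accession:
        out = {}
        for acc, rows in design.groupby("accession", sort=False):
            sub = matrix.subset(samples=list(rows["sample_id"]))
            out[acc] = pvca_environmental(
                sub, rows.reset_index(drop=True), env_model,
                n_bins=n_bins, by_accession=False, retain_threshold=retain_threshold,
                max_components=max_components, method=method, weighting=weighting,
            )
        return out

    binned, usable, constant = _bin_continuous(design, terms, n_bins)
    for term in constant:
        warnings.warn(f"covariate {term!r} is constant in this stratum; component set to 0")
    # binned covariates can collide into identical sample partitions (e.g. the
    # two temperature series); the later one is unidentifiable and dropped
    kept: list[str] = []
    for term in usable:
        clash = next(
            (k for k in kept if _same_partition(_term_labels(binned, k), _term_labels(binned, term))),
            None,
        )
        if clash is not None:
            warnings.warn(
                f"covariate {term!r} bins identically to {clash!r} in this stratum; "
                "component set to 0"
            )
            constant.append(term)
        else:
            kept.append(term)
    usable = kept
    if not usable:
        raise ValidationError("no usable (non-constant) factors in environmental model")
    decomp = pvca(
        matrix, binned, usable,
        retain_threshold=retain_threshold, max_components=max_components,
        method=method, weighting=weighting,
    )
    props = {t.removesuffix("_bin"): v for t, v in decomp.proportions.items()}
    for term in constant:
        props[term] = 0.0
    return VarianceDecomposition(props, method=decomp.method, details=decomp.details)
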