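"""Gene-wise significance testing across the life-cycle time series.

Two complementary screens:

* `anova_per_gene` — a fixed-effects factorial ANOVA per gene (sequential
  sums of squares in model order), giving per-term F statistics, p-values
  and Benjamini-Hochberg q-values across genes.
* `spline_timecourse_test` — a time-course test that fits a natural cubic
  spline of day to each gene and compares it to a flat (intercept-only)
  profile with an F-like statistic; significance comes from permuting the
  sample-day assignment, so no distributional assumptions are made about the
  replicate noise. Resolution of the permutation p-value is 1/(n_perm + 1).

Both are vectorized across all genes at once: the hat matrices depend only
on the design, so each model (and each permutation) costs one thin QR plus
a genes x samples matrix product.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg, stats

from ._basis import natural_spline_basis
from .core_data import ExpressionMatrix, ValidationError
from .pvca import _term_labels, parse_model

__all__ = [
    "anova_per_gene",
    "bh_fdr",
    "spline_timecourse_test",
    "select_significant",
]


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j >= i} p_(j) * m / j on the sorted p-values, mapped back
    to the input order and capped at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p-values must be one-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _onehot(labels: pd.Series) -> np.ndarray:
    codes, _ = pd.factorize(labels)
    z = np.zeros((len(codes), codes.max() + 1))
    z[np.arange(len(codes)), codes] = 1.0
    return z


def _orth(m: np.ndarray) -> np.ndarray:
    return linalg.orth(m)


def anova_per_gene(
    matrix: ExpressionMatrix,
    design: pd.DataFrame,
    model_spec: str = "accession + flowering_status + accession:flowering_status",
) -> pd.DataFrame:
    """Per-gene factorial ANOVA; returns a long table (gene_id, term, F, p, q).

    Terms enter sequentially in model order (type-I sums of squares).
    Zero-variance genes get F = 0, p = 1 by convention, so the output always
    has one row per (gene, term). Requires residual degrees of freedom.
    """
    terms = parse_model(model_spec)
    if list(matrix.sample_ids) != list(design["sample_id"]):
        design = design.set_index("sample_id").loc[matrix.sample_ids].reset_index()
    n = len(design)
    for term in terms:
        if ":" not in term and _term_labels(design, term).nunique() < 2:
            raise ValidationError(f"factor {term!r} has fewer than 2 levels")

    y = matrix.values  # genes x samples
    yc = y - y.mean(axis=1, keepdims=True)
    tss = (yc**2).sum(axis=1)

    bases = [np.ones((n, 1)) / np.sqrt(n)]
    dfs = []
    cum = np.ones((n, 1))
    prev_rank = 1
    for term in terms:
        cum = np.hstack([cum, _onehot(_term_labels(design, term))])
        q = _orth(cum)
        dfs.append(q.shape[1] - prev_rank)
        prev_rank = q.shape[1]
        bases.append(q)
    df_error = n - prev_rank
    if df_error <= 0:
        raise ValidationError("saturated model: no residual degrees of freedom")
    if any(d == 0 for d in dfs):
        bad = terms[dfs.index(0)]
        raise ValidationError(f"term {bad!r} adds no degrees of freedom (aliased)")

    fitted_ss = [((b.T @ y.T) ** 2).sum(axis=0) - (y.sum(axis=1) ** 2) / n for b in bases]
    ss_terms = [fitted_ss[j + 1] - fitted_ss[j] for j in range(len(terms))]
    ss_error = np.clip(tss - fitted_ss[-1], 0.0, None)

    rows = []
    flat = tss <= 1e-12
    mse = np.where(ss_error > 0, ss_error / df_error, np.nan)
    for term, ssj, dfj in zip(terms, ss_terms, dfs):
        with np.errstate(invalid="ignore", divide="ignore"):
            fstat = (ssj / dfj) / mse
        p = stats.f.sf(fstat, dfj, df_error)
        fstat = np.where(flat | ~np.isfinite(fstat), 0.0, fstat)
        p = np.where(flat | ~np.isfinite(p), 1.0, p)
        rows.append(
            pd.DataFrame(
                {"gene_id": matrix.gene_ids, "term": term, "F": fstat, "p": p, "q": bh_fdr(p)}
            )
        )
    return pd.concat(rows, ignore_index=True)


def spline_timecourse_test(
    matrix: ExpressionMatrix,
    design: pd.DataFrame,
    df: int = 3,
    n_perm: int = 199,
    seed: int = 0,
) -> pd.DataFrame:
    """Spline time-course test: smooth-in-day vs flat profile, permutation null.

    The alternative fits a natural cubic spline of day with `df` basis
    columns (knots at interior day quantiles); the statistic is
    F = ((RSS0 - RSS1)/df) / (RSS1/(n - df - 1)). Day labels are permuted
    across samples (shared permutations; under the null each gene's p-value
    is exactly valid by exchangeability). Zero-variance genes get p = 1.

    Returns a table (gene_id, F, p, q).
    """
    if list(matrix.sample_ids) != list(design["sample_id"]):
        design = design.set_index("sample_id").loc[matrix.sample_ids].reset_index()
    days = design["day"].to_numpy(dtype=float)
    distinct = np.unique(days).size
    if distinct < df + 2:
        raise ValidationError(
            f"only {distinct} distinct days; spline df={df} needs at least {df + 2} — use a smaller df"
        )
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    n = len(days)
    df_error = n - df - 1
    if df_error <= 0:
        raise ValidationError("not enough samples for the requested spline df")

    y = matrix.values
    yt = y.T  # samples x genes
    col_mean = yt.mean(axis=0)
    rss0 = ((yt - col_mean) ** 2).sum(axis=0)
    basis = natural_spline_basis(days, df)

    def fstat(order: np.ndarray) -> np.ndarray:
        q = _orth(np.hstack([np.ones((n, 1)), basis[order]]))
        fit = (q.T @ yt) ** 2
        explained = fit.sum(axis=0) - n * col_mean**2
        rss1 = np.clip(rss0 - explained, 0.0, None)
        with np.errstate(invalid="ignore", divide="ignore"):
            return ((rss0 - rss1) / df) / (rss1 / df_error)

    identity = np.arange(n)
    f_obs = fstat(identity)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(y.shape[0])
    for _ in range(n_perm):
        perm = rng.permutation(n)
        f_perm = fstat(perm)
        exceed += np.where(np.isfinite(f_perm) & np.isfinite(f_obs), f_perm >= f_obs, 0.0)
    p = (1.0 + exceed) / (n_perm + 1.0)

    flat = rss0 <= 1e-12
    f_obs = np.where(flat | ~np.isfinite(f_obs), 0.0, f_obs)
    p = np.where(flat, 1.0, p)
    return pd.DataFrame({"gene_id": matrix.gene_ids, "F": f_obs, "p": p, "q": bh_fdr(p)})


def select_significant(results: pd.DataFrame, q_threshold: float) -> list[str]:
    """Genes whose q-value is at or below the threshold, input order preserved."""
    if "q" not in results.columns:
        raise ValidationError("results table carries no q-values")
    return list(results.loc[results["q"] <= q_threshold, "gene_id"])
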