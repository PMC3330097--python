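"""Natural cubic spline basis over sampling days.

Shared by the synthetic generator (smooth cluster templates) and the
time-course test (the alternative model). Uses the truncated-power
construction with linearity constraints beyond the boundary knots: for knots
xi_1 < ... < xi_K the basis is {x, N_1, ..., N_{K-2}} with
N_k = d_k - d_{K-1}, d_k(x) = [(x - xi_k)^3_+ - (x - xi_K)^3_+] / (xi_K - xi_k),
giving df = K - 1 columns (intercept excluded).
"""

from __future__ import annotations

import numpy as np

__all__ = ["natural_spline_basis"]


def natural_spline_basis(x: np.ndarray, df: int) -> np.ndarray:
    """Evaluate a natural cubic spline basis with `df` columns (no intercept).

    Knots sit at evenly spaced quantiles of the distinct values of `x`
    (boundary knots at min and max). Requires at least df + 1 distinct values.
    """
    x = np.asarray(x, dtype=float)
    if df < 1:
        raise ValueError("spline df must be >= 1")
    distinct = np.unique(x)
    if distinct.size < df + 1:
        raise ValueError(
            f"need at least {df + 1} distinct x values for df={df}; "
            f"got {distinct.size} — reduce df"
        )
    knots = np.quantile(distinct, np.linspace(0.0, 1.0, df + 1))
    knots = np.unique(knots)
    if knots.size < df + 1:
        raise ValueError("degenerate knot sequence; reduce df")

    def d(k: int) -> np.ndarray:
        num = np.clip(x - knots[k], 0.0, None) ** 3 - np.clip(x - knots[-1], 0.0, None) ** 3
        return num / (knots[-1] - knots[k])

    cols = [x]
    last = d(len(knots) - 2)
    for k in range(len(knots) - 2):
        cols.append(d(k) - last)
    return np.column_stack(cols)
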