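"""Small shared statistical helpers."""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries are excluded from the family and returned as NaN.
    """
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    if mask.any():
        q[mask] = multipletests(p[mask], method="fdr_bh")[1]
    return q


def pearson_with_pvalues(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All pairwise Pearson correlations between the columns of ``x`` with
    two-sided p-values from the t approximation on n-2 degrees of freedom.

    Zero-variance columns yield NaN correlation and NaN p against every other
    column (flagged by the caller).
    """
    from scipy import stats

    x = np.asarray(x, dtype=float)
    n, k = x.shape
    if n < 3:
        raise ValueError("need at least 3 observations for correlation testing")
    sd = x.std(axis=0, ddof=1)
    # a truly constant column can yield a tiny nonzero sd in floating point
    usable = (sd > 0) & (x.max(axis=0) > x.min(axis=0))
    if not usable.any():
        raise ValueError("all columns have zero variance")
    z = np.zeros_like(x)
    z[:, usable] = (x[:, usable] - x[:, usable].mean(axis=0)) / sd[usable]
    r = z.T @ z / (n - 1)
    r = np.clip(r, -1.0, 1.0)
    r[~usable, :] = np.nan
    r[:, ~usable] = np.nan
    np.fill_diagonal(r, np.where(usable, 1.0, np.nan))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    p[~np.isfinite(r)] = np.nan
    np.fill_diagonal(p, np.nan)
    return r, p


def geometric_mean_rows(values: np.ndarray, rows: np.ndarray) -> np.ndarray:
    """Geometric mean across the given rows of a non-negative matrix; exact 0
    whenever any selected row is 0 at that position."""
    sub = values[rows]
    if sub.shape[0] == 1:
        return sub[0].astype(float).copy()
    anyzero = np.any(sub == 0, axis=0)
    with np.errstate(divide="ignore"):
        gm = np.exp(np.mean(np.log(np.where(sub > 0, sub, 1.0)), axis=0))
    gm[anyzero] = 0.0
    return gm
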