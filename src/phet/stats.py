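"""Correlation layer: normality screening and pairwise Pearson tests.

Pearson r with a two-sided p-value from t = r sqrt((n-2)/(1-r^2)) on n-2
degrees of freedom, significance at alpha = .05, and Shapiro-Wilk normality
screening (Royston's algorithm via scipy). Plots with a missing value in
either member of a pair are dropped pairwise, so diversity correlations keep
their full n even when SES/NRI is undefined for some plots. No
multiple-testing correction by default; Holm adjustment is available as an
opt-in flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "pearson",
    "shapiro_wilk",
    "correlation_table",
    "normality_screen",
]

ALPHA = 0.05


@dataclass(frozen=True)
class CorrelationResult:
    var_x: str
    var_y: str
    n: int
    r: float
    p: float
    significant: bool


def pearson(x, y, *, var_x: str = "x", var_y: str = "y",
            alpha: float = ALPHA) -> CorrelationResult:
    """Pearson correlation with pairwise deletion of missing values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a zero-variance variable")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(var_x=var_x, var_y=var_y, n=int(n),
                             r=float(r), p=float(p),
                             significant=bool(p < alpha))


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk W and p-value for 3 <= n <= 5000 nonconstant data."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for constant data")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    m = pvals.size
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(1.0, running)
    return adj


def correlation_table(metrics: pd.DataFrame, pairs, *, alpha: float = ALPHA,
                      holm: bool = False) -> pd.DataFrame:
    """One Pearson test per (var_x, var_y) pair over a per-plot metrics table.

    Output rows follow the input pair order. With ``holm=True`` an extra
    ``p_holm`` column carries step-down-adjusted p-values and drives the
    significance flag instead of the raw p.
    """
    rows = []
    for var_x, var_y in pairs:
        for v in (var_x, var_y):
            if v not in metrics.columns:
                raise KeyError(f"unknown variable {v!r}")
        if var_x == var_y:
            res = CorrelationResult(var_x, var_y, int(metrics[var_x].notna().sum()),
                                    1.0, 0.0, True)
        else:
            res = pearson(metrics[var_x], metrics[var_y],
                          var_x=var_x, var_y=var_y, alpha=alpha)
        rows.append(res.__dict__)
    table = pd.DataFrame(rows, columns=["var_x", "var_y", "n", "r", "p", "significant"])
    if holm and len(table):
        table["p_holm"] = _holm(table["p"].to_numpy())
        table["significant"] = table["p_holm"] < alpha
    return table


def normality_screen(metrics: pd.DataFrame, columns=None, *,
                     alpha: float = ALPHA) -> pd.DataFrame:
    """Shapiro-Wilk screen of analysis variables; one row per column."""
    if columns is None:
        columns = [c for c in metrics.columns if pd.api.types.is_numeric_dtype(metrics[c])]
    rows = []
    for col in columns:
        w, p = shapiro_wilk(metrics[col].to_numpy())
        rows.append({"variable": col, "W": w, "p": p, "normal": p >= alpha})
    return pd.DataFrame(rows, columns=["variable", "W", "p", "normal"])
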