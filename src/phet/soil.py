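"""Per-plot soil nutrient summaries.

Availability is the arithmetic mean M of the replicate measurements
(four corner samples per plot in the study design) and heterogeneity is the
coefficient of variation CV = SD/M with the sample (n-1) standard deviation.
Both are natural-log transformed before entering the correlation layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SoilPlotSummary",
    "summarize_plot",
    "log_transform",
    "summarize_table",
    "read_soil_csv",
    "write_soil_csv",
]

NUTRIENTS = ("AN", "EP")  # alkali-hydrolyzable nitrogen, extractable phosphorus
SOIL_COLUMNS = ("plot_id", "nutrient", "replicate_index", "value_mg_per_kg")


@dataclass(frozen=True)
class SoilPlotSummary:
    mean: float        # M, mg/kg
    sd: float          # sample SD, mg/kg
    cv: float          # SD / M, dimensionless
    log_mean: float    # ln M
    log_cv: float      # ln CV; NaN when CV == 0


def summarize_plot(values) -> SoilPlotSummary:
    """Mean, sample SD, CV and their logs for one plot's replicates."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValueError("need at least 2 replicate values for a CV")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValueError("replicate values must be positive and finite")
    m = float(v.mean())
    sd = float(v.std(ddof=1))
    cv = sd / m
    return SoilPlotSummary(
        mean=m, sd=sd, cv=cv,
        log_mean=float(np.log(m)),
        log_cv=float(np.log(cv)) if cv > 0 else float("nan"),
    )


def log_transform(values) -> np.ndarray:
    """Elementwise natural log; rejects nonpositive entries by position."""
    v = np.asarray(values, dtype=float)
    bad = np.where(~(v > 0))[0]
    if bad.size:
        raise ValueError(f"nonpositive values at positions {bad.tolist()}; cannot log-transform")
    return np.log(v)


def summarize_table(soil: pd.DataFrame) -> pd.DataFrame:
    """Per-plot wide summary from a long soil table.

    Input columns: plot_id, nutrient, replicate_index, value_mg_per_kg.
    Output: one row per plot with <nutrient>_{mean,cv,log_mean,log_cv}.
    """
    missing = set(SOIL_COLUMNS) - set(soil.columns)
    if missing:
        raise ValueError(f"soil table missing columns: {sorted(missing)}")
    rows: dict[str, dict[str, float]] = {}
    for (plot, nutrient), grp in soil.groupby(["plot_id", "nutrient"], sort=True):
        s = summarize_plot(grp["value_mg_per_kg"].to_numpy())
        row = rows.setdefault(str(plot), {})
        row[f"{nutrient}_mean"] = s.mean
        row[f"{nutrient}_cv"] = s.cv
        row[f"{nutrient}_log_mean"] = s.log_mean
        row[f"{nutrient}_log_cv"] = s.log_cv
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "plot_id"
    return out


def read_soil_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(SOIL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"soil CSV missing columns: {sorted(missing)}")
    df["plot_id"] = df["plot_id"].astype(str)
    return df


def write_soil_csv(soil: pd.DataFrame, path) -> None:
    soil.to_csv(path, index=False)
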