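#!/usr/bin/env python
"""Normality screen and correlation grid over the per-plot metrics.

Reads results/plot_metrics_niche.csv, runs Shapiro-Wilk on the analysis
variables, then the standard Pearson grid (soil availability and
heterogeneity on the log scale against rarefied richness, effective species
number, and NRI, plus the NRI-richness and within-nutrient mean-CV pairs and
the heterogeneity-phylodiversity pairs). Writes
results/normality_screen.csv and results/correlations_niche.csv and prints
the significant rows.
"""

from pathlib import Path

import pandas as pd

from phet.pipeline import DEFAULT_PAIRS
from phet.stats import correlation_table, normality_screen

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"

SCREEN_VARS = ["R_TR", "e_H", "nri", "AN_log_mean", "AN_log_cv",
               "EP_log_mean", "EP_log_cv", "pd_rarefied", "hill_pd_q1"]


def main() -> None:
    metrics = pd.read_csv(RESULTS / "plot_metrics_niche.csv", index_col="plot_id")

    screen = normality_screen(metrics.dropna(subset=["nri"]), SCREEN_VARS)
    screen.to_csv(RESULTS / "normality_screen.csv", index=False)
    n_pass = int(screen["normal"].sum())
    print(f"normality screen: {n_pass}/{len(screen)} variables consistent with "
          f"normality at alpha = .05")

    corr = correlation_table(metrics, DEFAULT_PAIRS)
    corr.to_csv(RESULTS / "correlations_niche.csv", index=False)
    sig = corr[corr.significant]
    print(f"\n{len(sig)}/{len(corr)} pairs significant at p < .05:")
    print(sig.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
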