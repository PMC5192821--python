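# phet — soil-nutrient heterogeneity, tree diversity, and community phylogenetic structure

`phet` is an analysis package for a classic question in community ecology:
does local environmental heterogeneity — here, the within-plot variability of
soil nutrients — promote tree species diversity, and does it reshape the
*phylogenetic* structure of the community? The package implements the full
analysis chain for plot-based forest inventories (stems with DBH > 1 cm in
20 × 20 m plots, replicate soil samples per plot, an ultrametric phylogeny of
the species pool), together with a calibrated simulator of the three
classical theoretical regimes (niche, unimodal, neutral) so that every stage
can be exercised and validated without field data.

## What it computes

Per plot, from a plot × species stem-count matrix, an ultrametric tree, and a
replicate soil table:

- **Taxonomic diversity** — richness *S*; Shannon index
  *H′ = −Σᵢ fᵢ ln fᵢ* over stem proportions *fᵢ*; effective number of species
  *e^H′*; and individual-based rarefied richness
  *E[Sₙ] = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)]* at the smallest plot total *n*.
- **Phylogenetic structure** — unweighted mean pairwise phylogenetic distance
  (MPD) of the species present; its standardized effect size under the
  taxa-labels permutation null,
  *SES = (MPD_obs − mean of randomized MPD) / SD of randomized MPD*
  (9,999 randomizations by default); the net relatedness index
  *NRI = −SES* (positive = clustering, negative = overdispersion); rooted
  Faith's PD with the same individual-based rarefaction applied branch-wise,
  *E[PDₙ] = Σₑ Lₑ [1 − C(N−Nₑ, n)/C(N, n)]*; and the order-1 phylogenetic
  Hill number *exp(−Σₑ (Lₑ/T̄) aₑ ln aₑ)* with *T̄ = Σₑ Lₑ aₑ*.
- **Soil** — availability *M* (mean) and heterogeneity *CV = SD/M* per
  nutrient (alkali-hydrolyzable nitrogen AN, extractable phosphorus EP),
  natural-log transformed for analysis.
- **Statistics** — Shapiro–Wilk normality screening and pairwise Pearson
  correlations (two-sided *t*, df = n−2, α = .05) across the standard grid
  of soil × diversity × structure variable pairs.

The simulator grows a unit-height pure-birth phylogeny, evolves species
nutrient optima by Brownian motion on it (phylogenetic niche conservatism),
and assembles plot communities by a stem lottery over micro-niches whose
scatter tracks the plot's realized phosphorus heterogeneity, with a
phylogenetic interaction that shifts from competitive repulsion of close
relatives (low heterogeneity) to relatedness-favouring filtering (high
heterogeneity). See `docs/methods.md` for the model and its calibration.

## Worked example

```bash
python analysis/01_simulate.py        # three scenario datasets -> scratch/data/
python analysis/02_plot_metrics.py    # per-plot metrics -> results/
python analysis/03_correlations.py    # normality screen + Pearson grid
python analysis/04_scenario_comparison.py
```

On the niche-coupled dataset (seed 1, 39 plots, 156-species pool) the
pipeline rarefies to the smallest plot total (86 stems) and the correlation
grid prints:

```
      var_x       var_y  n      r      p  significant
  EP_log_cv        R_TR 39 0.7443 0.0000         True
  EP_log_cv         e_H 39 0.6250 0.0000         True
  EP_log_cv         nri 39 0.6335 0.0000         True
EP_log_mean   EP_log_cv 39 0.3844 0.0157         True
  EP_log_cv pd_rarefied 39 0.4221 0.0074         True
```

Phosphorus heterogeneity (log CV of EP) is positively correlated with
rarefied richness, effective species number, NRI, and rarefied PD, while no
nitrogen pair reaches significance — the niche-regime fingerprint: plots
with more heterogeneous phosphorus hold more species, and their trees shift
from phylogenetically overdispersed to clustered. The scenario comparison
makes the contrast explicit: over 20 replicate simulations per regime the
heterogeneity–richness correlation is significant in 100% of niche-regime
replicates (NRI tercile means −1.16 → +2.04 across the heterogeneity
gradient) and in 0% of neutral ones.

The same stages are scriptable from the shell:

```bash
phet simulate --scenario niche_coupled --seed 1 --out-dir data/
phet run --tree data/tree.nwk --community data/community.csv \
         --soil data/soil.csv --rarefy auto --nrand 9999 --seed 1 --out out/
```

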