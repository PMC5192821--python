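# Methods

## Scope and data model

The package analyses plot-based forest inventory data in three parts: an
ultrametric phylogeny of the regional species pool (Newick, branch lengths
required, tip labels matching the community matrix's species columns), a
plot × species stem-count matrix (stems with DBH > 1 cm), and a long-format
soil table of replicate nutrient measurements per plot (four corner samples
in the emulated design; alkali-hydrolyzable nitrogen AN and extractable
phosphorus EP, mg/kg). Tree inference is upstream of the package: the
ultrametric tree is an input, validated on load (unique tips, nonnegative
branch lengths, root-to-tip depths equal within a relative tolerance of
1e-6 of tree height — real chronograms carry rounding noise; the tolerance
is configurable). Zero-length branches are allowed (soft polytomies),
negative ones rejected.

## Metrics

**Shannon diversity.** H′ = −Σ fᵢ ln fᵢ over stem proportions, natural log;
e^H′ is the Hill number of order 1. Species with zero count are excluded
(0·ln 0 := 0).

**Individual-based rarefaction.** E[Sₙ] = Σᵢ [1 − C(N−Nᵢ, n)/C(N, n)], the
without-replacement hypergeometric expectation, evaluated with log-gamma
binomials for numerical range. The analytic expectation (not a random
subsample) is always reported; a seeded Monte-Carlo subsampler exists purely
as a cross-check oracle. The default depth n is the smallest per-plot total
("auto"), matching standard practice of rarefying to the smallest sample.

**MPD and SES/NRI.** MPD is the unweighted mean of patristic distances over
all unordered pairs of species present (presence/absence; abundances never
enter). The null model permutes the species labels of the pool's distance
matrix, holding plot richness fixed; for unweighted MPD this is equivalent
to drawing a uniformly random same-size species set from the pool, which is
how the null is sampled (vectorised and chunked). SES = (observed −
null mean)/null SD with the sample (n−1) SD; NRI = −SES. Defaults: 9,999
randomizations in the pipeline; study-level evaluation runs use 199 for
throughput. Per-plot null substreams are derived from (seed, plot index) so
results do not depend on evaluation order. Plots with fewer than two
species, or a degenerate null (plot = entire pool, star-tree distances),
yield missing MPD/SES/NRI rather than zeros, and are dropped pairwise from
correlations involving NRI only. An exhaustive variant enumerates every
distinct relabeling outcome (all same-size subsets) for small pools; its
null moments use each outcome once, with the same (n−1) SD convention.

**Faith's PD.** Rooted convention: the spanning subtree of a species set
always includes the path to the root, so single-species PD is positive and
rarefaction to n = 1 is well defined. Rarefied PD applies the hypergeometric
survival probability branch-wise: E[PDₙ] = Σₑ Lₑ[1 − C(N−Nₑ, n)/C(N, n)],
where Nₑ counts stems descending through edge e.

**Phylogenetic Hill number (q = 1).** With branch relative abundances aₑ and
T̄ = Σ Lₑ aₑ (the abundance-weighted mean tip depth), the reported effective
number is exp(−Σₑ (Lₑ/T̄) aₑ ln aₑ). The general-q form
(Σₑ (Lₑ/T̄) aₑ^q)^{1/(1−q)} is implemented only as the independent limit
check at q = 1 ± 1e-6. The time horizon is fixed at T̄ ("mean effective"
tree depth); on an ultrametric tree with all tips abundant T̄ equals the
tree height, and on equal-depth star trees the metric reduces exactly to
e^H′.

**Soil summaries.** Availability M = arithmetic mean, heterogeneity
CV = SD/M with the sample (n−1) SD — the statistical default, stated
explicitly so tests can be exact. Both are natural-log transformed for the
correlation layer ("log-transformed" is taken as ln; base is a display
convention only); a CV of exactly 0 has no defined log and propagates as
missing. CV is invariant under unit rescaling.

**Correlation layer.** Pearson r with the two-sided p from
t = r√((n−2)/(1−r²)) on n−2 df (scipy.stats.pearsonr), significance at
α = .05, pairwise (not listwise) deletion of missing values so diversity
pairs keep their full n when some plots lack NRI. Shapiro–Wilk (Royston's
algorithm via scipy) screens each analysis variable. No multiple-testing
correction by default; Holm step-down is available behind a flag. Exact
p-values are stored; "p < .001"-style display is formatting only.

## The synthetic-data generator

The generator emulates the study design the metrics assume: 39 plots, a
156-species pool on a unit-height pure-birth (Yule) tree, 84–300 stems per
plot after the DBH > 1 cm census filter (per-stem lognormal DBH, median
4 cm, log-SD 0.7), and four corner soil samples per plot with latent plot
means and CVs drawn uniformly from the observed emulation windows
(AN 123.25–240.25 mg/kg, CV 0.02–0.35; EP 2.43–23.4 mg/kg, CV 0.16–1.13).
Replicates are lognormal with exactly the latent mean and CV by moment
inversion, so the latent CV is the controlled quantity. An optional Gaussian
copula couples the EP mean and CV draws (off by default); note that even
uncoupled, the *realized* mean and CV of skewed replicates correlate
positively, which is itself a feature of such data.

**Realized vs latent heterogeneity.** Community assembly responds to the
realized corner-sample CV — the soil pattern actually present in the plot —
not to the latent distribution parameter. This is the ecologically coherent
choice (trees experience the realized pattern, and the four samples measure
it nearly exactly) and it makes the measured heterogeneity an almost
noiseless covariate. The latent parameter is recoverable from 4 replicates
only with substantial attenuation (correlation ≈ 0.6–0.75 and a downward
slope bias for skewed replicates at high CV); truth tables record both.

**Niche-coupled regime.** Species nutrient optima evolve by Brownian motion
on the simulated tree (one N(0, Lₑ) increment per edge), standardised to
unit SD — close relatives share similar requirements by construction. Each
plot has a position on the trait axis (N(0, 0.5)) and offers 8 micro-niches
whose centers scatter around it with SD 0.45 + 0.9 · CV*: heterogeneous
plots span more of the niche axis. Stem-by-stem lottery: species weight =
Gaussian kernel sum over micro-niches (width 0.25) × a lognormal
species-level competitive ability (log-SD 1.0), plus a 6% uniform
immigration mass from the regional pool that keeps plots away from
degenerate monocultures. A species entering the plot is screened against
the residents through a phylogenetic kernel exp(−(d/1.2)²): below the
pivot heterogeneity (CV* = 0.55) the interaction is competitive repulsion
of close relatives with log-odds up to 12 (→ overdispersion), above it the
sign flips to relatedness-favouring filtering with log-odds up to 4 — the
mechanism by which moderated competition lets close relatives coexist in
heterogeneous plots (→ clustering). Screened candidates are redrawn up to
20 times.

**Unimodal regime.** As above, plus an effective-area penalty: stem counts
are binomially thinned with survival 1 − 0.8·(CV*/CV_max)², so high
heterogeneity shrinks populations and stochastic extinctions bend the
heterogeneity–richness relation into a hump.

**Neutral regime.** Stems are drawn from a shared metacommunity lognormal
SAD (log-SD 1.5) distorted per plot by lognormal dispersal/drift noise
(log-SD 1.5), independent of the soil. The drift term matters for
calibration: with a single shared abundance draw, chance alignment between
abundance and phylogeny gives all plots of a dataset a common SES offset and
inflates the pooled SES SD above its nominal unit value.

**Calibration.** The interaction strengths and micro-niche geometry were
selected by the committed sweep (`analysis/05_calibrate_generator.py`) to
make the regime contrast decisive at the study's sample size (n = 39): the
niche regime yields measured-CV correlations of ≈ 0.78 (rarefied richness)
and ≈ 0.63 (NRI) with tercile NRI means ≈ −1.2 → +2.2, detectable in
essentially every replicate, while the neutral regime stays at nominal
false-positive rates. Two realism trade-offs follow and are deliberate:
per-plot richness spans roughly 8–100 across the heterogeneity gradient,
wider than the 25–47 window typical of a single field forest (a gradient
steep enough for near-certain detection at n = 39 cannot also be richness-
flat); and the regime effects are stronger than the modest field-scale
correlations (r ≈ .4–.5) one expects in real inventories. Passing
scenario-recovery tests therefore demonstrates that the pipeline detects
the regimes' fingerprints, not that real forests show effects this large.

## Determinism and numerics

All randomness flows from numpy SeedSequence spawning: one top-level seed;
named substreams for tree, soil, and community generation and per-plot null
models, so outputs are bit-for-bit reproducible and independent of
evaluation order. Binomial coefficients use log-gamma differences;
distances are computed from the edge–tip incidence decomposition (O(n²)
memory, n = pool size) and validated against an independent traversal
implementation in the tests. Degenerate cases are explicit: empty or
all-zero count vectors, subsample depths outside [1, N], non-positive soil
values, constant vectors in Shapiro–Wilk, and zero-variance correlations
all raise; undefined SES/NRI propagates as missing.

## Study-level evaluation runs

`phet.evaluation` packages the standing checks: (1) neutral SES calibration
over 200 replicate study-sized datasets at 199 randomizations — pooled SES
mean ≈ 0 (tested against a cluster-aware SE, since plots within a dataset
share a tree and pool) and SD within [0.9, 1.1]; (2) exact agreement of
analytic rarefaction (richness and PD) with subset enumeration for all
abundance vectors of total ≤ 8 and 3-SE agreement with 10,000-draw
Monte-Carlo on 50 larger cases; (3) closed-form limits; (4) exact agreement
of the exhaustive null with brute-force relabeling enumeration on pools of
≤ 7 species; (5) scenario recovery over 100 replicate seeds per regime; and
(6) type-I calibration of the Pearson layer at n = 39 over 2,000 null
simulations. Replicate counts were chosen to keep each run in the minutes
range on one CPU; `scripts/acceptance.py` executes the same functions and
records the numbers.

## Known limitations

The generator's plots are statistically exchangeable — no spatial
autocorrelation between plots, no within-plot stem maps, no dispersal
kernels, no temporal dynamics. Soil replicates are iid within a plot, so
"heterogeneity" is variance, not spatial pattern. MPD is the only structure
metric (no MNTD/NTI, no abundance weighting, no independent-swap or
frequency null models), and Hill-PD is reported at q = 1 only. The
correlation layer is deliberately bivariate, mirroring the analysis design
it implements; no regression or SEM.
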