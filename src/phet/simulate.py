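"""Synthetic plot/soil/phylogeny generator.

Emulates the study design the analysis modules assume: 39 plots of 20 x 20 m,
four corner soil samples per plot (alkali-hydrolyzable nitrogen AN and
extractable phosphorus EP, mg/kg), a regional pool of ~156 tree species on an
ultrametric phylogeny, and per-plot stem counts of 84-300 individuals with
DBH > 1 cm. Three assembly regimes are available:

``niche_coupled``
    Species nutrient optima evolve by Brownian motion on the phylogeny
    (phylogenetic niche conservatism). Each plot offers a set of narrow
    micro-niches whose scatter grows with its realized phosphorus
    heterogeneity CV*; stems are sampled by lottery among species whose
    optima match the offered micro-niches, screened by a phylogenetic
    interaction that flips from competitive repulsion of close relatives at
    low CV* to relatedness-favouring filtering at high CV*. Richness and the
    net relatedness index both increase with CV*.
``unimodal``
    As ``niche_coupled``, plus an effective-area penalty thinning stem
    numbers at high CV*, so stochastic extinctions bend the
    heterogeneity-richness relation into a hump.
``neutral``
    Stems drawn from a shared metacommunity abundance distribution distorted
    per plot by lognormal dispersal/drift noise, independent of the soil:
    no heterogeneity-diversity relation, SES consistent with the null.

Every stem carries a lognormal DBH and the DBH > 1 cm census filter is
applied before counting. All outputs are reproducible bit-for-bit from
(config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .diversity import write_community_csv
from .soil import write_soil_csv
from .tree import UltrametricTree

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_soil",
    "brownian_traits",
    "simulate_community",
    "simulate_dataset",
]

SCENARIOS = ("niche_coupled", "unimodal", "neutral")


@dataclass
class SimulationConfig:
    """Generator settings; defaults emulate the study conditions."""

    n_plots: int = 39
    n_soil_replicates: int = 4
    pool_size: int = 156
    stems_range: tuple[int, int] = (84, 300)
    scenario: str = "niche_coupled"
    # nutrient emulation windows (per-plot latent mean and CV drawn uniformly)
    an_mean_range: tuple[float, float] = (123.25, 240.25)   # mg/kg
    an_cv_range: tuple[float, float] = (0.02, 0.35)
    ep_mean_range: tuple[float, float] = (2.43, 23.4)       # mg/kg
    ep_cv_range: tuple[float, float] = (0.16, 1.13)
    couple_mean_cv: bool = False   # rank-correlate EP mean and CV (copula rho)
    mean_cv_rho: float = 0.6
    # niche / assembly parameters (trait axis standardised to unit SD)
    niche_breadth: float = 0.25        # micro-niche kernel width
    n_microniches: int = 8
    microniche_spread_base: float = 0.45   # center scatter at CV* = 0
    microniche_spread_scale: float = 0.9   # center scatter per unit CV*
    plot_center_sd: float = 0.5
    clade_filter_strength: float = 12.0    # repulsion log-odds as CV* -> 0
    relatedness_filter_strength: float = 4.0   # filtering log-odds at high CV*
    cv_pivot: float = 0.55                 # CV* where repulsion hands over to filtering
    repulsion_scale: float = 1.2           # phylogenetic kernel width (tree height units)
    max_repulsion_retries: int = 20
    immigration: float = 0.06              # uniform lottery mass from the regional pool
    unimodal_penalty: float = 0.8
    # lognormal sd of per-species competitive ability in the niche lottery
    lottery_sigma: float = 1.0
    # neutral regime: metacommunity abundance skew and per-plot drift skew
    sad_sigma: float = 1.5
    dispersal_sigma: float = 1.5
    # stem diameters (cm): lognormal, census filter at dbh_min
    dbh_log_median: float = 4.0
    dbh_log_sigma: float = 0.7
    dbh_min: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.n_plots < 3:
            raise ValueError("need at least 3 plots")
        if self.pool_size < 2:
            raise ValueError("pool_size must be >= 2")
        if self.n_soil_replicates < 2:
            raise ValueError("need >= 2 soil replicates per plot for a CV")
        lo, hi = self.stems_range
        if not (0 < lo <= hi):
            raise ValueError("invalid stems_range")
        for name in ("an_mean_range", "an_cv_range", "ep_mean_range", "ep_cv_range"):
            a, b = getattr(self, name)
            if a < 0 or b < a:
                raise ValueError(f"invalid {name}")


@dataclass
class SyntheticDataset:
    tree: UltrametricTree
    community: pd.DataFrame     # plots x species stem counts
    soil: pd.DataFrame          # long table: plot_id, nutrient, replicate_index, value
    truth: pd.DataFrame         # per-plot latent values
    config: SimulationConfig

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "tree.nwk").write_text(self.tree.to_newick() + "\n", encoding="utf-8")
        write_community_csv(self.community, out / "community.csv")
        write_soil_csv(self.soil, out / "soil.csv")
        truth = {
            "config": asdict(self.config),
            "plots": self.truth.reset_index().to_dict(orient="records"),
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1), encoding="utf-8")


# ---------------------------------------------------------------------------
# phylogeny

def simulate_tree(pool_size: int, seed=None) -> UltrametricTree:
    """Pure-birth (Yule) tree on *pool_size* tips, rescaled to unit height.

    Equal-rates branching: waiting times are exponential with rate equal to
    the number of live lineages and the splitting lineage is uniform.
    """
    if pool_size < 2:
        raise ValueError("pool_size must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    children: dict[int, tuple[int, int]] = {}
    birth = {0: 0.0}
    end: dict[int, float] = {}
    active = [0]
    next_id = 1
    t = 0.0
    while len(active) < pool_size:
        t += rng.exponential(1.0 / len(active))
        i = int(rng.integers(len(active)))
        node = active.pop(i)
        end[node] = t
        kids = (next_id, next_id + 1)
        next_id += 2
        for k in kids:
            birth[k] = t
        children[node] = kids
        active.extend(kids)
    t += rng.exponential(1.0 / pool_size)
    for node in active:
        end[node] = t

    # height is measured from the root's first split; the stem segment
    # before it carries no information and is dropped
    height = t - end[0]
    if height <= 0:
        height = 1.0
    width = len(str(pool_size))
    counter = [0]

    def newick(node: int) -> str:
        length = (end[node] - birth[node]) / height
        if node in children:
            a, b = children[node]
            return f"({newick(a)},{newick(b)}):{length!r}"
        counter[0] += 1
        return f"sp{counter[0]:0{width}d}:{length!r}"

    a, b = children[0]
    text = f"({newick(a)},{newick(b)});"
    return UltrametricTree.from_newick(text)


def brownian_traits(tree: UltrametricTree, rng: np.random.Generator,
                    standardize: bool = True) -> np.ndarray:
    """Brownian trait at each tip (ordered as ``tree.tip_labels``).

    One independent N(0, L_e) increment per edge, summed down each tip's
    root path; optionally standardised to zero mean, unit SD across tips.
    """
    increments = rng.normal(0.0, 1.0, size=tree.edge_lengths.size) * np.sqrt(tree.edge_lengths)
    z = tree.edge_tip_incidence.T.astype(float) @ increments
    if standardize:
        sd = z.std()
        if sd > 0:
            z = (z - z.mean()) / sd
    return z


# ---------------------------------------------------------------------------
# soil

def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given arithmetic mean and CV."""
    sigma2 = np.log1p(cv * cv)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def simulate_soil(config: SimulationConfig,
                  rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-plot replicate nutrient measurements plus latent truth.

    Latent plot means M* and CVs CV* are uniform on the configured windows;
    replicates are lognormal with exactly that mean and CV (moment
    inversion), so CV* is the controlled heterogeneity. With
    ``couple_mean_cv`` the EP mean and CV are drawn rank-correlated through
    a Gaussian copula.
    """
    n = config.n_plots
    width = max(2, len(str(n)))
    plot_ids = [f"P{i + 1:0{width}d}" for i in range(n)]
    truth = pd.DataFrame(index=pd.Index(plot_ids, name="plot_id"))
    rows = []
    for nutrient, mean_range, cv_range in (
        ("AN", config.an_mean_range, config.an_cv_range),
        ("EP", config.ep_mean_range, config.ep_cv_range),
    ):
        if nutrient == "EP" and config.couple_mean_cv:
            zz = rng.multivariate_normal(
                [0.0, 0.0],
                [[1.0, config.mean_cv_rho], [config.mean_cv_rho, 1.0]], size=n)
            from scipy.stats import norm
            u_mean, u_cv = norm.cdf(zz[:, 0]), norm.cdf(zz[:, 1])
        else:
            u_mean, u_cv = rng.random(n), rng.random(n)
        means = mean_range[0] + u_mean * (mean_range[1] - mean_range[0])
        cvs = cv_range[0] + u_cv * (cv_range[1] - cv_range[0])
        truth[f"{nutrient}_mean_true"] = means
        truth[f"{nutrient}_cv_true"] = cvs
        real_cv, real_mean = [], []
        for p, (m, cv) in enumerate(zip(means, cvs)):
            if cv == 0:
                vals = np.full(config.n_soil_replicates, m)
            else:
                mu, sigma = _lognormal_params(m, cv)
                vals = rng.lognormal(mu, sigma, size=config.n_soil_replicates)
            # the realized corner pattern is the heterogeneity the trees see
            real_mean.append(float(vals.mean()))
            real_cv.append(float(vals.std(ddof=1) / vals.mean()))
            for r, v in enumerate(vals, start=1):
                rows.append((plot_ids[p], nutrient, r, float(v)))
        truth[f"{nutrient}_mean_realized"] = real_mean
        truth[f"{nutrient}_cv_realized"] = real_cv
    soil = pd.DataFrame(rows, columns=["plot_id", "nutrient", "replicate_index",
                                       "value_mg_per_kg"])
    return soil, truth


# ---------------------------------------------------------------------------
# communities

def _draw_stems_neutral(n_stems: int, pool_abund: np.ndarray, config: SimulationConfig,
                        rng: np.random.Generator) -> np.ndarray:
    counts = np.zeros(pool_abund.size, dtype=int)
    cum = np.cumsum(pool_abund)
    placed = 0
    while placed < n_stems:
        sp = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
        dbh = config.dbh_log_median * np.exp(rng.normal(0.0, config.dbh_log_sigma))
        if dbh <= config.dbh_min:
            continue  # census filter: stem too thin to record
        counts[sp] += 1
        placed += 1
    return counts


def _draw_stems_niche(n_stems: int, weights: np.ndarray, dist: np.ndarray,
                      interaction: float, config: SimulationConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Stem-by-stem lottery with a phylogenetic interaction at first occurrence.

    A species entering the plot is screened against the residents:
    ``interaction > 0`` penalises proximity to the closest resident relative
    (competitive repulsion -> overdispersion), ``interaction < 0`` penalises
    distance instead (relatives pass the filter more easily -> clustering).
    Stems of already-resident species are never screened.
    """
    n_sp = weights.size
    counts = np.zeros(n_sp, dtype=int)
    present = np.zeros(n_sp, dtype=bool)
    cum = np.cumsum(weights)
    tau2 = (config.repulsion_scale * 1.0) ** 2  # trees are unit height
    placed = 0
    while placed < n_stems:
        sp = -1
        for _ in range(config.max_repulsion_retries):
            cand = int(np.searchsorted(cum, rng.random() * cum[-1], side="right"))
            if present[cand] or interaction == 0 or not present.any():
                sp = cand
                break
            prox = float(np.exp(-dist[cand, present] ** 2 / tau2).max())
            penalty = interaction * prox if interaction > 0 else -interaction * (1.0 - prox)
            if rng.random() < np.exp(-penalty):
                sp = cand
                break
        if sp < 0:
            sp = cand  # retries exhausted: admit the last candidate
        dbh = config.dbh_log_median * np.exp(rng.normal(0.0, config.dbh_log_sigma))
        if dbh <= config.dbh_min:
            continue
        counts[sp] += 1
        present[sp] = True
        placed += 1
    return counts


def simulate_community(tree: UltrametricTree, truth: pd.DataFrame,
                       config: SimulationConfig,
                       rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot x species stem counts under the configured assembly regime.

    Returns the community matrix and an augmented copy of *truth* with the
    per-plot latent assembly variables (trait optimum of the plot center,
    repulsion strength, realised stem target).
    """
    n_sp = len(tree)
    plot_ids = list(truth.index)
    truth = truth.copy()

    optima = brownian_traits(tree, rng)
    truth.attrs["species_optima"] = dict(zip(tree.tip_labels, optima.round(6).tolist()))

    dist = tree.pairwise_distances().values
    pool_abund = None
    ability = None
    if config.scenario == "neutral":
        pool_abund = rng.lognormal(0.0, config.sad_sigma, size=n_sp)
        pool_abund /= pool_abund.sum()
    else:
        # species-level competitive ability, independent of the phylogeny,
        # skews the lottery so stem abundances follow a realistic SAD
        ability = rng.lognormal(0.0, config.lottery_sigma, size=n_sp)

    lo, hi = config.stems_range
    cv_lo, cv_hi = config.ep_cv_range
    centers = rng.normal(0.0, config.plot_center_sd, size=len(plot_ids))
    counts_rows = []
    lam_col, stems_col = [], []
    for p, plot in enumerate(plot_ids):
        n_stems = int(rng.integers(lo, hi + 1))
        # assembly responds to the soil pattern actually present in the plot
        # (the realized corner CV), not the latent generating parameter
        cv_star = float(truth.loc[plot, "EP_cv_realized"])
        if config.scenario == "neutral":
            # local community = metacommunity SAD distorted by dispersal/drift
            local = pool_abund * rng.lognormal(0.0, config.dispersal_sigma, size=n_sp)
            counts = _draw_stems_neutral(n_stems, local / local.sum(), config, rng)
            lam = 0.0
        else:
            spread = config.microniche_spread_base + config.microniche_spread_scale * cv_star
            niche_centers = rng.normal(centers[p], spread, size=config.n_microniches)
            w = np.exp(-(optima[:, None] - niche_centers[None, :]) ** 2
                       / (2.0 * config.niche_breadth ** 2)).sum(axis=1)
            w = ability * (w + 1e-9)
            # dispersal from the regional pool: a small uniform arrival mass
            # keeps richness away from degenerate one-species plots
            w = (1.0 - config.immigration) * w / w.sum() + config.immigration / n_sp
            # competitive repulsion below cv_pivot, relatedness filtering above
            rel = 1.0 - cv_star / config.cv_pivot
            lam = (config.clade_filter_strength * rel if rel >= 0
                   else config.relatedness_filter_strength * rel)
            counts = _draw_stems_niche(n_stems, w, dist, lam, config, rng)
            if config.scenario == "unimodal":
                # effective-area penalty: shrinking per-species populations at
                # high heterogeneity drives stochastic extinctions
                survival = max(0.05, 1.0 - config.unimodal_penalty * (cv_star / cv_hi) ** 2)
                counts = rng.binomial(counts, survival)
                if counts.sum() == 0:
                    counts[int(np.argmax(w))] = 1
        counts_rows.append(counts)
        lam_col.append(lam)
        stems_col.append(n_stems)

    community = pd.DataFrame(np.vstack(counts_rows),
                             index=pd.Index(plot_ids, name="plot_id"),
                             columns=list(tree.tip_labels))
    truth["plot_center"] = centers
    truth["repulsion"] = lam_col
    truth["stems_target"] = stems_col
    truth["scenario"] = config.scenario
    return community, truth


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full dataset (tree + soil + community + truth) from one seed.

    Independent named substreams per stage, so e.g. the soil draw does not
    perturb the community draw when a parameter changes upstream.
    """
    ss = np.random.SeedSequence(config.seed)
    tree_ss, soil_ss, comm_ss = ss.spawn(3)
    tree = simulate_tree(config.pool_size, np.random.default_rng(tree_ss))
    soil, truth = simulate_soil(config, np.random.default_rng(soil_ss))
    community, truth = simulate_community(tree, truth, config,
                                          np.random.default_rng(comm_ss))
    return SyntheticDataset(tree=tree, community=community, soil=soil,
                            truth=truth, config=config)
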