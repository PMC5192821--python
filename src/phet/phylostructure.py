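"""Community phylogenetic structure per plot.

Implements the unweighted mean pairwise phylogenetic distance (MPD), its
standardised effect size under the taxa-labels permutation null, the net
relatedness index NRI = -SES (positive = phylogenetic clustering, negative =
overdispersion), rooted Faith's PD with individual-based analytic
rarefaction, and the order-1 phylogenetic Hill number.

The taxa-labels null shuffles the species labels of the pool's distance
matrix while holding plot richness fixed; for unweighted presence/absence
MPD this is equivalent to drawing a uniformly random same-size species set
from the pool, which is how the shuffle is realised (vectorised, chunked).
The null standard deviation uses the sample (n-1) convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .tree import DistanceMatrix, UltrametricTree

__all__ = [
    "MetricUndefinedError",
    "NullModelSpec",
    "PhyloStructureResult",
    "mpd",
    "ses_mpd",
    "faith_pd",
    "rarefied_pd",
    "rarefied_pd_mc",
    "hill_pd",
    "hill_pd_q1",
]


class MetricUndefinedError(ValueError):
    """A metric is undefined for this input (e.g. MPD with < 2 species)."""


@dataclass(frozen=True)
class NullModelSpec:
    """Randomisation scheme for SES."""

    name: str = "taxa_labels"
    n_randomizations: int = 9_999
    seed: int | None = None

    def __post_init__(self):
        if self.name != "taxa_labels":
            raise ValueError(f"unknown null model {self.name!r}")
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")


@dataclass(frozen=True)
class PhyloStructureResult:
    mpd_obs: float
    null_mean: float
    null_sd: float
    ses: float
    nri: float
    n_randomizations: int


def mpd(present_species, dist: DistanceMatrix) -> float:
    """Unweighted MPD: mean distance over unordered distinct pairs present.

    Presence/absence only; duplicating abundances cannot change it.
    """
    labels = sorted(set(present_species))
    if len(labels) < 2:
        raise MetricUndefinedError("MPD requires at least 2 species")
    sub = dist.submatrix(labels)
    k = sub.shape[0]
    return float(sub.sum() / (k * (k - 1)))


def _null_mpd_sample(dist: DistanceMatrix, k: int, n_rand: int,
                     rng: np.random.Generator, chunk: int = 2_000) -> np.ndarray:
    """MPD of n_rand random k-subsets of the pool (taxa-labels null)."""
    n = len(dist)
    d = dist.values
    out = np.empty(n_rand)
    done = 0
    while done < n_rand:
        m = min(chunk, n_rand - done)
        # uniform random k-subsets: first k of a random permutation per row
        ranks = rng.random((m, n))
        idx = np.argpartition(ranks, k - 1, axis=1)[:, :k]
        sub = d[idx[:, :, None], idx[:, None, :]]
        out[done:done + m] = sub.sum(axis=(1, 2)) / (k * (k - 1))
        done += m
    return out


def _exhaustive_null_mpd(dist: DistanceMatrix, k: int) -> np.ndarray:
    """MPD over every k-subset of the pool.

    Every label permutation maps the plot to some k-subset, and each subset
    is the image of equally many permutations, so the permutation null and
    the uniform-subset enumeration have identical distributions.
    """
    n = len(dist)
    d = dist.values
    vals = []
    for combo in itertools.combinations(range(n), k):
        idx = np.array(combo)
        vals.append(d[np.ix_(idx, idx)].sum() / (k * (k - 1)))
    return np.array(vals)


def ses_mpd(present_species, dist: DistanceMatrix,
            null: NullModelSpec = NullModelSpec(),
            rng: np.random.Generator | None = None,
            exhaustive: bool = False) -> PhyloStructureResult:
    """SES of MPD under the taxa-labels null; NRI = -SES.

    SES = (observed MPD - mean of randomised MPDs) / sd of randomised MPDs.
    When the null sd is zero (plot = full pool, or a star tree) SES and NRI
    are returned as NaN: the standardisation is undefined, and callers treat
    the plot as missing.

    With ``exhaustive=True`` the null enumerates every distinct relabeling
    outcome (all same-size subsets of the pool; small pools only) instead
    of Monte-Carlo sampling.
    """
    obs = mpd(present_species, dist)
    k = len(set(present_species))
    if exhaustive:
        # label permutations act on plots through their image subset, and all
        # k-subsets are images of equally many permutations, so the complete
        # null is the set of distinct subset values, each counted once
        null_vals = _exhaustive_null_mpd(dist, k)
        n_rand = null_vals.size
        null_mean = float(null_vals.mean())
        null_sd = float(null_vals.std(ddof=1)) if n_rand > 1 else 0.0
        if null_sd > 1e-12 * max(1.0, abs(null_mean)):
            ses = (obs - null_mean) / null_sd
        else:
            null_sd = 0.0
            ses = float("nan")
        return PhyloStructureResult(
            mpd_obs=obs, null_mean=null_mean, null_sd=null_sd,
            ses=float(ses), nri=float(-ses), n_randomizations=n_rand,
        )
    if rng is None:
        rng = np.random.default_rng(null.seed)
    n_rand = null.n_randomizations
    null_vals = _null_mpd_sample(dist, k, n_rand, rng)
    null_mean = float(null_vals.mean())
    null_sd = float(null_vals.std(ddof=1)) if null_vals.size > 1 else 0.0
    if null_sd > 0 and not math.isclose(null_sd, 0.0, abs_tol=1e-12 * max(1.0, null_mean)):
        ses = (obs - null_mean) / null_sd
    else:
        null_sd = 0.0 if null_vals.size > 1 else null_sd
        ses = float("nan")
    return PhyloStructureResult(
        mpd_obs=obs, null_mean=null_mean, null_sd=null_sd,
        ses=float(ses), nri=float(-ses), n_randomizations=n_rand,
    )


def faith_pd(present_species, tree: UltrametricTree) -> float:
    """Rooted Faith's PD of the present species (root path included)."""
    return tree.total_branch_length(present_species)


def _ln_choose(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def rarefied_pd(counts, tree: UltrametricTree, n: int) -> float:
    """Expected rooted Faith's PD of a without-replacement sample of n stems.

    E[PD_n] = sum_e L_e [1 - C(N - N_e, n) / C(N, n)] where N_e is the stem
    count subtended by edge e — each branch survives subsampling exactly when
    at least one of its descendant stems is drawn.
    """
    c = np.asarray(counts, dtype=float)
    if c.shape != (len(tree),):
        raise ValueError("counts must align with the tree's tip set")
    if np.any(c < 0) or not np.allclose(c, np.round(c)):
        raise ValueError("counts must be nonnegative integers")
    total = int(round(c.sum()))
    if total < 1:
        raise ValueError("counts must contain at least one stem")
    n = int(n)
    if not 1 <= n <= total:
        raise ValueError(f"subsample size {n} out of range [1, {total}]")
    edge_counts = tree.edge_tip_incidence @ c
    rest = total - edge_counts
    p_absent = np.zeros_like(edge_counts)
    ok = rest >= n
    p_absent[ok] = np.exp(_ln_choose(rest[ok], n) - _ln_choose(np.float64(total), n))
    return float((tree.edge_lengths * (1.0 - p_absent)).sum())


def rarefied_pd_mc(counts, tree: UltrametricTree, n: int, n_draws: int = 10_000,
                   rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Monte-Carlo rarefied PD (mean, standard error) for cross-checking."""
    c = np.asarray(counts, dtype=int)
    pool = np.repeat(np.arange(c.size), c)
    rng = np.random.default_rng() if rng is None else rng
    inc = tree.edge_tip_incidence
    lengths = tree.edge_lengths
    vals = np.empty(n_draws)
    for d in range(n_draws):
        take = rng.choice(pool, size=n, replace=False)
        present = np.zeros(c.size, dtype=bool)
        present[np.unique(take)] = True
        vals[d] = lengths[(inc & present).any(axis=1)].sum()
    return float(vals.mean()), float(vals.std(ddof=1) / np.sqrt(n_draws))


def _branch_abundances(counts, tree: UltrametricTree) -> tuple[np.ndarray, np.ndarray]:
    c = np.asarray(counts, dtype=float)
    if c.shape != (len(tree),):
        raise ValueError("counts must align with the tree's tip set")
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    total = c.sum()
    if total <= 0:
        raise ValueError("counts must contain at least one stem")
    a = (tree.edge_tip_incidence @ c) / total
    return tree.edge_lengths, a


def hill_pd(counts, tree: UltrametricTree, q: float) -> float:
    """Phylogenetic Hill number of order q, as an effective species number.

    With L_e the branch lengths, a_e the relative abundance flowing through
    branch e, and T-bar = sum L_e a_e the abundance-weighted mean tip depth:

        q != 1:  [ sum_e (L_e / T-bar) a_e^q ] ^ (1 / (1 - q))
        q == 1:  exp( - sum_e (L_e / T-bar) a_e ln a_e )

    evaluated at temporal scale T-bar. Used at general q only as the
    independent limit check for the q = 1 case.
    """
    lengths, a = _branch_abundances(counts, tree)
    tbar = float((lengths * a).sum())
    pos = a > 0
    w = lengths[pos] / tbar
    ap = a[pos]
    if q == 1:
        return float(np.exp(-(w * ap * np.log(ap)).sum()))
    s = float((w * ap ** q).sum())
    return float(s ** (1.0 / (1.0 - q)))


def hill_pd_q1(counts, tree: UltrametricTree) -> float:
    """Order-1 phylogenetic Hill number (effective number of species)."""
    return hill_pd(counts, tree, q=1.0)
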