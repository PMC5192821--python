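"""Study-level evaluation runs: null calibration, oracle checks, scenario
recovery, and type-I calibration.

These functions re-run the pipeline end to end at the study's scale
(39 plots, 156-species pool) and summarise the outcome; the test suite and
the reproduction script both drive them. Every function takes an explicit
seed and is deterministic given it.
"""

from __future__ import annotations

import itertools

import numpy as np

from .diversity import (rarefied_richness, rarefied_richness_mc,
                        smallest_sample_size)
from .phylostructure import NullModelSpec, rarefied_pd, rarefied_pd_mc, ses_mpd
from .simulate import SimulationConfig, simulate_dataset, simulate_tree
from .soil import summarize_table
from .stats import pearson

__all__ = [
    "neutral_ses_calibration",
    "rarefaction_oracle_check",
    "scenario_recovery",
    "type_one_error_rate",
]


def _dataset_seed(seed: int, index: int) -> int:
    return int((seed * 100_003 + index) % (2 ** 31 - 1))


def _plot_statistics(ds, n_randomizations: int, rng: np.random.Generator):
    """Per-plot (log CV_EP, rarefied richness, SES, NRI) for one dataset."""
    comm = ds.community
    n0 = smallest_sample_size(comm)
    logcv = summarize_table(ds.soil)["EP_log_cv"].to_numpy()
    dist = ds.tree.pairwise_distances()
    null = NullModelSpec(n_randomizations=n_randomizations)
    rtr, ses, nri = [], [], []
    for _, row in comm.iterrows():
        rtr.append(rarefied_richness(row.to_numpy(), n0))
        res = ses_mpd(list(row.index[row > 0]), dist, null, rng=rng)
        ses.append(res.ses)
        nri.append(res.nri)
    return logcv, np.array(rtr), np.array(ses), np.array(nri)


def neutral_ses_calibration(seed: int, n_datasets: int = 200,
                            n_randomizations: int = 199) -> dict:
    """SES of MPD under neutral assembly across replicate datasets.

    Returns the pooled SES mean and SD, a cluster-aware standard error of
    the mean (plots within a dataset share a tree and species pool), and
    the maximum |NRI + SES| as a sign-convention check.
    """
    all_ses, dataset_means = [], []
    nri_identity_err = 0.0
    for i in range(n_datasets):
        cfg = SimulationConfig(scenario="neutral", seed=_dataset_seed(seed, i))
        ds = simulate_dataset(cfg)
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1, i)))
        _, _, ses, nri = _plot_statistics(ds, n_randomizations, rng)
        ok = np.isfinite(ses)
        nri_identity_err = max(nri_identity_err, float(np.abs(nri[ok] + ses[ok]).max()))
        all_ses.append(ses[ok])
        dataset_means.append(ses[ok].mean())
    pooled = np.concatenate(all_ses)
    dataset_means = np.array(dataset_means)
    return {
        "n_plots_total": int(pooled.size),
        "ses_mean": float(pooled.mean()),
        "ses_sd": float(pooled.std(ddof=1)),
        "ses_mean_se": float(dataset_means.std(ddof=1) / np.sqrt(n_datasets)),
        "nri_identity_max_abs_err": float(nri_identity_err),
    }


def _abundance_vectors(max_total: int = 8):
    """All positive-count abundance vectors (as partitions) with N <= max_total."""
    for total in range(1, max_total + 1):
        # partitions of `total` in nonincreasing order
        def parts(n, cap):
            if n == 0:
                yield ()
                return
            for first in range(min(n, cap), 0, -1):
                for rest in parts(n - first, first):
                    yield (first,) + rest
        yield from parts(total, total)


def _enumerate_rarefied_richness(counts, n):
    pool = [sp for sp, c in enumerate(counts) for _ in range(c)]
    combos = list(itertools.combinations(range(len(pool)), n))
    return sum(len({pool[i] for i in combos_i}) for combos_i in combos) / len(combos)


def _enumerate_rarefied_pd(counts, tree, n):
    labels = tree.tip_labels
    pool = [labels[sp] for sp, c in enumerate(counts) for _ in range(c)]
    vals = [tree.total_branch_length({pool[i] for i in combo})
            for combo in itertools.combinations(range(len(pool)), n)]
    return float(np.mean(vals))


def rarefaction_oracle_check(seed: int, n_random_cases: int = 50,
                             n_draws: int = 10_000) -> dict:
    """Analytic rarefaction vs exhaustive enumeration and Monte-Carlo.

    Enumeration covers every abundance vector with total count <= 8 (richness
    and rooted PD, at every subsample depth); the Monte-Carlo arm draws
    larger random cases and records the worst deviation in standard errors.
    """
    err_rich = err_pd = 0.0
    tree8 = simulate_tree(8, np.random.default_rng(seed))
    for vec in _abundance_vectors(8):
        counts = list(vec) + [0] * (8 - len(vec))
        total = sum(vec)
        for n in range(1, total + 1):
            err_rich = max(err_rich, abs(
                rarefied_richness(vec, n) - _enumerate_rarefied_richness(vec, n)))
            err_pd = max(err_pd, abs(
                rarefied_pd(counts, tree8, n) - _enumerate_rarefied_pd(counts, tree8, n)))

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(2,)))
    z_rich = z_pd = 0.0
    for _ in range(n_random_cases):
        n_sp = int(rng.integers(5, 20))
        tree = simulate_tree(n_sp, rng)
        counts = rng.integers(0, 40, size=n_sp)
        counts[int(rng.integers(n_sp))] = max(1, counts[int(rng.integers(n_sp))])
        total = int(counts.sum())
        n = int(rng.integers(2, max(3, total)))
        def z_score(analytic, mean, se):
            # if every draw is identical the empirical SE is 0 even though a
            # rare miss event has tiny positive probability; the rule-of-three
            # bound 3/n_draws floors the uncertainty in that regime
            return abs(analytic - mean) / max(se, 3.0 / n_draws)

        mean, se = rarefied_richness_mc(counts[counts > 0], n, n_draws=n_draws, rng=rng)
        z_rich = max(z_rich, z_score(rarefied_richness(counts, n), mean, se))
        mean, se = rarefied_pd_mc(counts, tree, n, n_draws=n_draws, rng=rng)
        z_pd = max(z_pd, z_score(rarefied_pd(counts, tree, n), mean, se))
    return {
        "enumeration_max_abs_err_richness": float(err_rich),
        "enumeration_max_abs_err_pd": float(err_pd),
        "mc_max_z_richness": float(z_rich),
        "mc_max_z_pd": float(z_pd),
    }


def scenario_recovery(seed: int, n_seeds: int = 100,
                      n_randomizations: int = 199) -> dict:
    """Heterogeneity-diversity recovery under the niche vs neutral regimes.

    For each replicate seed and scenario: one study-sized dataset, the
    Pearson tests of log CV_EP against rarefied richness and against NRI,
    and the per-dataset NRI means in the lowest and highest heterogeneity
    terciles. Reports significance rates (significant AND positive) and
    pooled tercile means.
    """
    out = {}
    for scenario in ("niche_coupled", "neutral"):
        hits_rtr = hits_nri = 0
        lo_terc, hi_terc = [], []
        for i in range(n_seeds):
            cfg = SimulationConfig(scenario=scenario, seed=_dataset_seed(seed, 10_000 + i))
            ds = simulate_dataset(cfg)
            rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3, i)))
            logcv, rtr, _, nri = _plot_statistics(ds, n_randomizations, rng)
            res_rtr = pearson(logcv, rtr)
            hits_rtr += res_rtr.significant and res_rtr.r > 0
            ok = np.isfinite(nri)
            res_nri = pearson(logcv[ok], nri[ok])
            hits_nri += res_nri.significant and res_nri.r > 0
            cv_true = ds.truth["EP_cv_realized"].to_numpy()
            order = np.argsort(cv_true)
            t = len(order) // 3
            lo_terc.append(np.nanmean(nri[order[:t]]))
            hi_terc.append(np.nanmean(nri[order[-t:]]))
        key = "niche" if scenario == "niche_coupled" else "neutral"
        out[f"{key}_rate_cv_ep_rtr"] = hits_rtr / n_seeds
        out[f"{key}_rate_cv_ep_nri"] = hits_nri / n_seeds
        out[f"{key}_nri_low_tercile_mean"] = float(np.mean(lo_terc))
        out[f"{key}_nri_high_tercile_mean"] = float(np.mean(hi_terc))
    return out


def type_one_error_rate(seed: int, n_sims: int = 2_000, n: int = 39) -> dict:
    """Rejection rate of the Pearson test on independent normal pairs."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(4,)))
    hits = sum(pearson(rng.normal(size=n), rng.normal(size=n)).significant
               for _ in range(n_sims))
    rate = hits / n_sims
    return {
        "rejection_rate": rate,
        "n_sims": n_sims,
        "binomial_se": float(np.sqrt(0.05 * 0.95 / n_sims)),
    }
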