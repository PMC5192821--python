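"""Taxonomic diversity metrics per plot.

Richness, the Shannon index H' = -sum f_i ln f_i over the stem proportions
f_i, its exponential e^H' (the effective number of species, i.e. the Hill
number of order 1), and individual-based rarefaction: the expected number of
species in a without-replacement subsample of n stems,

    E[S_n] = sum_i [ 1 - C(N - N_i, n) / C(N, n) ],

the hypergeometric absence-probability form. Rarefaction here is the analytic
expectation, not a random subsample; a seeded Monte-Carlo variant exists for
cross-checking only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "shannon_effective",
    "rarefied_richness",
    "rarefied_richness_mc",
    "smallest_sample_size",
    "read_community_csv",
    "write_community_csv",
    "validate_community",
]


def _clean_counts(counts) -> np.ndarray:
    c = np.asarray(counts, dtype=float)
    if c.ndim != 1:
        raise ValueError("counts must be a 1-D vector")
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    if not np.any(c > 0):
        raise ValueError("counts must contain at least one positive value")
    return c


def shannon_effective(counts) -> tuple[float, float]:
    """Shannon index H' (nats) and effective number of species e^H'.

    Species with zero count are excluded (0 ln 0 := 0). Scale-invariant:
    only the proportions f_i enter.
    """
    c = _clean_counts(counts)
    f = c[c > 0] / c.sum()
    h = float(-(f * np.log(f)).sum())
    return h, float(np.exp(h))


def _ln_choose(n: np.ndarray, k: float) -> np.ndarray:
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def rarefied_richness(counts, n: int) -> float:
    """Expected species count in a without-replacement sample of *n* stems."""
    c = _clean_counts(counts)
    c = c[c > 0]
    if not np.allclose(c, np.round(c)):
        raise ValueError("rarefaction requires integer counts")
    total = int(round(c.sum()))
    n = int(n)
    if n < 1:
        raise ValueError("subsample size must be >= 1")
    if n > total:
        raise ValueError(f"subsample size {n} exceeds total count {total}")
    rest = total - c
    # P(species i absent) = C(N - N_i, n) / C(N, n), zero when N - N_i < n
    p_absent = np.zeros_like(c)
    ok = rest >= n
    p_absent[ok] = np.exp(_ln_choose(rest[ok], n) - _ln_choose(np.float64(total), n))
    return float((1.0 - p_absent).sum())


def rarefied_richness_mc(counts, n: int, n_draws: int = 10_000,
                         rng: np.random.Generator | None = None) -> tuple[float, float]:
    """Monte-Carlo rarefaction (mean, standard error) for cross-checking."""
    c = _clean_counts(counts).astype(int)
    pool = np.repeat(np.arange(c.size), c)
    if not 1 <= n <= pool.size:
        raise ValueError("subsample size out of range")
    rng = np.random.default_rng() if rng is None else rng
    richness = np.empty(n_draws)
    for d in range(n_draws):
        take = rng.choice(pool, size=n, replace=False)
        richness[d] = np.unique(take).size
    return float(richness.mean()), float(richness.std(ddof=1) / np.sqrt(n_draws))


def smallest_sample_size(community: pd.DataFrame) -> int:
    """Minimum per-plot total stem count; the default rarefaction depth."""
    validate_community(community)
    return int(community.sum(axis=1).min())


def validate_community(community: pd.DataFrame) -> None:
    """Check plot x species count-matrix invariants."""
    if community.shape[0] == 0 or community.shape[1] == 0:
        raise ValueError("community matrix is empty")
    if community.columns.duplicated().any():
        raise ValueError("duplicate species identifiers")
    if community.index.duplicated().any():
        raise ValueError("duplicate plot identifiers")
    vals = community.to_numpy()
    if np.any(vals < 0) or not np.allclose(vals, np.round(vals)):
        raise ValueError("counts must be nonnegative integers")
    totals = vals.sum(axis=1)
    if np.any(totals < 1):
        bad = list(community.index[totals < 1])
        raise ValueError(f"plots with zero stems: {bad}")


def read_community_csv(path) -> pd.DataFrame:
    """Plot x species matrix: first column plot_id, remaining columns counts."""
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df = df.astype(int)
    validate_community(df)
    return df


def write_community_csv(community: pd.DataFrame, path) -> None:
    community.to_csv(path, index_label="plot_id")
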