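"""End-to-end orchestration: inputs -> per-plot metrics -> correlations.

Takes the three standard inputs (ultrametric Newick tree, plot x species
community CSV, long soil CSV) or a simulation config, computes every
per-plot quantity the correlation layer consumes, and runs the standard
correlation grid. One top-level seed drives all randomisation; the null
model for each plot uses a substream derived from the plot's position so
results do not depend on evaluation order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .diversity import (rarefied_richness, shannon_effective,
                        smallest_sample_size, validate_community,
                        read_community_csv)
from .phylostructure import (MetricUndefinedError, NullModelSpec, faith_pd,
                             hill_pd_q1, rarefied_pd, ses_mpd)
from .soil import read_soil_csv, summarize_table
from .stats import correlation_table
from .simulate import SimulationConfig, simulate_dataset
from .tree import UltrametricTree

__all__ = [
    "RunConfig",
    "DEFAULT_PAIRS",
    "validate_inputs",
    "compute_plot_metrics",
    "run_pipeline",
]

#: the correlation grid: nutrient availability and heterogeneity (log scale)
#: against diversity and phylogenetic structure, plus the NRI-richness and
#: within-nutrient mean-CV checks, and the heterogeneity-phylodiversity pairs.
DEFAULT_PAIRS: tuple[tuple[str, str], ...] = tuple(
    (soil_var, response)
    for soil_var in ("AN_log_mean", "AN_log_cv", "EP_log_mean", "EP_log_cv")
    for response in ("R_TR", "e_H", "nri")
) + (
    ("nri", "richness"),
    ("AN_log_mean", "AN_log_cv"),
    ("EP_log_mean", "EP_log_cv"),
    ("EP_log_cv", "pd_rarefied"),
    ("EP_log_cv", "hill_pd_q1"),
)


@dataclass
class RunConfig:
    """Either the three input paths or a simulation config must be given."""

    tree_path: str | None = None
    community_path: str | None = None
    soil_path: str | None = None
    simulation: SimulationConfig | None = None
    rarefaction_n: int | str = "auto"
    n_randomizations: int = 9_999
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        paths = (self.tree_path, self.community_path, self.soil_path)
        if self.simulation is None and not all(paths):
            raise ValueError("provide either all three input paths or a simulation config")
        if self.simulation is not None and any(paths):
            raise ValueError("give input paths or a simulation config, not both")
        if self.rarefaction_n != "auto" and int(self.rarefaction_n) < 1:
            raise ValueError("rarefaction_n must be 'auto' or a positive integer")


def validate_inputs(tree: UltrametricTree, community: pd.DataFrame,
                    soil: pd.DataFrame) -> list[str]:
    """Cross-input consistency report; empty list means the pipeline may run."""
    problems: list[str] = []
    try:
        validate_community(community)
    except ValueError as exc:
        problems.append(f"community: {exc}")
    unknown = sorted(set(community.columns) - set(tree.tip_labels))
    if unknown:
        problems.append(f"species absent from tree: {unknown}")
    soil_plots = set(soil["plot_id"].astype(str))
    comm_plots = set(map(str, community.index))
    if soil_plots != comm_plots:
        only_soil = sorted(soil_plots - comm_plots)
        only_comm = sorted(comm_plots - soil_plots)
        problems.append(f"plot_id mismatch: only in soil {only_soil}, only in community {only_comm}")
    bad = soil.loc[~(soil["value_mg_per_kg"] > 0)]
    if len(bad):
        problems.append(
            "nonpositive soil values (log transform undefined) in plots "
            f"{sorted(bad['plot_id'].unique().tolist())}")
    return problems


def _plot_rng(seed: int, plot_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(917, plot_index)))


def compute_plot_metrics(tree: UltrametricTree, community: pd.DataFrame,
                         soil: pd.DataFrame | None = None, *,
                         rarefaction_n: int | str = "auto",
                         n_randomizations: int = 9_999,
                         seed: int = 0) -> pd.DataFrame:
    """Per-plot diversity, phylogenetic-structure, and soil summaries.

    Plots with fewer than two species get NaN MPD/SES/NRI (the metrics are
    undefined there); all other columns are always filled. Rows follow the
    sorted plot order regardless of input row order.
    """
    validate_community(community)
    community = community.sort_index().sort_index(axis=1)
    if rarefaction_n == "auto":
        rarefaction_n = smallest_sample_size(community)
    rarefaction_n = int(rarefaction_n)
    if rarefaction_n > smallest_sample_size(community):
        raise ValueError("rarefaction_n exceeds the smallest plot total")

    dist = tree.pairwise_distances()
    # counts aligned to the tree tip order for the branch-wise rarefaction
    aligned = community.reindex(columns=list(tree.tip_labels), fill_value=0)
    null = NullModelSpec(n_randomizations=n_randomizations)

    rows = []
    for p, (plot, row) in enumerate(community.iterrows()):
        counts = row.to_numpy()
        present = list(row.index[counts > 0])
        h, eh = shannon_effective(counts)
        tip_counts = aligned.loc[plot].to_numpy()
        rec = {
            "plot_id": plot,
            "richness": int((counts > 0).sum()),
            "total_stems": int(counts.sum()),
            "H": h,
            "e_H": eh,
            "R_TR": rarefied_richness(counts, rarefaction_n),
            "pd": faith_pd(present, tree),
            "pd_rarefied": rarefied_pd(tip_counts, tree, rarefaction_n),
            "hill_pd_q1": hill_pd_q1(tip_counts, tree),
        }
        try:
            res = ses_mpd(present, dist, null, rng=_plot_rng(seed, p))
            rec.update(mpd=res.mpd_obs, null_mean=res.null_mean,
                       null_sd=res.null_sd, ses=res.ses, nri=res.nri)
        except MetricUndefinedError:
            rec.update(mpd=np.nan, null_mean=np.nan, null_sd=np.nan,
                       ses=np.nan, nri=np.nan)
        rows.append(rec)
    metrics = pd.DataFrame(rows).set_index("plot_id")
    metrics["rarefaction_n"] = rarefaction_n
    metrics["seed"] = seed

    if soil is not None:
        summary = summarize_table(soil)
        summary.index = summary.index.astype(metrics.index.dtype)
        metrics = metrics.join(summary, how="left")
    return metrics


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run simulate/load -> per-plot metrics -> correlation grid.

    Returns (plot metrics, correlation table, run manifest) and, when
    ``config.out_dir`` is set, writes ``plot_metrics.csv``,
    ``correlations.csv`` and ``manifest.json`` there.
    """
    checksums = {}
    if config.simulation is not None:
        ds = simulate_dataset(config.simulation)
        tree, community, soil = ds.tree, ds.community, ds.soil
    else:
        tree = UltrametricTree.from_file(config.tree_path)
        community = read_community_csv(config.community_path)
        soil = read_soil_csv(config.soil_path)
        checksums = {name: _sha256(Path(p)) for name, p in
                     (("tree", config.tree_path),
                      ("community", config.community_path),
                      ("soil", config.soil_path))}

    problems = validate_inputs(tree, community, soil)
    if problems:
        raise ValueError("input validation failed:\n- " + "\n- ".join(problems))

    metrics = compute_plot_metrics(
        tree, community, soil,
        rarefaction_n=config.rarefaction_n,
        n_randomizations=config.n_randomizations,
        seed=config.seed,
    )
    correlations = correlation_table(metrics, DEFAULT_PAIRS)

    n_missing_nri = int(metrics["nri"].isna().sum())
    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "n_randomizations": config.n_randomizations,
        "rarefaction_n": int(metrics["rarefaction_n"].iloc[0]),
        "n_plots": int(len(metrics)),
        "n_species_pool": len(tree),
        "plots_with_undefined_nri": n_missing_nri,
        "input_checksums": checksums,
        "config": {k: (asdict(v) if isinstance(v, SimulationConfig) else v)
                   for k, v in asdict(config).items()},
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        metrics.to_csv(out / "plot_metrics.csv")
        correlations.to_csv(out / "correlations.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1),
                                           encoding="utf-8")
    return metrics, correlations, manifest
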