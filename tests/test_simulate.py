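"""Synthetic tree / soil / community generator."""

import numpy as np
import pandas as pd
import pytest

from phet.diversity import smallest_sample_size
from phet.phylostructure import NullModelSpec, ses_mpd
from phet.simulate import (SimulationConfig, simulate_community, simulate_dataset,
                           simulate_soil, simulate_tree, brownian_traits)
from phet.soil import summarize_table


class TestConfig:
    def test_defaults_emulate_study_design(self):
        cfg = SimulationConfig()
        assert cfg.n_plots == 39 and cfg.n_soil_replicates == 4
        assert cfg.pool_size == 156 and cfg.stems_range[0] == 84

    @pytest.mark.parametrize("kw", [dict(scenario="bogus"), dict(n_plots=2),
                                    dict(pool_size=1), dict(stems_range=(0, 10)),
                                    dict(ep_cv_range=(0.5, 0.1))])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(**kw)


class TestSimulateTree:
    def test_two_tip_cherry_unit_height(self):
        t = simulate_tree(2, np.random.default_rng(0))
        assert len(t) == 2
        assert t.height == pytest.approx(1.0)
        assert np.allclose(t.tip_depths, 1.0)

    def test_deterministic_newick(self):
        a = simulate_tree(156, np.random.default_rng(42)).to_newick()
        b = simulate_tree(156, np.random.default_rng(42)).to_newick()
        assert a == b

    def test_pool_size_validated(self):
        with pytest.raises(ValueError):
            simulate_tree(1)

    def test_cherry_count_matches_yule_expectation(self):
        # equal-rates trees have n/3 expected cherries
        rng = np.random.default_rng(5)
        counts = []
        for _ in range(300):
            t = simulate_tree(64, rng)
            counts.append(sum(
                1 for nd in t._dendropy.preorder_internal_node_iter()
                if all(c.is_leaf() for c in nd.child_nodes())))
        counts = np.array(counts)
        se = counts.std(ddof=1) / np.sqrt(counts.size)
        assert abs(counts.mean() - 64 / 3) <= 3 * se


class TestBrownianTraits:
    def test_standardised_and_deterministic(self):
        t = simulate_tree(50, np.random.default_rng(1))
        z1 = brownian_traits(t, np.random.default_rng(2))
        z2 = brownian_traits(t, np.random.default_rng(2))
        assert np.array_equal(z1, z2)
        assert z1.mean() == pytest.approx(0, abs=1e-12)
        assert z1.std() == pytest.approx(1, abs=1e-12)

    def test_phylogenetic_signal(self):
        # closely related tips carry more similar trait values
        t = simulate_tree(80, np.random.default_rng(3))
        d = t.pairwise_distances().values
        diffs = []
        for rep in range(30):
            z = brownian_traits(t, np.random.default_rng(100 + rep), standardize=False)
            dz = np.abs(z[:, None] - z[None, :])
            iu = np.triu_indices_from(d, 1)
            close = dz[iu][d[iu] < np.median(d[iu])].mean()
            far = dz[iu][d[iu] >= np.median(d[iu])].mean()
            diffs.append(far - close)
        assert np.mean(diffs) > 0


class TestSimulateSoil:
    def test_ranges_and_shape(self):
        cfg = SimulationConfig(seed=0)
        soil, truth = simulate_soil(cfg, np.random.default_rng(0))
        assert len(soil) == 39 * 2 * 4
        assert set(soil.nutrient) == {"AN", "EP"}
        assert (truth["EP_cv_true"].between(*cfg.ep_cv_range)).all()
        assert (truth["AN_mean_true"].between(*cfg.an_mean_range)).all()
        assert (soil["value_mg_per_kg"] > 0).all()

    def test_estimated_cv_recovers_realized_truth(self):
        cfg = SimulationConfig(n_plots=1000)
        soil, truth = simulate_soil(cfg, np.random.default_rng(3))
        s = summarize_table(soil)
        assert list(s.index) == list(truth.index)
        for nut in ("AN", "EP"):
            cvhat = s[f"{nut}_cv"].to_numpy()
            realized = truth[f"{nut}_cv_realized"].to_numpy()
            slope = np.polyfit(realized, cvhat, 1)[0]
            assert 0.9 <= slope <= 1.1
            assert np.corrcoef(cvhat, realized)[0, 1] > 0.8
            # the latent parameter is recovered with the expected small-sample
            # downward bias at 4 replicates
            latent_slope = np.polyfit(truth[f"{nut}_cv_true"], cvhat, 1)[0]
            assert 0.5 <= latent_slope <= 1.0

    def test_mean_cv_coupling_flag(self):
        cfg = SimulationConfig(n_plots=300, couple_mean_cv=True)
        _, truth = simulate_soil(cfg, np.random.default_rng(4))
        r = np.corrcoef(truth["EP_mean_true"], truth["EP_cv_true"])[0, 1]
        assert r > 0.3

    def test_deterministic(self):
        cfg = SimulationConfig(seed=9)
        s1, _ = simulate_soil(cfg, np.random.default_rng(9))
        s2, _ = simulate_soil(cfg, np.random.default_rng(9))
        pd.testing.assert_frame_equal(s1, s2)


class TestSimulateCommunity:
    def test_dataset_consistency(self, small_sim_config):
        ds = simulate_dataset(small_sim_config)
        assert set(ds.community.columns) <= set(ds.tree.tip_labels)
        assert list(ds.community.index) == list(ds.truth.index)
        assert set(ds.soil.plot_id) == set(ds.community.index)
        totals = ds.community.sum(axis=1)
        lo, hi = small_sim_config.stems_range
        assert ((totals >= lo) & (totals <= hi)).all()

    def test_bitwise_reproducibility(self, small_sim_config, tmp_path):
        d1, d2 = tmp_path / "run1", tmp_path / "run2"
        simulate_dataset(small_sim_config).write(d1)
        simulate_dataset(small_sim_config).write(d2)
        for name in ("tree.nwk", "community.csv", "soil.csv", "truth.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_neutral_ignores_soil(self):
        # richness under neutrality is uncorrelated with heterogeneity:
        # pool several seeds and expect a near-zero correlation
        rs = []
        for seed in range(4):
            ds = simulate_dataset(SimulationConfig(scenario="neutral", seed=seed))
            rich = (ds.community > 0).sum(axis=1)
            rs.append(np.corrcoef(ds.truth["EP_cv_realized"], rich)[0, 1])
        assert abs(np.mean(rs)) < 0.2

    def test_niche_coupling_direction(self):
        ds = simulate_dataset(SimulationConfig(scenario="niche_coupled", seed=1))
        rich = (ds.community > 0).sum(axis=1)
        r = np.corrcoef(ds.truth["EP_cv_realized"], rich)[0, 1]
        assert r > 0.4

    def test_unimodal_hump(self):
        # effective-area penalty: high heterogeneity loses species again
        mid, hi = [], []
        for seed in (1, 2, 3):
            ds = simulate_dataset(SimulationConfig(scenario="unimodal", seed=seed))
            cv = ds.truth["EP_cv_realized"]
            rich = (ds.community > 0).sum(axis=1)
            mid += list(rich[(cv > 0.4) & (cv < 0.7)])
            hi += list(rich[cv > 0.9])
        assert np.mean(mid) > np.mean(hi)

    def test_interaction_sign_drives_nri(self):
        # pin heterogeneity low (strong repulsion) vs high (relatedness
        # filtering) and compare mean NRI through the null model
        null = NullModelSpec(n_randomizations=99)
        means = {}
        for name, cv_range in (("low", (0.10, 0.12)), ("high", (1.10, 1.13))):
            cfg = SimulationConfig(n_plots=12, pool_size=64, stems_range=(60, 120),
                                   ep_cv_range=cv_range, seed=21)
            ds = simulate_dataset(cfg)
            dist = ds.tree.pairwise_distances()
            rng = np.random.default_rng(22)
            nri = [ses_mpd(list(r.index[r > 0]), dist, null, rng=rng).nri
                   for _, r in ds.community.iterrows()]
            means[name] = np.nanmean(nri)
        assert means["low"] < 0 < means["high"]

    def test_truth_records_scenario_and_latents(self, small_sim_config):
        ds = simulate_dataset(small_sim_config)
        for col in ("EP_cv_true", "EP_cv_realized", "plot_center",
                    "repulsion", "stems_target", "scenario"):
            assert col in ds.truth.columns
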