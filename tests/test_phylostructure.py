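"""MPD, the taxa-labels null, SES/NRI, rarefied PD, and Hill-PD."""

import itertools
import math

import numpy as np
import pytest

from phet.phylostructure import (MetricUndefinedError, NullModelSpec, faith_pd,
                                 hill_pd, hill_pd_q1, mpd, rarefied_pd,
                                 rarefied_pd_mc, ses_mpd)
from phet.simulate import simulate_tree
from phet.tree import parse_newick


def brute_force_label_permutation_null(dist, present):
    """Oracle: MPD of the plot's image under every pool-label permutation.

    Returns one value per distinct image (each image arises from equally
    many permutations, so the null distribution is uniform over them).
    """
    labels = list(dist.labels)
    present = set(present)
    images = set()
    for perm in itertools.permutations(labels):
        relabel = dict(zip(labels, perm))
        images.add(frozenset(relabel[s] for s in present))
    return np.array(sorted(mpd(img, dist) for img in images))


def enumerate_rarefied_pd(counts, tree, n):
    """Oracle: mean spanning branch sum over all C(N, n) subsamples."""
    labels = tree.tip_labels
    pool = [labels[sp] for sp, c in enumerate(counts) for _ in range(c)]
    vals = [tree.total_branch_length(set(pool[i] for i in combo))
            for combo in itertools.combinations(range(len(pool)), n)]
    return float(np.mean(vals))


class TestMPD:
    def test_single_pair(self, example_dist):
        assert mpd({"A", "B"}, example_dist) == pytest.approx(2.0)

    def test_three_species_hand_sum(self, example_dist):
        assert mpd({"A", "B", "C"}, example_dist) == pytest.approx(10 / 3)

    def test_abundance_invariance(self, example_dist):
        # presence/absence only: duplicated entries change nothing
        assert mpd(["A", "B", "C", "C", "C"], example_dist) == pytest.approx(10 / 3)

    def test_fewer_than_two_species_undefined(self, example_dist):
        with pytest.raises(MetricUndefinedError):
            mpd({"A"}, example_dist)

    def test_unknown_species(self, example_dist):
        with pytest.raises(KeyError):
            mpd({"A", "Z"}, example_dist)


class TestSesMpd:
    def test_exhaustive_three_species_pool(self, example_dist):
        # null over {A,B},{A,C},{B,C}: values {2, 4, 4}
        res = ses_mpd({"A", "B"}, example_dist, exhaustive=True)
        assert res.mpd_obs == pytest.approx(2.0)
        assert res.null_mean == pytest.approx(10 / 3)
        assert res.null_sd == pytest.approx(np.std([2, 4, 4], ddof=1))
        assert res.ses == pytest.approx(-1.1547005, abs=1e-6)
        assert res.nri == pytest.approx(+1.1547005, abs=1e-6)

    def test_full_pool_has_undefined_ses(self, example_dist):
        res = ses_mpd({"A", "B", "C"}, example_dist, exhaustive=True)
        assert math.isnan(res.ses) and math.isnan(res.nri)

    def test_nri_is_negative_ses(self):
        tree = simulate_tree(30, np.random.default_rng(4))
        dist = tree.pairwise_distances()
        rng = np.random.default_rng(5)
        for _ in range(5):
            plot = rng.choice(tree.tip_labels, size=8, replace=False)
            res = ses_mpd(plot, dist, NullModelSpec(n_randomizations=99), rng=rng)
            assert res.nri == -res.ses

    def test_sampled_null_matches_exhaustive_moments(self):
        tree = simulate_tree(10, np.random.default_rng(6))
        dist = tree.pairwise_distances()
        plot = tree.tip_labels[:4]
        exact = ses_mpd(plot, dist, exhaustive=True)
        approx = ses_mpd(plot, dist, NullModelSpec(n_randomizations=4000),
                         rng=np.random.default_rng(7))
        assert approx.null_mean == pytest.approx(exact.null_mean, rel=0.05)
        assert approx.null_sd == pytest.approx(exact.null_sd, rel=0.10)

    def test_mean_ses_near_zero_under_random_assembly(self):
        # random same-size draws from the pool are exactly the null's model
        tree = simulate_tree(40, np.random.default_rng(8))
        dist = tree.pairwise_distances()
        rng = np.random.default_rng(9)
        null = NullModelSpec(n_randomizations=199)
        ses = np.array([
            ses_mpd(rng.choice(tree.tip_labels, size=8, replace=False),
                    dist, null, rng=rng).ses
            for _ in range(150)
        ])
        assert abs(ses.mean()) <= 3 * ses.std(ddof=1) / math.sqrt(ses.size)

    def test_clustered_and_dispersed_plots_have_signed_nri(self):
        # two clades of 8: within-clade plots cluster, cross-clade plots disperse
        tips_a = ",".join(f"a{i}:1" for i in range(8))
        tips_b = ",".join(f"b{i}:1" for i in range(8))
        tree = parse_newick(f"(({tips_a}):7,({tips_b}):7);")
        dist = tree.pairwise_distances()
        rng = np.random.default_rng(10)
        null = NullModelSpec(n_randomizations=199)
        within = np.mean([
            ses_mpd([f"a{i}" for i in rng.choice(8, 4, replace=False)],
                    dist, null, rng=rng).nri
            for _ in range(20)
        ])
        across = np.mean([
            ses_mpd([f"a{i}" for i in rng.choice(8, 2, replace=False)]
                    + [f"b{i}" for i in rng.choice(8, 2, replace=False)],
                    dist, null, rng=rng).nri
            for _ in range(20)
        ])
        assert within > 0 > across


class TestFaithPD:
    def test_full_set(self, example_tree):
        assert faith_pd(["A", "B", "C"], example_tree) == pytest.approx(5.0)

    def test_single_tip_root_path(self, example_tree):
        assert faith_pd(["B"], example_tree) == pytest.approx(2.0)


class TestRarefiedPD:
    def test_hand_example(self, example_tree):
        # counts (A:2, B:1, C:0), n=2: branches contribute 1 + 2/3 + 1 + 0
        assert rarefied_pd([2, 1, 0], example_tree, 2) == pytest.approx(8 / 3)

    def test_full_sample_equals_faith_pd(self, example_tree):
        counts = [2, 1, 0]
        assert rarefied_pd(counts, example_tree, 3) == pytest.approx(
            faith_pd(["A", "B"], example_tree))

    def test_matches_enumeration(self):
        tree = simulate_tree(6, np.random.default_rng(11))
        counts = [2, 1, 0, 3, 1, 1]
        for n in range(1, sum(counts) + 1):
            assert rarefied_pd(counts, tree, n) == pytest.approx(
                enumerate_rarefied_pd(counts, tree, n), abs=1e-10)

    def test_matches_monte_carlo(self):
        tree = simulate_tree(15, np.random.default_rng(12))
        rng = np.random.default_rng(13)
        counts = rng.integers(0, 30, size=15)
        counts[0] = max(counts[0], 1)
        n = int(counts.sum() // 3)
        analytic = rarefied_pd(counts, tree, n)
        mc_mean, mc_se = rarefied_pd_mc(counts, tree, n, n_draws=2000, rng=rng)
        assert abs(analytic - mc_mean) <= 3 * mc_se

    def test_monotone_in_n(self, example_tree):
        counts = [5, 3, 2]
        vals = [rarefied_pd(counts, example_tree, n) for n in range(1, 11)]
        assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_out_of_range(self, example_tree):
        with pytest.raises(ValueError):
            rarefied_pd([1, 1, 1], example_tree, 4)


class TestHillPD:
    def test_single_species_is_one(self, example_tree):
        assert hill_pd_q1([0, 5, 0], example_tree) == pytest.approx(1.0)

    def test_star_tree_reduces_to_shannon(self):
        from phet.diversity import shannon_effective
        tree = parse_newick("(A:3,B:3,C:3,D:3);")
        counts = [5, 1, 2, 9]
        _, eh = shannon_effective(counts)
        assert hill_pd_q1(counts, tree) == pytest.approx(eh, rel=1e-9)

    def test_equal_counts_value_frozen_from_general_q_oracle(self, example_tree):
        # branch sum: T-bar = 2, exponent = 1.73513/2; cross-checked below
        # against the general-q formula approaching q = 1
        val = hill_pd_q1([1, 1, 1], example_tree)
        assert val == pytest.approx(2.3811016, abs=1e-6)
        for q in (1 + 1e-6, 1 - 1e-6):
            assert hill_pd([1, 1, 1], example_tree, q) == pytest.approx(val, rel=1e-5)

    def test_replication_invariance(self, random_tree):
        rng = np.random.default_rng(14)
        counts = rng.integers(0, 9, size=len(random_tree))
        counts[2] = max(counts[2], 1)
        v1 = hill_pd_q1(counts, random_tree)
        v3 = hill_pd_q1(3 * counts, random_tree)
        assert v3 == pytest.approx(v1, rel=1e-12)
        assert v1 >= 1.0

    def test_all_zero_rejected(self, example_tree):
        with pytest.raises(ValueError):
            hill_pd_q1([0, 0, 0], example_tree)


class TestExhaustiveNullEqualsBruteForce:
    @pytest.mark.parametrize("pool_size, k", [(5, 2), (6, 3), (7, 3)])
    def test_small_pools(self, pool_size, k):
        tree = simulate_tree(pool_size, np.random.default_rng(pool_size))
        dist = tree.pairwise_distances()
        plot = tree.tip_labels[:k]
        res = ses_mpd(plot, dist, exhaustive=True)
        brute = brute_force_label_permutation_null(dist, plot)
        assert res.null_mean == pytest.approx(brute.mean(), abs=1e-12)
        assert res.null_sd == pytest.approx(brute.std(ddof=1), rel=1e-9)
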