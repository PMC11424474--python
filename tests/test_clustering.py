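"""Classification, nearest-neighbour pairing and the shuffle Monte Carlo test."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spinisi import (
    ClusteringConfig,
    classify_spine,
    derive_threshold,
    monte_carlo_test,
    nearest_neighbor_pairs,
    pair_fractions,
    shuffle_deltas,
)
from spinisi.clustering import SpinePair, classify_codes, pair_metric_counts


def brute_force_pairs(positions, d_min=1.0, d_max=3.5):
    """All-pairs oracle: per-spine argmin distance, dedupe, filter.

    Equidistant ties break toward the neighbour with the smaller position,
    mirroring the production rule.
    """
    positions = np.asarray(positions, dtype=float)
    n = positions.size
    found = {}
    for i in range(n):
        best, best_d = None, np.inf
        for j in range(n):
            if j == i:
                continue
            d = abs(positions[i] - positions[j])
            if d < best_d or (d == best_d and positions[j] < positions[best]):
                best, best_d = j, d
        if best is None:
            continue
        key = (min(i, best), max(i, best))
        found[key] = best_d
    return {
        (a, b, d) for (a, b), d in found.items() if d_min <= d <= d_max
    }


def summary_frame(positions, delta_bars, dendrite_id=0):
    return pd.DataFrame(
        {
            "dendrite_id": dendrite_id,
            "spine_id": np.arange(len(positions)),
            "position_um": positions,
            "delta_bar": delta_bars,
            "persistent": True,
        }
    )


class TestClassification:
    @pytest.mark.parametrize(
        "delta,expected",
        [
            (0.20, "increasing"),
            (-0.20, "decreasing"),
            (0.14, "stable"),
            (-0.14, "stable"),
            (0.0, "stable"),
        ],
    )
    def test_threshold_rule(self, delta, expected):
        assert classify_spine(delta, tau=0.14) == expected

    def test_undefined_change_rejected(self):
        with pytest.raises(ValueError):
            classify_spine(float("nan"))

    def test_codes_match_labels(self):
        deltas = np.array([-0.5, -0.14, 0.0, 0.14, 0.5])
        assert list(classify_codes(deltas, 0.14)) == [-1, 0, 0, 0, 1]


class TestDeriveThreshold:
    def test_sample_standard_deviation(self):
        assert derive_threshold([-0.1, 0.1]) == pytest.approx(
            np.sqrt(0.02), rel=1e-12
        )

    def test_degenerate_spread_falls_back(self):
        with pytest.warns(UserWarning, match="zero spread"):
            assert derive_threshold([0.3, 0.3, 0.3]) == 0.14

    def test_insufficient_data_falls_back(self):
        with pytest.warns(UserWarning, match="fewer than two"):
            assert derive_threshold([0.1]) == 0.14

    def test_recovers_generating_sd(self):
        rng = np.random.default_rng(0)
        tau = derive_threshold(rng.normal(0, 0.14, size=10_000))
        assert 0.135 <= tau <= 0.145


class TestNearestNeighborPairs:
    def test_small_example(self):
        pairs = {
            (p.a, p.b, p.distance)
            for p in nearest_neighbor_pairs([0.0, 2.0, 3.0])
        }
        assert pairs == {(0, 1, 2.0), (1, 2, 1.0)}

    def test_too_close_excluded(self):
        assert nearest_neighbor_pairs([0.0, 0.5]) == []

    def test_too_far_excluded(self):
        assert nearest_neighbor_pairs([0.0, 5.0]) == []

    def test_boundary_distances_retained(self):
        pairs = nearest_neighbor_pairs([0.0, 1.0])
        assert len(pairs) == 1 and pairs[0].distance == 1.0
        pairs = nearest_neighbor_pairs([0.0, 3.5])
        assert len(pairs) == 1 and pairs[0].distance == 3.5

    def test_single_spine_no_pairs(self):
        assert nearest_neighbor_pairs([1.0]) == []

    def test_tie_breaks_toward_smaller_position(self):
        # spine 1 is equidistant from 0 and 2 and must pair leftward; spine 2
        # prefers spine 3, so the (1, 2) pair exists only under a rightward
        # tie-break
        pairs = {
            (p.a, p.b) for p in nearest_neighbor_pairs([0.0, 2.0, 4.0, 5.0])
        }
        assert pairs == {(0, 1), (2, 3)}

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = rng.integers(2, 13)
            if rng.random() < 0.5:
                grid = np.arange(0, 30.25, 0.25)
                positions = rng.choice(grid, size=n, replace=False)
            else:
                positions = rng.uniform(0, 25, size=n)
            got = {
                (p.a, p.b, p.distance)
                for p in nearest_neighbor_pairs(positions)
            }
            assert got == brute_force_pairs(positions)


class TestPairFractions:
    def test_all_increasing(self):
        pairs = [SpinePair(i, i + 1, 2.0) for i in range(4)]
        codes = np.ones(5, dtype=int)
        assert pair_fractions(pairs, codes) == {
            "both_increased": 100.0,
            "both_decreased": 0.0,
            "same_direction": 100.0,
            "opposite_direction": 0.0,
        }

    def test_single_opposite_pair(self):
        pairs = [SpinePair(0, 1, 2.0)]
        fractions = pair_fractions(pairs, np.array([1, -1]))
        assert fractions["opposite_direction"] == 100.0
        assert fractions["same_direction"] == 0.0

    def test_mixed_enumeration(self):
        # pairs classified (inc,inc), (dec,dec), (inc,stable), (inc,dec)
        codes = np.array([1, 1, -1, -1, 1, 0, 1, -1])
        pairs = [
            SpinePair(0, 1, 2.0),
            SpinePair(2, 3, 2.0),
            SpinePair(4, 5, 2.0),
            SpinePair(6, 7, 2.0),
        ]
        assert pair_fractions(pairs, codes) == {
            "both_increased": 25.0,
            "both_decreased": 25.0,
            "same_direction": 50.0,
            "opposite_direction": 25.0,
        }

    def test_no_pairs_rejected(self):
        with pytest.raises(ValueError):
            pair_fractions([], np.array([1]))

    @given(codes=st.lists(st.sampled_from([-1, 0, 1]), min_size=2, max_size=9))
    def test_same_direction_decomposition(self, codes):
        codes = np.array(codes)
        pairs = [
            SpinePair(i, i + 1, 2.0) for i in range(len(codes) - 1)
        ]
        counts = pair_metric_counts(pairs, codes)
        assert counts["same_direction"] == (
            counts["both_increased"] + counts["both_decreased"]
        )
        assert (
            counts["same_direction"] + counts["opposite_direction"]
            <= len(pairs)
        )


class TestShuffle:
    def test_preserves_multiset_and_class_counts(self):
        rng = np.random.default_rng(1)
        df = pd.concat(
            [
                summary_frame([0, 1.5, 3, 4.5], [-0.5, 0.3, 0.0, 0.2], 0),
                summary_frame([0, 2.0, 4.0], [0.9, -0.9, 0.1], 1),
            ],
            ignore_index=True,
        )
        shuffled = shuffle_deltas(df, rng)
        for dend_id, group in df.groupby("dendrite_id"):
            got = shuffled[shuffled["dendrite_id"] == dend_id]["delta_bar"]
            assert sorted(got) == sorted(group["delta_bar"])

    def test_identical_values_are_a_noop(self):
        rng = np.random.default_rng(2)
        df = summary_frame([0, 1.5, 3.0], [0.5, 0.5, 0.5])
        shuffled = shuffle_deltas(df, rng)
        pd.testing.assert_frame_equal(shuffled, df)

    def test_single_spine_unchanged(self):
        rng = np.random.default_rng(3)
        df = summary_frame([1.0], [0.4])
        pd.testing.assert_frame_equal(shuffle_deltas(df, rng), df)

    def test_permutations_are_uniform(self):
        rng = np.random.default_rng(4)
        df = summary_frame([0, 1.5, 3.0], [1.0, 2.0, 3.0])
        counts = {}
        for _ in range(10_000):
            order = tuple(shuffle_deltas(df, rng)["delta_bar"])
            counts[order] = counts.get(order, 0) + 1
        assert len(counts) == 6
        for freq in counts.values():
            assert abs(freq / 10_000 - 1 / 6) < 0.02


class TestMonteCarlo:
    def test_segregated_decreases_match_exhaustive_tail(self):
        # 6 contiguous decreasing spines then 6 increasing, spacing 1.25 um:
        # all 11 adjacent pairs retained, observed both-decreased count 5.
        positions = np.arange(12) * 1.25
        deltas = [-0.5] * 6 + [0.5] * 6
        df = summary_frame(positions, deltas)
        # exact tail: arrangements of 6 decreases with >= 5 adjacent
        # dec-dec pairs among C(12,6) = 924 equally likely arrangements
        exact = 0
        for dec_set in itertools.combinations(range(12), 6):
            dec = np.zeros(12, dtype=bool)
            dec[list(dec_set)] = True
            if np.sum(dec[:-1] & dec[1:]) >= 5:
                exact += 1
        exact_p = exact / 924
        assert exact_p == pytest.approx(7 / 924)
        config = ClusteringConfig(n_pools=10_000, seed=3)
        result = monte_carlo_test(df, config)
        assert result.observed_counts["both_decreased"] == 5
        assert result.tails["both_decreased"] == "upper"
        assert result.p_values["both_decreased"] <= 0.01
        assert abs(result.p_values["both_decreased"] - exact_p) < 0.004

    def test_determinism_given_seed(self):
        df = summary_frame(
            np.arange(8) * 1.5, [-0.3, 0.2, -0.4, 0.0, 0.5, -0.2, 0.1, 0.3]
        )
        config = ClusteringConfig(n_pools=500, seed=11)
        a = monte_carlo_test(df, config)
        b = monte_carlo_test(df, config)
        assert a.p_values == b.p_values
        assert all(
            np.array_equal(a.shuffled[m], b.shuffled[m]) for m in a.shuffled
        )

    def test_observed_below_chance_uses_lower_tail(self):
        # strict alternation of inc/dec at 1.5 um spacing: zero same-direction
        # pairs, far below the shuffle median -> auto picks the lower tail
        positions = np.arange(10) * 1.5
        deltas = [0.5 if i % 2 else -0.5 for i in range(10)]
        result = monte_carlo_test(
            summary_frame(positions, deltas),
            ClusteringConfig(n_pools=2000, seed=5),
        )
        assert result.tails["same_direction"] == "lower"
        assert result.p_values["same_direction"] < 0.05
        assert result.tails["opposite_direction"] == "upper"

    def test_add_one_correction_bounds_p_away_from_zero(self):
        positions = np.arange(12) * 1.25
        deltas = [-0.5] * 6 + [0.5] * 6
        df = summary_frame(positions, deltas)
        plain = monte_carlo_test(df, ClusteringConfig(n_pools=200, seed=7))
        corrected = monte_carlo_test(
            df, ClusteringConfig(n_pools=200, seed=7, include_observed=True)
        )
        for metric in plain.p_values:
            assert corrected.p_values[metric] >= 1 / 201
            assert corrected.p_values[metric] >= plain.p_values[metric]

    def test_no_pairs_anywhere_rejected(self):
        df = summary_frame([0.0, 0.5], [0.5, -0.5])  # below d_min
        with pytest.raises(ValueError, match="no retained pairs"):
            monte_carlo_test(df, ClusteringConfig(n_pools=100, seed=1))

    def test_small_pool_count_warns(self):
        with pytest.warns(UserWarning, match="resolution"):
            ClusteringConfig(n_pools=50)

    def test_nonpersistent_spines_ignored(self):
        df = summary_frame(np.arange(6) * 1.5, [0.5, -0.5, 0.3, -0.3, 0.2, -0.2])
        df.loc[5, "persistent"] = False
        df.loc[5, "delta_bar"] = np.nan
        result = monte_carlo_test(df, ClusteringConfig(n_pools=100, seed=2))
        assert result.n_pairs == 5 - 1  # 5 persistent spines, adjacent pairs
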