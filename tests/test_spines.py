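"""Per-spine metrics: normalization, change score, turnover, density."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spinisi import (
    SpineSimConfig,
    baseline_size,
    density_table,
    normalized_change,
    paired_session_average,
    raw_spine_size,
    simulate_spine_dataset,
    size_change_table,
    spine_density,
    turnover_rates,
    turnover_table,
)
from spinisi.spines import DegenerateIntensityError

from conftest import make_dataset


class TestRawSpineSize:
    @pytest.mark.parametrize(
        "spine,shaft,bg,expected",
        [(10, 6, 2, 2.0), (2, 6, 2, 0.0), (6, 10, 2, 0.5)],
    )
    def test_shaft_normalization(self, spine, shaft, bg, expected):
        assert raw_spine_size(spine, shaft, bg) == pytest.approx(expected)

    def test_below_background_clips_to_zero(self):
        assert raw_spine_size(1, 6, 2) == 0.0

    def test_degenerate_denominator_raises(self):
        with pytest.raises(DegenerateIntensityError):
            raw_spine_size(5, 4, 4)
        with pytest.raises(DegenerateIntensityError):
            raw_spine_size(5, 3, 4)


class TestNormalizedChange:
    @pytest.mark.parametrize(
        "v_d,v_base,expected",
        [(1.3, 1.3, 0.0), (0.0, 0.7, -1.0), (3.0, 1.0, 0.5), (0.7, 0.0, 1.0)],
    )
    def test_closed_form(self, v_d, v_base, expected):
        assert normalized_change(v_d, v_base) == pytest.approx(expected)

    def test_both_zero_undefined(self):
        with pytest.raises(ValueError):
            normalized_change(0.0, 0.0)

    def test_negative_sizes_rejected(self):
        with pytest.raises(ValueError):
            normalized_change(-0.1, 1.0)

    @given(
        v_d=st.floats(0, 1e6, allow_nan=False),
        v_base=st.floats(0, 1e6, allow_nan=False),
    )
    def test_bounded_and_antisymmetric(self, v_d, v_base):
        if v_d + v_base == 0:
            return
        delta = normalized_change(v_d, v_base)
        assert -1.0 <= delta <= 1.0
        assert normalized_change(v_base, v_d) == pytest.approx(-delta)

    @given(
        v_base=st.floats(0.01, 1e3),
        v_lo=st.floats(0, 1e3),
        v_hi=st.floats(0, 1e3),
    )
    def test_monotone_in_current_size(self, v_base, v_lo, v_hi):
        if v_lo == v_hi:
            return
        lo, hi = sorted([v_lo, v_hi])
        assert normalized_change(lo, v_base) < normalized_change(hi, v_base)


class TestBaselineSize:
    def test_mean_over_present_baseline_sessions(self):
        sizes = np.array([1.0, 1.2, 9.0, 9.0])
        mask = np.array([True, True, False, False])
        assert baseline_size(sizes, mask) == pytest.approx(1.1)

    def test_single_session(self):
        sizes = np.array([np.nan, 0.8, 9.0])
        mask = np.array([True, True, False])
        assert baseline_size(sizes, mask) == pytest.approx(0.8)

    def test_absent_everywhere_is_nan(self):
        sizes = np.array([np.nan, np.nan, 2.0])
        mask = np.array([True, True, False])
        assert np.isnan(baseline_size(sizes, mask))


class TestTurnover:
    @pytest.mark.parametrize(
        "n_prev,n_added,n_elim,expected",
        [
            (10, 2, 1, (0.2, 0.1, 0.3)),
            (5, 0, 0, (0.0, 0.0, 0.0)),
            (4, 0, 4, (0.0, 1.0, 1.0)),
        ],
    )
    def test_rates(self, n_prev, n_added, n_elim, expected):
        add, elim, turn = turnover_rates(n_prev, n_added, n_elim)
        assert (add, elim) == pytest.approx(expected[:2])
        assert turn == add + elim  # exact identity, not approx

    def test_no_previous_spines_raises(self):
        with pytest.raises(ValueError):
            turnover_rates(0, 1, 0)

    def test_table_counts_additions_and_eliminations(self):
        # spine 1 eliminated on day 1; spine 2 added on day 1
        dataset = make_dataset(
            [
                (2.0, [True, True, True, True], [1.0] * 4),
                (4.0, [True, True, False, False], [1.0] * 4),
                (6.0, [False, False, True, True], [1.0] * 4),
            ]
        )
        table = turnover_table(dataset).set_index("day")
        assert table.loc[0, "n_added"] == 0
        assert table.loc[1, "n_prev"] == 2
        assert table.loc[1, "n_added"] == 1
        assert table.loc[1, "n_eliminated"] == 1
        assert table.loc[1, "turnover"] == pytest.approx(1.0)
        assert table.loc[2, "n_prev"] == 2


class TestDensity:
    def test_count_over_length(self):
        dataset = make_dataset(
            [(i * 2.0, [True] * 4, [1.0] * 4) for i in range(12)],
            length=24.0,
        )
        assert spine_density(dataset.dendrites[0], 0) == pytest.approx(0.5)

    def test_empty_dendrite(self):
        dataset = make_dataset([(2.0, [False] * 4, [1.0] * 4)])
        assert spine_density(dataset.dendrites[0], 0) == 0.0

    def test_unit_rescale_invariance(self):
        positions = [2.0, 5.0, 9.0]
        for scale in (1.0, 10.0):
            dataset = make_dataset(
                [(p * scale, [True] * 4, [1.0] * 4) for p in positions],
                length=30.0 * scale,
            )
            density = density_table(dataset)["density"].iloc[0]
            assert density * scale == pytest.approx(0.1)


class TestPairedSessionAverage:
    def test_adjacent_pair_means(self):
        series = pd.Series({-3: 0.1, -2: 0.3})
        out = paired_session_average(series)
        assert out.to_dict() == {"-3/-2": pytest.approx(0.2)}

    def test_constant_series_stays_constant(self):
        series = pd.Series({d: 0.7 for d in (-3, -2, -1, 0, 1, 2, 3, 4)})
        out = paired_session_average(series)
        assert len(out) == 4
        assert np.allclose(out.to_numpy(), 0.7)

    def test_odd_leftover_dropped_with_warning(self):
        series = pd.Series({1: 0.0, 2: 1.0, 3: 5.0})
        with pytest.warns(UserWarning, match="leftover"):
            out = paired_session_average(series)
        assert list(out.index) == ["1/2"]

    def test_odd_leftover_kept_on_request(self):
        series = pd.Series({1: 0.0, 2: 1.0, 3: 5.0})
        out = paired_session_average(series, leftover="keep")
        assert out["3"] == pytest.approx(5.0)


class TestSizeChangeTable:
    def test_deltas_and_window_average(self, simple_dataset):
        table = size_change_table(simple_dataset)
        spines = table.spines.set_index("spine_id")
        # spine 0: baseline 1.0, post 1.5 -> delta (1.5-1)/(2.5) = 0.2
        assert spines.loc[0, "delta_bar"] == pytest.approx(0.2)
        assert spines.loc[1, "delta_bar"] == pytest.approx(-1 / 3)
        assert spines.loc[2, "delta_bar"] == pytest.approx(0.0)
        assert spines["persistent"].all()

    def test_baseline_session_deltas_reference_baseline_mean(self):
        dataset = make_dataset([(2.0, [True] * 4, [0.8, 1.2, 1.0, 1.0])])
        table = size_change_table(dataset)
        changes = table.changes.set_index("day")
        # baseline mean 1.0; day -1 delta = (0.8-1)/(1.8)
        assert changes.loc[-1, "delta"] == pytest.approx(-0.2 / 1.8)
        assert changes.loc[0, "delta"] == pytest.approx(0.2 / 2.2)

    def test_absent_in_window_excluded(self):
        dataset = make_dataset(
            [
                (2.0, [True, True, True, False], [1.0] * 4),
                (4.0, [False, True, True, True], [1.0] * 4),
                (6.0, [True, True, True, True], [1.0] * 4),
            ]
        )
        table = size_change_table(dataset)
        spines = table.spines.set_index("spine_id")
        assert not spines.loc[0, "persistent"]  # absent day 2
        assert not spines.loc[1, "persistent"]  # absent baseline day -1
        assert spines.loc[2, "persistent"]
        assert len(table.excluded) == 2

    def test_pipeline_recovers_generator_truth_without_noise(self):
        config = SpineSimConfig(
            n_dendrites=20, noise_cv=0.0, neighbor_rho=0.5,
            global_shift=-0.05, seed=42,
        )
        dataset = simulate_spine_dataset(config)
        table = size_change_table(dataset)
        persistent = table.spines[table.spines["persistent"]]
        truth = persistent["true_change"].to_numpy()
        measured = persistent["delta_bar"].to_numpy()
        mask = ~np.isnan(truth)  # spines added mid-experiment have no truth
        assert mask.sum() > 50
        assert np.max(np.abs(measured[mask] - truth[mask])) < 1e-9
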