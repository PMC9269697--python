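import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mobiso.features import (
    INDOOR_FEATURE_COLUMNS,
    OUTDOOR_FEATURE_COLUMNS,
    Window,
    _circular_mean_deg,
    accel_statistics,
    indoor_feature_rows,
    make_windows,
    modal_category,
    outdoor_feature_rows,
    window_mobility,
)
from mobiso.io_formats import IndoorSample
from mobiso.synth import SynthConfig, UserProfile, generate_traces


def indoor_stream(duration_s, rate_hz=1.6, accel=None, t0=1_651_482_000.0):
    """Plain indoor stream at a fixed rate with constant or supplied accel."""
    times = t0 + np.arange(0.0, duration_s, 1.0 / rate_hz)
    out = []
    for i, t in enumerate(times):
        a = accel[i] if accel is not None else (0.0, 0.0, 9.81)
        out.append(
            IndoorSample(
                tag_id="tag01",
                timestamp=float(t),
                success=True,
                coords=(12000.0, 9000.0, 1000.0),
                accel=tuple(a),
                status=0,
                zones=((2, "zone2"),),
            )
        )
    return out


class TestMakeWindows:
    def test_35s_at_1p6hz_gives_three_complete_windows(self):
        windows = make_windows(indoor_stream(35.0), length=10.0)
        assert len(windows) == 3
        assert all(w.end - w.start == 10.0 for w in windows)

    def test_outdoor_10min_sampling_40min_window_gives_4_samples(self):
        stream = [(1_651_482_000.0 + 600.0 * i,) for i in range(24)]
        windows = make_windows(stream, length=2400.0, domain="outdoor")
        assert len(windows) == 6
        assert all(len(w.samples) == 4 for w in windows)

    def test_empty_input_gives_empty_sequence(self):
        assert make_windows([], length=10.0) == []

    def test_unsorted_input_rejected(self):
        stream = [(2.0,), (1.0,)]
        with pytest.raises(ValueError):
            make_windows(stream, length=10.0)

    def test_windows_are_contiguous_and_anchored_at_first_sample(self):
        stream = indoor_stream(40.0)
        windows = make_windows(stream, length=10.0)
        assert windows[0].start == stream[0].timestamp
        for a, b in zip(windows, windows[1:]):
            assert b.start == a.end

    def test_full_trailing_window_kept(self):
        stream = [(float(i),) for i in range(40)]  # 1 Hz, 40 s
        windows = make_windows(stream, length=10.0)
        assert len(windows) == 4


class TestAccelStatistics:
    def window_from(self, accel_rows):
        t0 = 0.0
        samples = tuple(
            IndoorSample(
                tag_id="t",
                timestamp=t0 + 0.1 * i,
                success=True,
                coords=(0.0, 0.0, 0.0),
                accel=tuple(a),
                status=0,
            )
            for i, a in enumerate(accel_rows)
        )
        return Window(user_id=0, start=t0, end=t0 + 10.0, samples=samples)

    def test_constant_signal_degenerate_conventions(self):
        c = 2.5
        stats = accel_statistics(self.window_from([(c, c, c)] * 8))
        assert stats["accel_std"] == 0.0
        assert stats["accel_skewness"] == 0.0
        assert stats["accel_kurtosis"] == 0.0
        assert stats["accel_n_peaks"] == 0
        assert stats["accel_sma"] == pytest.approx(3 * abs(c))
        assert stats["accel_avg_resultant"] == pytest.approx(np.sqrt(3) * abs(c))

    def test_hand_computed_axis_statistics(self):
        # same series on each axis: per-axis stats equal the axis stats
        rows = [(v, v, v) for v in (1.0, 2.0, 3.0, 4.0)]
        stats = accel_statistics(self.window_from(rows))
        assert stats["accel_mean"] == pytest.approx(2.5)
        assert stats["accel_median"] == pytest.approx(2.5)
        assert stats["accel_std"] == pytest.approx(np.sqrt(1.25))  # population SD

    @given(
        data=st.lists(
            st.tuples(*[st.floats(-20, 20) for _ in range(3)]),
            min_size=3,
            max_size=40,
        )
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_energy_equals_resultant_second_moment(self, data):
        stats = accel_statistics(self.window_from(data))
        arr = np.array(data)
        second_moment = float((np.linalg.norm(arr, axis=1) ** 2).mean())
        assert stats["accel_energy"] == pytest.approx(second_moment, rel=1e-9)
        assert stats["accel_energy"] >= 0
        assert stats["accel_sma"] >= 0

    def test_single_sample_window_rejected(self):
        with pytest.raises(ValueError):
            accel_statistics(self.window_from([(0.0, 0.0, 9.8)]))

    def test_per_axis_variant_averages_to_pooled_value(self, rng):
        rows = [tuple(v) for v in rng.normal(0, 1, size=(12, 3))]
        w = self.window_from(rows)
        pooled = accel_statistics(w)
        per_axis = accel_statistics(w, average_axes=False)
        for key in ("accel_mean", "accel_std", "accel_skewness"):
            axis_mean = np.mean([per_axis[f"{key}_{ax}"] for ax in "xyz"])
            assert pooled[key] == pytest.approx(axis_mean, rel=1e-12)


class TestWindowMobility:
    def test_stationary_tag(self):
        w = Window(user_id=0, start=0.0, end=10.0, samples=((0.0,), (5.0,)))
        dist, speed = window_mobility(w, np.zeros((2, 2)))
        assert (dist, speed) == (0.0, 0.0)

    def test_straight_line(self):
        w = Window(user_id=0, start=0.0, end=10.0, samples=((0.0,), (5.0,)))
        dist, speed = window_mobility(w, np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert dist == pytest.approx(5.0)
        assert speed == pytest.approx(0.5)

    def test_speed_times_length_equals_distance(self, rng):
        pts = rng.normal(size=(16, 2))
        w = Window(
            user_id=0, start=0.0, end=10.0,
            samples=tuple((0.5 * i,) for i in range(16)),
        )
        dist, speed = window_mobility(w, pts)
        assert speed * 10.0 == pytest.approx(dist, rel=1e-12)

    def test_no_positions_flagged(self):
        w = Window(user_id=0, start=0.0, end=10.0, samples=())
        with pytest.raises(ValueError):
            window_mobility(w, None)


class TestModalCategory:
    @pytest.mark.parametrize(
        "values, mode",
        [(("A", "A", "B"), "A"), (("A", "B"), "A"), ((2, 1, 1, 2, 2), 2)],
    )
    def test_majority_and_tie_rule(self, values, mode):
        assert modal_category(values) == mode

    def test_matches_bruteforce_argmax(self, rng):
        draws = list(rng.integers(0, 5, size=1000))
        counts = {v: draws.count(v) for v in set(draws)}
        best = max(counts.values())
        winners = {v for v, c in counts.items() if c == best}
        assert modal_category(draws) in winners

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            modal_category([])


class TestFeatureTables:
    def test_one_hour_indoor_stream_gives_360_rows(self):
        rows = indoor_feature_rows(indoor_stream(3600.0), user_id=1)
        assert len(rows) == 360
        assert list(rows.columns) == list(INDOOR_FEATURE_COLUMNS)

    def test_24h_outdoor_stream_gives_36_rows(self):
        profile = UserProfile(
            user_id=1,
            indoor_places=(((12.0, 9.0), 1.0),),
            outdoor_places=(((61.47, 23.78), 1.0),),
        )
        traces = generate_traces([profile], SynthConfig(days=1, seed=0))
        rows = outdoor_feature_rows(traces.outdoor[1], user_id=1)
        assert len(rows) == 36
        assert list(rows.columns) == list(OUTDOOR_FEATURE_COLUMNS)

    def test_all_invalid_fixes_give_zero_rows(self):
        profile = UserProfile(
            user_id=1,
            indoor_places=(((12.0, 9.0), 1.0),),
            outdoor_places=(((61.47, 23.78), 1.0),),
        )
        traces = generate_traces([profile], SynthConfig(days=1, seed=0))
        import dataclasses

        invalid = [dataclasses.replace(s, valid=False) for s in traces.outdoor[1]]
        rows = outdoor_feature_rows(invalid, user_id=1)
        assert rows.empty

    def test_fix_to_fix_speed_agrees_for_uniform_sampling(self):
        profile = UserProfile(
            user_id=1,
            indoor_places=(((12.0, 9.0), 1.0),),
            outdoor_places=(((61.47, 23.78), 1.0),),
        )
        traces = generate_traces([profile], SynthConfig(days=1, seed=0))
        total = outdoor_feature_rows(traces.outdoor[1], user_id=1)
        fix = outdoor_feature_rows(
            traces.outdoor[1], user_id=1, speed_method="fix_to_fix"
        )
        # uniform 10-min spacing: mean segment speed ≈ window-total speed
        # up to the boundary segments a window excludes
        assert np.allclose(
            fix.avg_estimated_speed, total.avg_estimated_speed, rtol=0.5, atol=0.01
        )

    def test_distance_speed_identity_on_cohort(self, cohort):
        tab = cohort["indoor_tab"]
        np.testing.assert_allclose(
            tab.avg_speed * 10.0, tab.avg_distance, rtol=1e-9
        )

    def test_distance_speed_correlation_above_point9(self, cohort):
        tab = cohort["indoor_tab"]
        r = np.corrcoef(tab.avg_distance, tab.avg_speed)[0, 1]
        assert r > 0.9

    def test_schema_is_stable_across_runs(self, cohort):
        assert list(cohort["indoor_tab"].columns) == list(INDOOR_FEATURE_COLUMNS)
        assert list(cohort["outdoor_tab"].columns) == list(OUTDOOR_FEATURE_COLUMNS)
        assert (cohort["outdoor_tab"].avg_course >= 0).all()
        assert (cohort["outdoor_tab"].avg_course < 360).all()


class TestCircularMean:
    def test_wraps_across_north(self):
        assert _circular_mean_deg(np.array([350.0, 10.0])) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_plain_average_when_no_wrap(self):
        assert _circular_mean_deg(np.array([80.0, 100.0])) == pytest.approx(90.0)
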