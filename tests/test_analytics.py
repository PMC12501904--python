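from datetime import datetime, timedelta

import numpy as np
import pandas as pd
import pytest

from circalight.analytics import (
    DayWindow,
    ExposureSeries,
    detect_nonwear,
    mask_dim_cct,
    paired_t,
    post_hoc_power,
    weekly_summary,
)


def make_series(timestamps, lux, motion, cct=None, cs=None, wear=None):
    n = len(timestamps)
    df = pd.DataFrame(
        {
            "timestamp": pd.to_datetime(timestamps),
            "lux": np.asarray(lux, dtype=float),
            "cct": np.full(n, 4000.0) if cct is None else np.asarray(cct, float),
            "cs": np.full(n, 0.2) if cs is None else np.asarray(cs, float),
            "motion": np.asarray(motion, dtype=bool),
            "day_flag": DayWindow().contains(pd.to_datetime(pd.Series(timestamps))).to_numpy(),
            "wear_flag": np.ones(n, bool) if wear is None else np.asarray(wear, bool),
        }
    )
    return ExposureSeries("test", df)


def regular_times(start, n, cadence_min):
    return [start + timedelta(minutes=i * cadence_min) for i in range(n)]


def nonwear_oracle(series, day_h=2.0, night_h=4.0, tol=1.0):
    """O(n^2) re-derivation: from each unflagged start index, extend the
    window while the lux range (recomputed from scratch over the whole
    window) stays under tolerance and no motion occurs; flag maximal
    windows longer than the applicable threshold."""
    df = series.data
    lux = df["lux"].to_numpy(float)
    motion = df["motion"].to_numpy(bool)
    ts = pd.to_datetime(df["timestamp"])
    day = series.day_window.contains(ts).to_numpy()
    cadence_h = (ts.iloc[1] - ts.iloc[0]).total_seconds() / 3600.0
    flagged = []
    i = 0
    n = len(df)
    while i < n:
        if motion[i]:
            i += 1
            continue
        j = i
        while j + 1 < n:
            window = lux[i : j + 2]
            if motion[j + 1] or max(window) - min(window) >= tol:
                break
            j += 1
        duration = (j - i + 1) * cadence_h
        threshold = day_h if any(day[i : j + 1]) else night_h
        if duration > threshold:
            flagged.append((i, j))
        i = j + 1
    return flagged


class TestDetectNonwear:
    def test_three_hour_daytime_flat_episode_is_flagged(self):
        start = datetime(2024, 3, 4, 8, 0)
        times = regular_times(start, 12 * 6, 10)  # 12 h at 10 min
        rng = np.random.default_rng(0)
        lux = 200 + 50 * rng.random(72)
        motion = rng.random(72) < 0.5
        flat = slice(18, 36)  # 11:00-14:00
        lux[flat] = 80.0
        motion[flat] = False
        series = make_series(times, lux, motion)
        intervals = detect_nonwear(series)
        assert intervals == [(18, 35)]

    def test_three_hour_night_flat_episode_is_below_threshold(self):
        start = datetime(2024, 3, 4, 22, 0)
        times = regular_times(start, 6 * 6, 10)  # 22:00-04:00
        lux = np.full(36, 0.5)
        lux[:9] = 5 + np.arange(9) * 3.0  # varying before midnight flat
        motion = np.zeros(36, bool)
        motion[:9] = True
        series = make_series(times, lux, motion)
        # flat run is 27 samples = 4.5 h -> flagged; trim to 3 h: not
        intervals = detect_nonwear(series)
        assert intervals == [(9, 35)]
        short = make_series(times[:27], lux[:27], motion[:27])
        assert detect_nonwear(short) == []  # 3 h at night < 4 h threshold

    def test_matches_brute_force_oracle_on_random_logs(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            start = datetime(2024, 3, 4, 0, 0)
            times = regular_times(start, n, 15)
            # blocky signal: long flat stretches at random levels
            levels = rng.choice([0.4, 50.0, 300.0, 2000.0], size=10)
            lux = np.repeat(levels, n // 10)
            lux += rng.random(n) * 0.2  # sub-tolerance jitter
            motion = rng.random(n) < 0.1
            series = make_series(times, lux, motion)
            assert detect_nonwear(series) == nonwear_oracle(series)

    def test_coarse_cadence_rejected(self):
        times = regular_times(datetime(2024, 3, 4), 48, 60)
        series = make_series(times, np.ones(48), np.zeros(48, bool))
        with pytest.raises(ValueError, match="cadence"):
            detect_nonwear(series)


class TestMaskDimCct:
    def test_bright_daytime_series_unchanged(self):
        times = regular_times(datetime(2024, 3, 4, 8, 0), 24, 15)
        series = make_series(times, np.full(24, 500.0), np.zeros(24, bool))
        masked = mask_dim_cct(series)
        assert masked.data["cct"].notna().all()

    def test_night_series_fully_masked(self):
        times = regular_times(datetime(2024, 3, 4, 22, 0), 24, 15)
        series = make_series(times, np.full(24, 500.0), np.zeros(24, bool))
        masked = mask_dim_cct(series)
        assert masked.data["cct"].isna().all()

    def test_mixed_series_matches_row_scan(self):
        rng = np.random.default_rng(1)
        times = regular_times(datetime(2024, 3, 4, 0, 0), 96, 15)
        lux = rng.uniform(0, 100, 96)
        series = make_series(times, lux, np.zeros(96, bool))
        masked = mask_dim_cct(series, lux_floor=10.0)
        df = series.data
        expected = [
            (not df["day_flag"].iloc[i]) or lux[i] < 10.0 for i in range(96)
        ]
        assert masked.data["cct"].isna().tolist() == expected
        assert masked.data["lux"].notna().all()
        assert masked.data["cs"].notna().all()


class TestWeeklySummary:
    def test_constant_week(self):
        times = regular_times(datetime(2024, 3, 4), 7 * 96, 15)
        series = make_series(times, np.full(7 * 96, 123.0),
                             np.zeros(7 * 96, bool))
        out = weekly_summary(series)
        day_lux = out[(out["period"] == "day") & (out["metric"] == "lux")]
        assert day_lux["mean"].iloc[0] == pytest.approx(123.0)
        assert day_lux["variance"].iloc[0] == 0.0

    def test_five_week_series_has_five_day_and_night_cells(self):
        times = regular_times(datetime(2024, 3, 4), 35 * 24, 60 // 2 * 2)
        # hourly cadence over 35 days
        times = regular_times(datetime(2024, 3, 4), 35 * 48, 30)
        n = len(times)
        series = make_series(times, np.linspace(1, 500, n),
                             np.zeros(n, bool))
        out = weekly_summary(series)
        lux_rows = out[out["metric"] == "lux"]
        assert len(lux_rows[lux_rows["period"] == "day"]) == 5
        assert len(lux_rows[lux_rows["period"] == "night"]) == 5

    def test_four_record_week_matches_hand_arithmetic(self):
        base = datetime(2024, 3, 4, 9, 0)
        times = [base + timedelta(days=d) for d in (0, 1, 2, 3)]
        times.append(base + timedelta(days=7))  # open the second week
        lux = [100.0, 200.0, 300.0, 400.0, 999.0]
        series = make_series(times, lux, np.zeros(5, bool))
        out = weekly_summary(series)
        cell = out[(out["week"] == 0) & (out["period"] == "day")
                   & (out["metric"] == "lux")].iloc[0]
        assert cell["mean"] == pytest.approx(250.0)       # (100+..+400)/4
        assert cell["variance"] == pytest.approx(50000.0 / 3.0)
        assert cell["n"] == 4

    def test_nonwear_records_are_excluded_exactly(self):
        times = regular_times(datetime(2024, 3, 4), 7 * 48, 30)
        n = len(times)
        rng = np.random.default_rng(2)
        lux = rng.uniform(10, 1000, n)
        wear = np.ones(n, bool)
        wear[100:150] = False
        series = make_series(times, lux, np.zeros(n, bool), wear=wear)
        out = weekly_summary(series)
        dropped = make_series(
            [t for i, t in enumerate(times) if wear[i]],
            lux[wear], np.zeros(wear.sum(), bool),
        )
        out2 = weekly_summary(dropped)
        lux_a = out[out["metric"] == "lux"].reset_index(drop=True)
        lux_b = out2[out2["metric"] == "lux"].reset_index(drop=True)
        pd.testing.assert_frame_equal(lux_a, lux_b)

    def test_short_series_rejected(self):
        times = regular_times(datetime(2024, 3, 4), 48, 30)
        series = make_series(times, np.ones(48), np.zeros(48, bool))
        with pytest.raises(ValueError, match="week"):
            weekly_summary(series)


class TestPairedT:
    def test_identical_vectors(self):
        result = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert result["t"] == 0.0
        assert result["p_two_tailed"] == 1.0

    def test_constant_nonzero_difference_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_t([1, 2, 3, 4, 5], [0, 1, 2, 3, 4])

    def test_hand_computed_example(self):
        result = paired_t([5, 6, 7, 8, 9], [4, 6, 6, 9, 7])
        # d = (1,0,1,-1,2): mean 0.6, sd 1.140175, t = 1.176697, df 4
        assert result["t"] == pytest.approx(1.176697, abs=1e-5)
        assert result["df"] == 4
        assert result["p_two_tailed"] == pytest.approx(0.304559, abs=1e-4)

    def test_antisymmetric_in_arguments(self):
        a, b = [5.0, 6, 7, 8, 9], [4.0, 6, 6, 9, 7]
        fwd, rev = paired_t(a, b), paired_t(b, a)
        assert fwd["t"] == pytest.approx(-rev["t"])
        assert fwd["p_two_tailed"] == pytest.approx(rev["p_two_tailed"])


class TestPower:
    def test_vanishing_effect_approaches_alpha(self):
        assert post_hoc_power(29, 1e-9, alpha=0.05, tails=1) == pytest.approx(
            0.05, abs=1e-3
        )

    def test_huge_effect_saturates(self):
        assert post_hoc_power(29, 5.0, alpha=0.05, tails=1) > 0.999

    def test_study_design_power(self):
        assert post_hoc_power(29, 0.53, alpha=0.05, tails=1) == pytest.approx(
            0.87, abs=0.01
        )

    def test_monotone_in_n_and_d(self):
        for d in (0.2, 0.5, 0.8):
            powers = [post_hoc_power(n, d) for n in (5, 10, 20, 40, 80)]
            assert all(a < b for a, b in zip(powers, powers[1:]))
        for n in (10, 29, 60):
            powers = [post_hoc_power(n, d) for d in (0.1, 0.3, 0.5, 0.8)]
            assert all(a < b for a, b in zip(powers, powers[1:]))

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            post_hoc_power(29, 0.5, alpha=1.5)
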