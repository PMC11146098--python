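"""Unit and property tests for the feedback engine."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from focusbar.engine import (
    Band,
    CalibrationError,
    Color,
    ColorCuts,
    EngineValidationError,
    InteractionSample,
    ReferenceRates,
    ThresholdSet,
    WeightConfig,
    band_time_fractions,
    bar_delta,
    calibrate_thresholds,
    classify_band,
    color_of,
    default_weights,
    initial_bar_state,
    input_level,
    run_session,
    session_levels,
    tick,
)
from conftest import make_log, random_log


# ---------------------------------------------------------------------------
# input_level
# ---------------------------------------------------------------------------


class TestInputLevel:
    def test_all_zero_window_is_zero(self, weights):
        window = make_log([(0, 0, 0, 0)] * 6)
        assert input_level(window, weights) == 0.0

    def test_unit_weight_sum(self):
        w = WeightConfig(1, 1, 0, 0)
        window = make_log([(4, 60, 0, 0)])
        assert input_level(window, w) == 64.0

    def test_six_bin_accumulation_matches_elementwise_sum(self):
        # independent accumulation oracle: per-channel elementwise totals
        # 6 bins of (1, 10, 300, 500) -> totals (6, 60, 1800, 3000)
        # level = 2*6 + 1*60 + 0.01*1800 + 0.005*3000 = 105.0
        w = WeightConfig(2.0, 1.0, 0.01, 0.005)
        window = make_log([(1, 10, 300, 500)] * 6)
        assert input_level(window, w) == pytest.approx(105.0)

    def test_empty_window_returns_zero_with_warning(self, weights, caplog):
        with caplog.at_level("WARNING"):
            assert input_level([], weights) == 0.0
        assert any("empty window" in r.message for r in caplog.records)

    def test_negative_channel_rejected(self):
        with pytest.raises(EngineValidationError):
            InteractionSample(t_start=0, clicks=-1, keystrokes=0, scroll_px=0, cursor_px=0)

    def test_oversized_window_rejected(self, weights):
        with pytest.raises(EngineValidationError):
            input_level(make_log([(1, 1, 1, 1)] * 7), weights)


class TestDefaultWeights:
    def test_reciprocal_of_reference_rates(self):
        w = default_weights(ReferenceRates(10, 100, 2000, 5000))
        assert (w.w_click, w.w_key, w.w_scroll, w.w_cursor) == (0.1, 0.01, 0.0005, 0.0002)

    def test_equal_rates_give_unit_weights(self):
        w = default_weights(ReferenceRates(1, 1, 1, 1))
        assert (w.w_click, w.w_key, w.w_scroll, w.w_cursor) == (1, 1, 1, 1)

    def test_nominal_minute_scores_four(self):
        # one deterministic minute at exactly the reference rates: each
        # channel contributes 1.0, so the level is 4.0
        w = default_weights()
        rows = [(2, 17, 334, 834), (2, 17, 334, 834), (2, 17, 333, 833),
                (2, 17, 333, 833), (1, 16, 333, 833), (1, 16, 333, 833)]
        totals = np.array(rows).sum(axis=0)
        assert tuple(totals) == (10, 100, 2000, 5000)
        assert input_level(make_log(rows), w) == pytest.approx(4.0)

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(EngineValidationError):
            ReferenceRates(clicks=0)


# ---------------------------------------------------------------------------
# calibrate_thresholds / classify_band
# ---------------------------------------------------------------------------


class TestCalibration:
    def test_mean_100_sd_40_cut_points(self):
        # any history with mu=100, population sigma=40
        levels = [60, 140, 60, 140, 60, 140, 60, 140]
        th = calibrate_thresholds(levels)
        assert th.mu == pytest.approx(100)
        assert th.sigma == pytest.approx(40)
        assert (th.lowest, th.low, th.high, th.highest) == (80, 90, 110, 120)
        assert not th.degenerate

    def test_constant_history_is_degenerate(self):
        th = calibrate_thresholds([50] * 5)
        assert th.degenerate
        assert th.lowest == th.low == th.high == th.highest == 50

    def test_too_few_samples(self):
        with pytest.raises(CalibrationError):
            calibrate_thresholds([1, 2, 3, 4])

    def test_matches_two_pass_oracle_on_lognormal(self, rng):
        levels = rng.lognormal(3.0, 0.8, size=1000)
        th = calibrate_thresholds(levels)
        # independent two-pass oracle
        mu = sum(levels) / len(levels)
        sigma = math.sqrt(sum((x - mu) ** 2 for x in levels) / len(levels))
        assert th.mu == pytest.approx(mu, abs=1e-9)
        assert th.sigma == pytest.approx(sigma, abs=1e-9)

    def test_lower_cut_points_floored_at_zero(self):
        # highly skewed nonnegative history: mu - sigma/2 < 0
        th = calibrate_thresholds([0] * 9 + [1])
        assert th.lowest == 0.0
        assert th.lowest <= th.low <= th.mu <= th.high <= th.highest

    @given(
        st.lists(st.floats(0, 1e6, allow_nan=False), min_size=5, max_size=60)
    )
    @settings(max_examples=200, deadline=None)
    def test_threshold_ordering_invariant(self, levels):
        th = calibrate_thresholds(levels)
        assert th.lowest <= th.low <= th.mu + 1e-12
        assert th.mu <= th.high <= th.highest + 1e-12


class TestClassifyBand:
    TH = ThresholdSet(mu=100, sigma=40, lowest=80, low=90, high=110, highest=120)

    @pytest.mark.parametrize(
        "level,band",
        [
            (100, Band.MID),
            (120.0001, Band.ABOVE_HIGHEST),
            (120, Band.HIGH_TO_HIGHEST),   # tie at highest stays below
            (110, Band.MID),               # tie at high stays mid
            (90, Band.LOWEST_TO_LOW),      # tie at low falls to the band below
            (80, Band.BELOW_LOWEST),
            (0, Band.BELOW_LOWEST),
            (1e9, Band.ABOVE_HIGHEST),
        ],
    )
    def test_boundary_convention(self, level, band):
        assert classify_band(level, self.TH) == band

    def test_degenerate_sigma_zero(self):
        th = calibrate_thresholds([7.0] * 5)
        assert classify_band(7.0, th) == Band.MID
        assert classify_band(7.0001, th) == Band.ABOVE_HIGHEST
        assert classify_band(6.9999, th) == Band.BELOW_LOWEST

    def test_agrees_with_interval_membership_oracle(self, rng):
        for _ in range(10_000):
            mu = rng.uniform(0, 100)
            sigma = rng.uniform(0.01, 50)
            th = ThresholdSet(
                mu=mu, sigma=sigma,
                lowest=max(0, mu - sigma / 2), low=max(0, mu - sigma / 4),
                high=mu + sigma / 4, highest=mu + sigma / 2,
            )
            level = rng.uniform(0, 200)
            # brute-force interval membership, written independently
            if level > th.highest:
                expect = Band.ABOVE_HIGHEST
            elif th.high < level <= th.highest:
                expect = Band.HIGH_TO_HIGHEST
            elif th.low < level <= th.high:
                expect = Band.MID
            elif th.lowest < level <= th.low:
                expect = Band.LOWEST_TO_LOW
            else:
                expect = Band.BELOW_LOWEST
            assert classify_band(level, th) == expect


# ---------------------------------------------------------------------------
# bar_delta / color_of / tick
# ---------------------------------------------------------------------------


class TestBar:
    @pytest.mark.parametrize(
        "band,delta",
        [
            (Band.ABOVE_HIGHEST, 10),
            (Band.HIGH_TO_HIGHEST, 5),
            (Band.MID, 2.5),
            (Band.LOWEST_TO_LOW, -5),
            (Band.BELOW_LOWEST, -10),
        ],
    )
    def test_deltas(self, band, delta):
        assert bar_delta(band) == delta

    @pytest.mark.parametrize(
        "fill,color",
        [(50, Color.YELLOW), (0, Color.RED), (100, Color.GREEN),
         (40, Color.YELLOW), (60, Color.YELLOW), (39.99, Color.RED),
         (60.01, Color.GREEN)],
    )
    def test_color_map(self, fill, color):
        assert color_of(fill) == color

    def test_color_out_of_range_rejected(self):
        with pytest.raises(EngineValidationError):
            color_of(100.5)

    def test_color_sweep_has_exactly_two_transitions(self):
        fills = np.arange(0, 100.5, 0.5)
        colors = [color_of(f) for f in fills]
        transitions = [
            (fills[i], colors[i - 1], colors[i])
            for i in range(1, len(colors))
            if colors[i] != colors[i - 1]
        ]
        assert len(transitions) == 2
        assert transitions[0] == (40.0, Color.RED, Color.YELLOW)
        assert transitions[1] == (60.5, Color.YELLOW, Color.GREEN)

    def test_tick_above_highest(self):
        th = TestClassifyBand.TH
        s = tick(initial_bar_state(), 500, th)
        assert (s.fill, s.minute_index) == (60, 1)

    def test_tick_clamps_at_zero(self):
        th = TestClassifyBand.TH
        s = tick(initial_bar_state(0.0), 0, th)
        assert s.fill == 0.0
        assert s.color == Color.RED

    def test_twenty_mid_ticks_saturate(self):
        th = TestClassifyBand.TH
        s = initial_bar_state()
        for _ in range(20):
            s = tick(s, 100, th)
        assert s.fill == 100.0
        assert s.color == Color.GREEN
        assert s.minute_index == 20


# ---------------------------------------------------------------------------
# run_session / band_time_fractions
# ---------------------------------------------------------------------------


from oracles import naive_replay


class TestRunSession:
    def test_empty_session_drains_in_five_minutes(self, weights):
        th = TestClassifyBand.TH
        trace = run_session([], weights, th, minutes=50)
        fills = [r.fill for r in trace.records]
        assert fills[:5] == [40, 30, 20, 10, 0]
        assert all(f == 0 for f in fills[5:])

    def test_replay_is_deterministic(self, weights, rng):
        log = random_log(rng)
        th = calibrate_thresholds(session_levels(log, weights))
        t1 = run_session(log, weights, th)
        t2 = run_session(log, weights, th)
        assert t1 == t2

    def test_matches_independent_replay_oracle(self, weights, rng):
        log = random_log(rng)
        th = calibrate_thresholds(rng.uniform(0, 8, size=40))
        trace = run_session(log, weights, th)
        expect = naive_replay(log, weights, th)
        got = [
            (r.minute_index, r.input_level, r.delta_pp, r.fill, r.color.value)
            for r in trace.records
        ]
        assert got == expect

    def test_out_of_order_log_rejected(self, weights):
        th = TestClassifyBand.TH
        log = make_log([(1, 1, 1, 1)] * 3)
        bad = [log[0], log[2], log[1]]
        with pytest.raises(EngineValidationError):
            run_session(bad, weights, th)

    def test_duplicate_bin_rejected(self, weights):
        th = TestClassifyBand.TH
        log = make_log([(1, 1, 1, 1)] * 2)
        with pytest.raises(EngineValidationError):
            run_session([log[0], log[0]], weights, th)

    def test_feedback_disabled_records_levels_only(self, weights, rng):
        log = random_log(rng)
        th = calibrate_thresholds(session_levels(log, weights))
        trace = run_session(log, weights, th, feedback_enabled=False)
        on = run_session(log, weights, th, feedback_enabled=True)
        assert all(r.fill is None and r.color is None and r.delta_pp is None
                   for r in trace.records)
        assert [r.input_level for r in trace.records] == [
            r.input_level for r in on.records
        ]
        with pytest.raises(EngineValidationError):
            band_time_fractions(trace)

    def test_monotone_response(self, weights, rng):
        """A stream with pointwise-higher levels never falls behind."""
        th = calibrate_thresholds(rng.uniform(0.5, 6, size=50))
        lo_log = random_log(rng, minutes=30)
        hi_log = [
            InteractionSample(s.t_start, s.clicks + 2, s.keystrokes + 20,
                              s.scroll_px + 100, s.cursor_px + 100)
            for s in lo_log
        ]
        lo = run_session(lo_log, weights, th, minutes=30)
        hi = run_session(hi_log, weights, th, minutes=30)
        for a, b in zip(hi.records, lo.records):
            assert a.input_level >= b.input_level
            assert a.fill >= b.fill

    def test_band_time_fractions_hand_count(self, weights):
        # 10-minute session: 5 minutes saturated-high activity then 5 idle.
        # fills: 60,70,80,90,100 then 90,80,70,60,50
        # colors: yellow, green x4, green x3, yellow x2 -> 7 green, 3 yellow
        # active bins give per-minute level ~8.4 (> highest=5 -> +10/min);
        # idle minutes give level 0 (<= lowest=3 -> -10/min)
        th = ThresholdSet(mu=4, sigma=2, lowest=3, low=3.5, high=4.5, highest=5)
        log = make_log([(4, 34, 668, 1668)] * 30 + [(0, 0, 0, 0)] * 30)
        trace = run_session(log, weights, th, minutes=10)
        fr = band_time_fractions(trace)
        assert fr == {"green": 0.7, "yellow": 0.3, "red": 0.0}
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-9)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_fill_bounds_and_delta_membership(self, seed):
        rng = np.random.default_rng(seed)
        weights = default_weights()
        log = random_log(rng, minutes=15)
        th = calibrate_thresholds(rng.uniform(0, 10, size=20))
        trace = run_session(log, weights, th, minutes=15)
        prev = 50.0
        for r in trace.records:
            assert 0 <= r.fill <= 100
            assert r.delta_pp in (-10, -5, 2.5, 5, 10)
            clamped = max(0.0, min(100.0, prev + r.delta_pp))
            assert r.fill == clamped
            prev = r.fill
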