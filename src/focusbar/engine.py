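"""Feedback engine: input levels, adaptive thresholds, and the per-minute bar.

The engine turns a stream of 10-second computer-interaction bins (mouse
clicks, keystrokes, scroll distance, cursor travel) into a unitless *input
level* once per minute, compares it against per-user thresholds derived from
that user's historical activity (mean ± one-fourth / one-half standard
deviation), and drives a red/yellow/green feedback bar that grows or shrinks
by a fixed number of percentage points each minute:

=================  =======
band               delta
=================  =======
above highest      +10 pp
high .. highest    +5 pp
low .. high (mid)  +2.5 pp
lowest .. low      -5 pp
at/below lowest    -10 pp
=================  =======

The mid band is deliberately rewarded (+2.5 pp) rather than held flat, so
steady on-task activity slowly fills the bar. Fill is clamped to [0, 100].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

#: Width of one interaction-log bin, seconds.
BIN_SECONDS = 10
#: Bins contributing to one input-level window (the previous 60 s).
BINS_PER_MINUTE = 60 // BIN_SECONDS

CHANNELS = ("clicks", "keystrokes", "scroll_px", "cursor_px")


class EngineValidationError(ValueError):
    """Raised when inputs violate an engine precondition."""


class CalibrationError(ValueError):
    """Raised when threshold calibration is impossible (too little history)."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class InteractionSample:
    """One 10-second bin of the four tracked interaction channels.

    ``t_start`` is seconds from session start and must be a multiple of the
    bin width. Counts are events; scroll/cursor are pixel distances.
    """

    t_start: float
    clicks: int
    keystrokes: int
    scroll_px: float
    cursor_px: float

    def __post_init__(self) -> None:
        if self.t_start < 0 or self.t_start % BIN_SECONDS != 0:
            raise EngineValidationError(
                f"t_start must be a nonnegative multiple of {BIN_SECONDS} s, "
                f"got {self.t_start!r}"
            )
        for name in CHANNELS:
            v = getattr(self, name)
            if v < 0:
                raise EngineValidationError(f"{name} must be >= 0, got {v!r}")


@dataclass(frozen=True)
class WeightConfig:
    """Per-channel coefficients combining the four channels into one level."""

    w_click: float
    w_key: float
    w_scroll: float
    w_cursor: float

    def __post_init__(self) -> None:
        ws = (self.w_click, self.w_key, self.w_scroll, self.w_cursor)
        if any(w < 0 for w in ws):
            raise EngineValidationError(f"weights must be >= 0, got {ws}")
        if not any(w > 0 for w in ws):
            raise EngineValidationError("at least one weight must be > 0")


@dataclass(frozen=True)
class ReferenceRates:
    """Expected per-minute activity for a nominally engaged user.

    Used to derive default weights so that each channel contributes 1.0 to
    the per-minute input level at nominal activity (the study's actual pilot
    weights were never published).
    """

    clicks: float = 10.0
    keystrokes: float = 100.0
    scroll_px: float = 2000.0
    cursor_px: float = 5000.0

    def __post_init__(self) -> None:
        for name in CHANNELS:
            v = getattr(self, name)
            if v <= 0:
                raise EngineValidationError(
                    f"reference rate {name} must be > 0, got {v!r}"
                )


DEFAULT_REFERENCE_RATES = ReferenceRates()


@dataclass(frozen=True)
class ThresholdSet:
    """Per-user calibration: mean, SD, and the four input-level cut points.

    ``lowest``/``highest`` sit at mu -/+ sigma/2 and ``low``/``high`` at
    mu -/+ sigma/4; the two lower cut points are floored at 0 (input levels
    are nonnegative). ``degenerate`` flags a zero-variance history.
    """

    mu: float
    sigma: float
    lowest: float
    low: float
    high: float
    highest: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise EngineValidationError(f"sigma must be >= 0, got {self.sigma!r}")
        if not (self.lowest <= self.low <= self.high <= self.highest):
            raise EngineValidationError(
                "thresholds must satisfy lowest <= low <= high <= highest"
            )


class Band(str, Enum):
    """Position of an input level relative to the four thresholds."""

    BELOW_LOWEST = "below_lowest"
    LOWEST_TO_LOW = "lowest_to_low"
    MID = "mid"
    HIGH_TO_HIGHEST = "high_to_highest"
    ABOVE_HIGHEST = "above_highest"


#: Per-minute bar change (percentage points of full bar width) per band.
DEFAULT_BAR_DELTAS: dict[Band, float] = {
    Band.ABOVE_HIGHEST: 10.0,
    Band.HIGH_TO_HIGHEST: 5.0,
    Band.MID: 2.5,
    Band.LOWEST_TO_LOW: -5.0,
    Band.BELOW_LOWEST: -10.0,
}


class Color(str, Enum):
    RED = "red"
    YELLOW = "yellow"
    GREEN = "green"


@dataclass(frozen=True)
class ColorCuts:
    """Fill -> color mapping: red below ``red_below``, green above
    ``green_above``, yellow in between (inclusive). The bar starts at fill 50,
    which must be yellow."""

    red_below: float = 40.0
    green_above: float = 60.0

    def __post_init__(self) -> None:
        if not (0 <= self.red_below <= self.green_above <= 100):
            raise EngineValidationError(
                "color cuts must satisfy 0 <= red_below <= green_above <= 100"
            )


DEFAULT_COLOR_CUTS = ColorCuts()
INITIAL_FILL = 50.0


@dataclass(frozen=True)
class BarState:
    """Feedback bar at one minute boundary."""

    fill: float
    color: Color
    minute_index: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.fill <= 100:
            raise EngineValidationError(f"fill must be in [0, 100], got {self.fill!r}")


@dataclass(frozen=True)
class MinuteRecord:
    """One per-minute entry of a feedback trace.

    ``delta_pp``, ``fill`` and ``color`` are None when feedback was disabled
    for the session (the probe still logs levels and bands silently).
    """

    minute_index: int
    input_level: float
    band: Band
    delta_pp: Optional[float]
    fill: Optional[float]
    color: Optional[Color]


@dataclass
class FeedbackTrace:
    """Per-minute record of a full session run."""

    records: list[MinuteRecord]
    feedback_enabled: bool
    participant_id: Optional[str] = None
    session: Optional[int] = None

    @property
    def final_fill(self) -> Optional[float]:
        if not self.feedback_enabled or not self.records:
            return None
        return self.records[-1].fill

    @property
    def mean_input_level(self) -> float:
        if not self.records:
            return 0.0
        return sum(r.input_level for r in self.records) / len(self.records)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def input_level(
    window: Sequence[InteractionSample], weights: WeightConfig
) -> float:
    """Weighted sum of all interaction in a one-minute window of bins.

    The window holds the (at most 6) bins of the preceding 60 seconds;
    missing bins simply contribute nothing. An empty window is valid (total
    idleness) and yields 0.
    """
    if len(window) == 0:
        logger.warning("input_level called with empty window; returning 0")
        return 0.0
    if len(window) > BINS_PER_MINUTE:
        raise EngineValidationError(
            f"window may contain at most {BINS_PER_MINUTE} bins, got {len(window)}"
        )
    clicks = sum(s.clicks for s in window)
    keys = sum(s.keystrokes for s in window)
    scroll = sum(s.scroll_px for s in window)
    cursor = sum(s.cursor_px for s in window)
    return (
        weights.w_click * clicks
        + weights.w_key * keys
        + weights.w_scroll * scroll
        + weights.w_cursor * cursor
    )


def default_weights(
    reference_rates: ReferenceRates = DEFAULT_REFERENCE_RATES,
) -> WeightConfig:
    """Reciprocal-of-reference-rate weights.

    Each channel contributes exactly 1.0 per minute when active at its
    nominal rate, equalizing the heterogeneous units (counts vs pixels).
    """
    return WeightConfig(
        w_click=1.0 / reference_rates.clicks,
        w_key=1.0 / reference_rates.keystrokes,
        w_scroll=1.0 / reference_rates.scroll_px,
        w_cursor=1.0 / reference_rates.cursor_px,
    )


def calibrate_thresholds(historical_levels: Sequence[float]) -> ThresholdSet:
    """Fit per-user thresholds from historical per-minute input levels.

    mu is the mean and sigma the population standard deviation of the
    history; cut points are mu -/+ sigma/2 (lowest/highest) and mu -/+
    sigma/4 (low/high), with the two lower cut points floored at 0.
    Requires at least 5 historical levels.
    """
    levels = [float(x) for x in historical_levels]
    if len(levels) < 5:
        raise CalibrationError(
            f"need >= 5 historical levels to calibrate, got {len(levels)}"
        )
    if any(x < 0 for x in levels):
        raise EngineValidationError("input levels must be >= 0")
    n = len(levels)
    mu = math.fsum(levels) / n
    sigma = math.sqrt(math.fsum((x - mu) ** 2 for x in levels) / n)
    degenerate = sigma == 0.0
    if degenerate:
        logger.warning(
            "degenerate calibration: all %d historical levels equal %g", n, mu
        )
    return ThresholdSet(
        mu=mu,
        sigma=sigma,
        lowest=max(0.0, mu - sigma / 2),
        low=max(0.0, mu - sigma / 4),
        high=mu + sigma / 4,
        highest=mu + sigma / 2,
        degenerate=degenerate,
    )


def classify_band(level: float, thresholds: ThresholdSet) -> Band:
    """Place an input level into one of the five threshold bands.

    Intervals are half-open with ties falling downward: a level exactly at
    a cut point belongs to the band below it (strict exceedance is required
    to move up a band). Degenerate (sigma = 0) thresholds classify any
    deviation from mu as above/below and mu itself as mid.
    """
    if thresholds.sigma == 0.0:
        if level > thresholds.mu:
            return Band.ABOVE_HIGHEST
        if level < thresholds.mu:
            return Band.BELOW_LOWEST
        return Band.MID
    if level > thresholds.highest:
        return Band.ABOVE_HIGHEST
    if level > thresholds.high:
        return Band.HIGH_TO_HIGHEST
    if level > thresholds.low:
        return Band.MID
    if level > thresholds.lowest:
        return Band.LOWEST_TO_LOW
    return Band.BELOW_LOWEST


def bar_delta(band: Band, deltas: Optional[dict[Band, float]] = None) -> float:
    """Percentage-point change of the bar for one minute in ``band``."""
    table = DEFAULT_BAR_DELTAS if deltas is None else deltas
    return table[band]


def color_of(fill: float, cuts: ColorCuts = DEFAULT_COLOR_CUTS) -> Color:
    """Color of the bar at a given fill percentage."""
    if not 0 <= fill <= 100:
        raise EngineValidationError(f"fill must be in [0, 100], got {fill!r}")
    if fill < cuts.red_below:
        return Color.RED
    if fill > cuts.green_above:
        return Color.GREEN
    return Color.YELLOW


def initial_bar_state(
    fill: float = INITIAL_FILL, cuts: ColorCuts = DEFAULT_COLOR_CUTS
) -> BarState:
    """Bar at session start: half-full (yellow by default) at minute 0."""
    return BarState(fill=fill, color=color_of(fill, cuts), minute_index=0)


def tick(
    state: BarState,
    level: float,
    thresholds: ThresholdSet,
    deltas: Optional[dict[Band, float]] = None,
    cuts: ColorCuts = DEFAULT_COLOR_CUTS,
) -> BarState:
    """Advance the bar by one minute given the minute's input level."""
    band = classify_band(level, thresholds)
    new_fill = min(100.0, max(0.0, state.fill + bar_delta(band, deltas)))
    return BarState(
        fill=new_fill,
        color=color_of(new_fill, cuts),
        minute_index=state.minute_index + 1,
    )


def _validate_log(log: Sequence[InteractionSample]) -> None:
    prev = -math.inf
    for i, s in enumerate(log):
        if s.t_start <= prev:
            raise EngineValidationError(
                f"bins must have strictly increasing t_start; "
                f"violation at index {i} (t_start={s.t_start})"
            )
        prev = s.t_start


def run_session(
    log: Sequence[InteractionSample],
    weights: WeightConfig,
    thresholds: ThresholdSet,
    feedback_enabled: bool = True,
    minutes: int = 50,
    initial_fill: float = INITIAL_FILL,
    deltas: Optional[dict[Band, float]] = None,
    cuts: ColorCuts = DEFAULT_COLOR_CUTS,
    participant_id: Optional[str] = None,
    session: Optional[int] = None,
) -> FeedbackTrace:
    """Replay one session: a bar tick per elapsed minute, from minute 1.

    The window for minute m holds the bins whose t_start lies in
    [60*(m-1), 60*m); bins beyond the session duration are ignored. With
    feedback disabled, levels and bands are still recorded (the probe logs
    during all sessions) but the bar itself — delta, fill, color — is absent.
    The result is a pure function of its arguments.
    """
    if minutes <= 0:
        raise EngineValidationError(f"minutes must be > 0, got {minutes}")
    _validate_log(log)

    by_minute: dict[int, list[InteractionSample]] = {}
    for s in log:
        m = int(s.t_start // 60) + 1
        if m <= minutes:
            by_minute.setdefault(m, []).append(s)

    records: list[MinuteRecord] = []
    state = initial_bar_state(initial_fill, cuts)
    for m in range(1, minutes + 1):
        window = by_minute.get(m, [])
        level = input_level(window, weights) if window else 0.0
        band = classify_band(level, thresholds)
        if feedback_enabled:
            new_state = tick(state, level, thresholds, deltas, cuts)
            records.append(
                MinuteRecord(
                    minute_index=m,
                    input_level=level,
                    band=band,
                    delta_pp=bar_delta(band, deltas),
                    fill=new_state.fill,
                    color=new_state.color,
                )
            )
            state = new_state
        else:
            records.append(
                MinuteRecord(
                    minute_index=m,
                    input_level=level,
                    band=band,
                    delta_pp=None,
                    fill=None,
                    color=None,
                )
            )
    return FeedbackTrace(
        records=records,
        feedback_enabled=feedback_enabled,
        participant_id=participant_id,
        session=session,
    )


def band_time_fractions(trace: FeedbackTrace) -> dict[str, float]:
    """Fractions of session minutes the bar spent green / yellow / red."""
    if not trace.feedback_enabled:
        raise EngineValidationError(
            "band_time_fractions requires a feedback-enabled trace"
        )
    if not trace.records:
        raise EngineValidationError("empty trace")
    n = len(trace.records)
    counts = {Color.GREEN: 0, Color.YELLOW: 0, Color.RED: 0}
    for r in trace.records:
        counts[r.color] += 1
    return {
        "green": counts[Color.GREEN] / n,
        "yellow": counts[Color.YELLOW] / n,
        "red": counts[Color.RED] / n,
    }


def session_levels(
    log: Sequence[InteractionSample],
    weights: WeightConfig,
    minutes: int = 50,
) -> list[float]:
    """Per-minute input levels of a session, without running the bar.

    Convenience for calibration: these are exactly the levels a
    feedback-disabled replay would record.
    """
    _validate_log(log)
    by_minute: dict[int, list[InteractionSample]] = {}
    for s in log:
        m = int(s.t_start // 60) + 1
        if m <= minutes:
            by_minute.setdefault(m, []).append(s)
    return [
        input_level(by_minute[m], weights) if m in by_minute else 0.0
        for m in range(1, minutes + 1)
    ]
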