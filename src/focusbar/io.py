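"""Session-log and trace file formats, plus run configuration.

The canonical session-log format is JSON-lines: one object per 10-second
bin with keys ``t_start``, ``clicks``, ``keystrokes``, ``scroll_px``,
``cursor_px``. An equivalent CSV dialect with the same headers is read and
written for spreadsheet interoperability. Timestamps are seconds from
session start, not wall clock.
"""

from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .engine import (
    CHANNELS,
    ColorCuts,
    EngineValidationError,
    FeedbackTrace,
    ReferenceRates,
    WeightConfig,
    InteractionSample,
    default_weights,
)

_FIELDS = ("t_start",) + CHANNELS


class LogFormatError(ValueError):
    pass


def _detect_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    return "csv" if path.suffix.lower() == ".csv" else "jsonl"


def read_session_log(
    path: Union[str, Path], fmt: Optional[Literal["jsonl", "csv"]] = None
) -> list[InteractionSample]:
    """Read and validate a session log (JSONL or CSV, by extension).

    Malformed lines are reported with their 1-based line number; duplicate
    or out-of-order timestamps and negative values are errors.
    """
    path = Path(path)
    fmt = _detect_format(path, fmt)
    samples: list[InteractionSample] = []
    seen: set[float] = set()

    def add(record: dict, lineno: int) -> None:
        try:
            s = InteractionSample(
                t_start=float(record["t_start"]),
                clicks=int(record["clicks"]),
                keystrokes=int(record["keystrokes"]),
                scroll_px=float(record["scroll_px"]),
                cursor_px=float(record["cursor_px"]),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise LogFormatError(f"{path}:{lineno}: invalid record: {exc}") from exc
        if s.t_start in seen:
            raise LogFormatError(f"{path}:{lineno}: duplicate t_start {s.t_start}")
        if samples and s.t_start < samples[-1].t_start:
            raise LogFormatError(
                f"{path}:{lineno}: out-of-order t_start {s.t_start}"
            )
        seen.add(s.t_start)
        samples.append(s)

    with path.open(newline="") as fh:
        if fmt == "jsonl":
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise LogFormatError(f"{path}:{lineno}: bad JSON: {exc}") from exc
                add(record, lineno)
        elif fmt == "csv":
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or set(_FIELDS) - set(reader.fieldnames):
                raise LogFormatError(
                    f"{path}: CSV header must contain {_FIELDS}"
                )
            for lineno, record in enumerate(reader, start=2):
                add(record, lineno)
        else:
            raise LogFormatError(f"unknown format {fmt!r}")
    return samples


def write_session_log(
    path: Union[str, Path],
    samples: Sequence[InteractionSample],
    fmt: Optional[Literal["jsonl", "csv"]] = None,
) -> None:
    path = Path(path)
    fmt = _detect_format(path, fmt)
    with path.open("w", newline="") as fh:
        if fmt == "jsonl":
            for s in samples:
                fh.write(
                    json.dumps(
                        {
                            "t_start": s.t_start,
                            "clicks": s.clicks,
                            "keystrokes": s.keystrokes,
                            "scroll_px": s.scroll_px,
                            "cursor_px": s.cursor_px,
                        }
                    )
                    + "\n"
                )
        elif fmt == "csv":
            writer = csv.writer(fh)
            writer.writerow(_FIELDS)
            for s in samples:
                writer.writerow(
                    [s.t_start, s.clicks, s.keystrokes, s.scroll_px, s.cursor_px]
                )
        else:
            raise LogFormatError(f"unknown format {fmt!r}")


def write_trace_csv(path: Union[str, Path], trace: FeedbackTrace) -> None:
    """Export a trace as CSV (minute, input_level, band, delta_pp, fill,
    color), suitable for re-plotting a bar-and-level session panel."""
    with Path(path).open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["minute", "input_level", "band", "delta_pp", "fill", "color"])
        for r in trace.records:
            writer.writerow(
                [
                    r.minute_index,
                    f"{r.input_level:.6g}",
                    r.band.value,
                    "" if r.delta_pp is None else r.delta_pp,
                    "" if r.fill is None else r.fill,
                    "" if r.color is None else r.color.value,
                ]
            )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


class BarConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    initial_fill: float = 50.0
    increment_above_highest: float = 10.0
    increment_high: float = 5.0
    increment_mid: float = 2.5
    decrement_low: float = -5.0
    decrement_below_lowest: float = -10.0
    red_below: float = 40.0
    green_above: float = 60.0

    @model_validator(mode="after")
    def _check(self) -> "BarConfig":
        ColorCuts(red_below=self.red_below, green_above=self.green_above)
        if not 0 <= self.initial_fill <= 100:
            raise ValueError("initial_fill must be in [0, 100]")
        return self


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n_participants: int = 27
    rho: float = Field(default=0.5, ge=-1.0, le=1.0)
    max_sessions: int = 12
    feedback_sessions: list[int] = [6, 7, 8, 9, 10]
    session_minutes: int = 50


class RunConfig(BaseModel):
    """Validated configuration for the CLI pipeline (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    reference_rates: dict[str, float] = {
        "clicks": 10.0,
        "keystrokes": 100.0,
        "scroll_px": 2000.0,
        "cursor_px": 5000.0,
    }
    weights: Optional[dict[str, float]] = None
    bar: BarConfig = BarConfig()
    bin_seconds: int = 10
    session_minutes: int = Field(default=50, gt=0)
    cohort: CohortConfig = CohortConfig()
    seed: int = Field(default=0, ge=0, lt=2**63)

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if set(self.reference_rates) != set(CHANNELS):
            raise ValueError(f"reference_rates must have keys {CHANNELS}")
        ReferenceRates(**self.reference_rates)
        if self.weights is not None:
            if set(self.weights) != {"w_click", "w_key", "w_scroll", "w_cursor"}:
                raise ValueError(
                    "weights must have keys w_click, w_key, w_scroll, w_cursor"
                )
            WeightConfig(**self.weights)
        if self.bin_seconds != 10:
            raise ValueError("bin_seconds is fixed at 10")
        return self

    def weight_config(self) -> WeightConfig:
        if self.weights is not None:
            return WeightConfig(**self.weights)
        return default_weights(ReferenceRates(**self.reference_rates))

    def color_cuts(self) -> ColorCuts:
        return ColorCuts(red_below=self.bar.red_below, green_above=self.bar.green_above)

    def bar_deltas(self) -> dict:
        from .engine import Band

        return {
            Band.ABOVE_HIGHEST: self.bar.increment_above_highest,
            Band.HIGH_TO_HIGHEST: self.bar.increment_high,
            Band.MID: self.bar.increment_mid,
            Band.LOWEST_TO_LOW: self.bar.decrement_low,
            Band.BELOW_LOWEST: self.bar.decrement_below_lowest,
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def load_config(path: Union[str, Path, None]) -> RunConfig:
    """Load a RunConfig from YAML, JSON or TOML (by extension); None -> defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text())
    elif suffix == ".json":
        data = json.loads(path.read_text())
    else:
        data = yaml.safe_load(path.read_text()) or {}
    return RunConfig(**data)
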