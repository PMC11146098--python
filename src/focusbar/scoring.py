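"""Questionnaire scoring: the three 7-item 0–21 study scales and the SUS.

The concentration, motivation and effort scales each sum seven already-
oriented four-point Likert items (0–3) to an index between 0 and 21. For
motivation and effort higher is better; for concentration *lower* is better
(the items ask about lapses — daydreaming, mind fog, inattention). The
System Usability Scale follows the standard 10-item scoring: odd items
contribute (value − 1), even items (5 − value), and the total is scaled by
2.5 to a 0–100 score, with 68 the conventional average.

Reverse-coding of raw instrument items is the data-preparation caller's
duty; this module expects oriented item values and refuses missing data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

STUDY_SCALES = ("concentration", "motivation", "effort")

#: Direction in which larger index values are "better".
SCALE_ORIENTATION = {
    "concentration": "lower_better",
    "motivation": "higher_better",
    "effort": "higher_better",
}


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class ScaleResponse:
    """Seven oriented 0–3 Likert items for one study scale."""

    scale: str
    items: tuple[int, ...]

    def __post_init__(self) -> None:
        if self.scale not in STUDY_SCALES:
            raise ScoringError(f"unknown scale {self.scale!r}")
        _check_items(self.items, n=7, lo=0, hi=3)


@dataclass(frozen=True)
class SusResponse:
    """Ten raw 1–5 SUS items."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        _check_items(self.items, n=10, lo=1, hi=5)


def _check_items(items: Sequence, n: int, lo: int, hi: int) -> None:
    if len(items) != n:
        raise ScoringError(f"expected {n} items, got {len(items)}")
    for i, v in enumerate(items, start=1):
        if v is None or (isinstance(v, float) and v != v):
            raise ScoringError(f"item {i} is missing (no imputation performed)")
        if not float(v).is_integer() or not lo <= int(v) <= hi:
            raise ScoringError(f"item {i} must be an integer in [{lo}, {hi}], got {v!r}")


def score_scale(response: ScaleResponse) -> int:
    """Sum of the seven items: the 0–21 index."""
    return int(sum(response.items))


def score_sus(response: SusResponse) -> float:
    """Standard SUS score in [0, 100]."""
    total = 0
    for i, v in enumerate(response.items, start=1):
        total += (v - 1) if i % 2 == 1 else (5 - v)
    return total * 2.5


def score_table(responses: pd.DataFrame) -> pd.DataFrame:
    """Score a tidy item-level table into per-administration index scores.

    Expects the simulator's wide format (participant_id, session, condition,
    feedback, concentration_1..7, motivation_1..7, effort_1..7, optional
    sus_1..10). Returns one row per administration with columns
    concentration, motivation, effort and sus (NaN where SUS was not
    administered, i.e. at baseline).
    """
    required = {"participant_id", "session", "condition", "feedback"}
    missing = required - set(responses.columns)
    if missing:
        raise ScoringError(f"missing columns: {sorted(missing)}")

    out = responses[["participant_id", "session", "condition", "feedback"]].copy()
    for scale in STUDY_SCALES:
        cols = [f"{scale}_{i}" for i in range(1, 8)]
        if any(c not in responses.columns for c in cols):
            raise ScoringError(f"missing item columns for scale {scale!r}")
        out[scale] = [
            score_scale(ScaleResponse(scale=scale, items=tuple(int(v) for v in row)))
            for row in responses[cols].to_numpy()
        ]
    sus_cols = [f"sus_{i}" for i in range(1, 11)]
    if all(c in responses.columns for c in sus_cols):
        sus_scores = []
        for row in responses[sus_cols].to_numpy():
            if pd.isna(row).all():
                sus_scores.append(float("nan"))
            else:
                sus_scores.append(
                    score_sus(SusResponse(items=tuple(int(v) for v in row)))
                )
        out["sus"] = sus_scores
    return out
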