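"""Synthetic interaction streams and synthetic ABA study cohorts.

Nothing in the original study's raw data was released, so every downstream
stage is exercised on simulated data with the study's published structure:

* **Interaction streams** come from a discrete-state Markov emitter. A user
  moves between behavioral states (typing, reading, browsing, idle) with
  geometric dwell times; each state emits Poisson counts per 10-second bin
  on the four channels. This is the minimal generative structure that
  reproduces the qualitative concern users raised about the probe — reading
  produces far less keyboard input than writing and so looks "idle" to a
  keystroke-weighted level.
* **Questionnaire cohorts** follow the study design: 27 participants, a
  baseline administration plus up to 12 VR sessions of three 7-item
  0–21 scales and a 10-item SUS, feedback on sessions 6–10 only (ABA),
  attrition truncating later sessions, and a shared per-participant random
  effect inducing correlation between a participant's baseline and VR
  scores.

All generation is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .engine import BIN_SECONDS, BINS_PER_MINUTE, CHANNELS, InteractionSample

RngLike = Union[int, np.random.Generator]


def _rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class SimulationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Interaction-stream archetypes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StateSpec:
    """One behavioral state: per-minute mean channel activity and mean dwell.

    Rates are per minute for readability; emission divides by the number of
    bins per minute. Dwell is geometric over bins with the given mean in
    minutes.
    """

    name: str
    clicks: float
    keystrokes: float
    scroll_px: float
    cursor_px: float
    dwell_minutes: float = 2.0

    def __post_init__(self) -> None:
        for ch in CHANNELS:
            if getattr(self, ch) < 0:
                raise SimulationError(f"state {self.name}: {ch} rate must be >= 0")
        if self.dwell_minutes <= 0:
            raise SimulationError(f"state {self.name}: dwell must be > 0")


@dataclass(frozen=True)
class ArchetypeSpec:
    """A Markov chain over behavioral states with Poisson bin emission."""

    name: str
    states: tuple[StateSpec, ...]
    transition: tuple[tuple[float, ...], ...]

    def __post_init__(self) -> None:
        k = len(self.states)
        if k == 0:
            raise SimulationError("archetype needs at least one state")
        t = np.asarray(self.transition, dtype=float)
        if t.shape != (k, k):
            raise SimulationError(
                f"transition matrix must be {k}x{k}, got {t.shape}"
            )
        if (t < 0).any() or not np.allclose(t.sum(axis=1), 1.0, atol=1e-9):
            raise SimulationError("transition rows must be nonnegative and sum to 1")


def _single_state(name: str, **rates: float) -> ArchetypeSpec:
    return ArchetypeSpec(
        name=name, states=(StateSpec(name=name, **rates),), transition=((1.0,),)
    )


# Per-minute activity rates per state. The study published no interaction
# distributions; these are labelled stand-ins chosen so that focused work
# (typing/browsing) is clearly separated from idling, with reading in between
# (low keyboard, nonzero scroll/cursor).
TYPING = _single_state(
    "typing", clicks=4, keystrokes=220, scroll_px=300, cursor_px=1200,
    dwell_minutes=4.0,
)
READING = _single_state(
    "reading", clicks=2, keystrokes=5, scroll_px=1200, cursor_px=2000,
    dwell_minutes=3.0,
)
BROWSING = _single_state(
    "browsing", clicks=12, keystrokes=40, scroll_px=4000, cursor_px=7000,
    dwell_minutes=2.0,
)
IDLE = _single_state(
    "idle", clicks=0, keystrokes=0, scroll_px=0, cursor_px=0, dwell_minutes=1.5
)


def work_session_archetype() -> ArchetypeSpec:
    """Mixed academic-work behavior: mostly typing/reading, some browsing,
    occasional idling. Used as the default calibration history."""
    states = (
        TYPING.states[0],
        READING.states[0],
        BROWSING.states[0],
        IDLE.states[0],
    )
    transition = (
        (0.0, 0.5, 0.3, 0.2),   # after typing
        (0.6, 0.0, 0.2, 0.2),   # after reading
        (0.5, 0.4, 0.0, 0.1),   # after browsing
        (0.4, 0.4, 0.2, 0.0),   # after idling
    )
    return ArchetypeSpec(name="work_session", states=states, transition=transition)


ARCHETYPES: dict[str, ArchetypeSpec] = {
    "typing": TYPING,
    "reading": READING,
    "browsing": BROWSING,
    "idle": IDLE,
    "work_session": work_session_archetype(),
}


def simulate_stream(
    archetype: ArchetypeSpec, minutes: int, seed: RngLike
) -> list[InteractionSample]:
    """Emit one session of 10-second interaction bins.

    The state chain starts in state 0, dwells a geometric number of bins,
    then jumps per the transition matrix; every bin emits independent
    Poisson counts at the current state's rates. Deterministic given seed.
    """
    if minutes <= 0:
        raise SimulationError(f"minutes must be > 0, got {minutes}")
    rng = _rng(seed)
    n_bins = minutes * BINS_PER_MINUTE
    rates = np.array(
        [[getattr(s, ch) / BINS_PER_MINUTE for ch in CHANNELS]
         for s in archetype.states]
    )
    trans = np.asarray(archetype.transition, dtype=float)
    k = len(archetype.states)

    state_seq = np.empty(n_bins, dtype=np.intp)
    state = 0
    i = 0
    while i < n_bins:
        mean_bins = archetype.states[state].dwell_minutes * BINS_PER_MINUTE
        p = min(1.0, 1.0 / mean_bins)
        dwell = int(rng.geometric(p))
        j = min(n_bins, i + dwell)
        state_seq[i:j] = state
        i = j
        if k > 1:
            state = int(rng.choice(k, p=trans[state]))

    counts = rng.poisson(rates[state_seq])  # (n_bins, 4)
    return [
        InteractionSample(
            t_start=float(b * BIN_SECONDS),
            clicks=int(counts[b, 0]),
            keystrokes=int(counts[b, 1]),
            scroll_px=float(counts[b, 2]),
            cursor_px=float(counts[b, 3]),
        )
        for b in range(n_bins)
    ]


# ---------------------------------------------------------------------------
# Questionnaire cohorts
# ---------------------------------------------------------------------------

SCALES = ("concentration", "motivation", "effort")

#: Default per-scale (mean, SD) for the baseline and VR conditions. These are
#: latent (pre-truncation) normal parameters; the VR motivation/effort means
#: sit above the 21-point ceiling, so realized scores pile up near the top of
#: the scale.
DEFAULT_SCALE_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "concentration": {"baseline": (15.63, 5.20), "vr": (3.73, 3.12)},
    "motivation": {"baseline": (18.96, 3.99), "vr": (23.72, 4.13)},
    "effort": {"baseline": (15.15, 4.39), "vr": (22.48, 4.60)},
}
DEFAULT_SUS_PARAMS: tuple[float, float] = (72.71, 17.71)

#: Sessions attended per participant (descending), matching the study's
#: attrition facts: 27 participants, 10 completing all 12 sessions, 16 with
#: at least two feedback sessions, 200 sessions in total (mean 7.4).
DEFAULT_DROPOUT: tuple[int, ...] = (
    12, 12, 12, 12, 12, 12, 12, 12, 12, 12,
    10, 9, 8, 8, 7, 7,
    5, 4, 4, 3, 3, 3, 2, 2, 2, 2, 1,
)


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one simulated ABA cohort."""

    n_participants: int = 27
    scale_params: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_SCALE_PARAMS.items()
        }
    )
    sus_params: tuple[float, float] = DEFAULT_SUS_PARAMS
    rho: float = 0.5
    max_sessions: int = 12
    feedback_sessions: tuple[int, ...] = (6, 7, 8, 9, 10)
    dropout: Optional[tuple[int, ...]] = None
    session_minutes: int = 50

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise SimulationError("n_participants must be >= 1")
        if not -1.0 <= self.rho <= 1.0:
            raise SimulationError(f"|rho| must be <= 1, got {self.rho}")
        for scale, conds in self.scale_params.items():
            for cond, (m, s) in conds.items():
                if s < 0:
                    raise SimulationError(f"{scale}/{cond}: SD must be >= 0")
        if self.sus_params[1] < 0:
            raise SimulationError("SUS SD must be >= 0")
        if self.dropout is not None and len(self.dropout) != self.n_participants:
            raise SimulationError(
                "dropout schedule length must equal n_participants"
            )

    def sessions_per_participant(self) -> tuple[int, ...]:
        if self.dropout is not None:
            return self.dropout
        if self.n_participants == len(DEFAULT_DROPOUT):
            return DEFAULT_DROPOUT
        # resample the default attrition pattern to other cohort sizes
        q = np.linspace(0, 1, self.n_participants)
        pat = np.quantile(np.array(DEFAULT_DROPOUT, dtype=float), 1 - q)
        return tuple(int(max(1, min(self.max_sessions, round(v)))) for v in pat)


@dataclass
class StudyTable:
    """One simulated cohort: item-level responses plus optional streams.

    ``responses`` is a wide tidy frame, one row per administration
    (participant x session; session 0 = baseline) with columns
    participant_id, session, condition, feedback, concentration_1..7,
    motivation_1..7, effort_1..7, sus_1..10 (SUS absent at baseline).
    ``streams`` maps (participant_id, session) to the session's bins.
    """

    responses: pd.DataFrame
    spec: CohortSpec
    streams: dict[tuple[str, int], list[InteractionSample]] = field(
        default_factory=dict
    )


def simulate_item_responses(
    target_mean: float,
    target_sd: float,
    n_items: int = 7,
    levels: int = 4,
    n: int = 1,
    seed: RngLike = 0,
) -> np.ndarray:
    """Draw item-level Likert responses whose sums track target moments.

    A target sum is drawn from a normal(target_mean, target_sd) truncated to
    [0, n_items*(levels-1)] and rounded; it is then spread across items as
    evenly as possible, with the remainder going to randomly chosen items.
    Returns an (n, n_items) integer array with entries in {0..levels-1}.

    Note the realized moments are those of the rounded truncated normal, not
    of the untruncated target — with a target near a scale end the realized
    mean is pulled inward.
    """
    max_sum = n_items * (levels - 1)
    if not 0 <= target_mean <= max_sum:
        raise SimulationError(
            f"target mean {target_mean} outside feasible range [0, {max_sum}]"
        )
    if target_sd < 0:
        raise SimulationError("target SD must be >= 0")
    rng = _rng(seed)
    if target_sd == 0:
        sums = np.full(n, int(round(target_mean)))
    else:
        from scipy.stats import truncnorm

        a = (0 - target_mean) / target_sd
        b = (max_sum - target_mean) / target_sd
        draws = truncnorm.rvs(
            a, b, loc=target_mean, scale=target_sd, size=n, random_state=rng
        )
        sums = np.clip(np.rint(draws), 0, max_sum).astype(int)
    return np.array([_spread_sum(s, n_items, levels, rng) for s in sums])


def _spread_sum(total: int, n_items: int, levels: int, rng: np.random.Generator) -> np.ndarray:
    """Distribute an integer total over items as evenly as possible."""
    base, rem = divmod(int(total), n_items)
    items = np.full(n_items, base, dtype=int)
    if rem:
        items[rng.choice(n_items, size=rem, replace=False)] += 1
    # feasible totals always give values within {0..levels-1}
    assert items.max() <= levels - 1 and items.min() >= 0
    return items


def _latent_scores(
    mean: float,
    sd: float,
    shared: np.ndarray,
    rho: float,
    lo: float,
    hi: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Latent normal scores with a shared participant effect, clipped to range."""
    eps = rng.standard_normal(shared.shape)
    latent = mean + sd * (
        math.sqrt(max(0.0, rho)) * shared + math.sqrt(1 - max(0.0, rho)) * eps
    )
    return np.clip(latent, lo, hi)


def simulate_study(
    cohort: CohortSpec, seed: RngLike = 0, include_streams: bool = False
) -> StudyTable:
    """Generate one full ABA cohort.

    Per participant: one shared standard-normal effect per scale couples the
    baseline and all VR session scores at correlation ``rho``; attrition
    follows the dropout schedule; the feedback flag follows the ABA schedule
    (on for sessions 6–10 by default). When ``include_streams`` is set, each
    VR session also gets a mixed work-behavior interaction stream.
    """
    rng = _rng(seed)
    sessions = cohort.sessions_per_participant()
    rows: list[dict] = []
    streams: dict[tuple[str, int], list[InteractionSample]] = {}
    arch = ARCHETYPES["work_session"]

    for p_idx in range(cohort.n_participants):
        pid = f"P{p_idx + 1:02d}"
        n_sess = sessions[p_idx]
        shared = {scale: rng.standard_normal() for scale in SCALES}
        shared["sus"] = rng.standard_normal()

        # one latent score per scale per administration (baseline = session 0)
        admin_sessions = [0] + list(range(1, n_sess + 1))
        for sess in admin_sessions:
            cond = "baseline" if sess == 0 else "vr"
            feedback = sess in cohort.feedback_sessions
            row: dict = {
                "participant_id": pid,
                "session": sess,
                "condition": cond,
                "feedback": bool(feedback and sess > 0),
            }
            for scale in SCALES:
                m, s = cohort.scale_params[scale][cond]
                latent = _latent_scores(
                    m, s, np.array(shared[scale]), cohort.rho, 0, 21, rng
                )
                total = int(np.clip(np.rint(latent), 0, 21))
                items = _spread_sum(total, 7, 4, rng)
                for i, v in enumerate(items, start=1):
                    row[f"{scale}_{i}"] = int(v)
            if cond == "vr":
                m, s = cohort.sus_params
                latent = _latent_scores(
                    m, s, np.array(shared["sus"]), cohort.rho, 0, 100, rng
                )
                contrib_total = int(np.clip(np.rint(latent / 2.5), 0, 40))
                contribs = _spread_sum(contrib_total, 10, 5, rng)
                for i, c in enumerate(contribs, start=1):
                    # odd items are positively worded (raw = contrib + 1),
                    # even items negatively (raw = 5 - contrib)
                    raw = c + 1 if i % 2 == 1 else 5 - c
                    row[f"sus_{i}"] = int(raw)
            rows.append(row)
            if include_streams and sess > 0:
                stream_seed = int(rng.integers(0, 2**31 - 1))
                streams[(pid, sess)] = simulate_stream(
                    arch, cohort.session_minutes, stream_seed
                )

    responses = pd.DataFrame(rows)
    return StudyTable(responses=responses, spec=cohort, streams=streams)
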