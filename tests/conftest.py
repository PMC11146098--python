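import numpy as np
import pytest

from focusbar.engine import (
    BIN_SECONDS,
    InteractionSample,
    WeightConfig,
    default_weights,
)


@pytest.fixture
def weights() -> WeightConfig:
    return default_weights()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240511)


def make_log(per_bin_rows):
    """Build a session log from (clicks, keys, scroll, cursor) rows, one per
    consecutive 10-second bin starting at t=0."""
    return [
        InteractionSample(
            t_start=float(i * BIN_SECONDS),
            clicks=int(c),
            keystrokes=int(k),
            scroll_px=float(s),
            cursor_px=float(m),
        )
        for i, (c, k, s, m) in enumerate(per_bin_rows)
    ]


def random_log(rng: np.random.Generator, minutes: int = 50):
    """A bursty random session log: per-bin Poisson activity with random
    per-minute intensity, including fully idle minutes."""
    rows = []
    for _ in range(minutes):
        if rng.random() < 0.2:  # idle minute
            rows.extend([(0, 0, 0, 0)] * 6)
        else:
            lam = rng.uniform(0.2, 3.0)
            rows.extend(
                zip(
                    rng.poisson(1.7 * lam, 6),
                    rng.poisson(17 * lam, 6),
                    rng.poisson(330 * lam, 6),
                    rng.poisson(830 * lam, 6),
                )
            )
    return make_log(rows)
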