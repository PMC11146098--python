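# Example focusbar run configuration (all keys optional; unknown keys rejected).

# Nominal per-minute activity of an engaged user; default weights are the
# reciprocals, so each channel contributes 1.0 per minute at these rates.
reference_rates:
  clicks: 10.0
  keystrokes: 100.0
  scroll_px: 2000.0
  cursor_px: 5000.0

# Uncomment to pin explicit channel weights instead:
# weights: {w_click: 0.1, w_key: 0.01, w_scroll: 0.0005, w_cursor: 0.0002}

bar:
  initial_fill: 50.0
  increment_above_highest: 10.0
  increment_high: 5.0
  increment_mid: 2.5
  decrement_low: -5.0
  decrement_below_lowest: -10.0
  red_below: 40.0
  green_above: 60.0

session_minutes: 50

cohort:
  n_participants: 27
  rho: 0.5
  max_sessions: 12
  feedback_sessions: [6, 7, 8, 9, 10]   # ABA: off 1-5, on 6-10, off 11-12
  session_minutes: 50

seed: 0
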