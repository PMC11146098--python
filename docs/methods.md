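# Methods

## The feedback engine

The engine models continuous attention monitoring as a pure function of an
interaction log. Interaction arrives in fixed 10-second bins of four
nonnegative channels (clicks, keystrokes, scroll px, cursor px). Each
minute `m` the **input level** is the weighted sum of all activity with
`t_start ∈ [60(m−1), 60m)`; missing bins contribute zero, so total idleness
is a level of 0, and the first tick occurs at minute 1 (no partial first
minute).

**Weights.** The probe's original channel weights were tuned in pilots and
never published. The package defaults to reciprocal-of-reference-rate
weights: given nominal per-minute rates for an engaged user (defaults:
10 clicks, 100 keystrokes, 2,000 scroll px, 5,000 cursor px per minute),
each weight is `1/rate`, so each channel contributes 1.0 at nominal
activity and a nominally engaged minute scores 4.0. This is a reproducible,
unit-consistent stand-in, fully overridable in the run configuration.

**Calibration.** Thresholds are per-user: μ is the mean and σ the
*population* standard deviation of historical per-minute levels, with cut
points μ ± σ/4 and μ ± σ/2. At least 5 historical minutes are required.
The intended history is all per-minute levels from the user's prior
sessions; with no prior data, the first five minutes of the current session
can be used with thresholds frozen thereafter (no future leakage). Two
numerical details:

* For highly skewed nonnegative histories μ − σ/2 (and, more rarely,
  μ − σ/4) can be negative; both lower cut points are floored at 0 so the
  ordering invariant `lowest ≤ low ≤ μ ≤ high ≤ highest` always holds.
* A zero-variance history produces a flagged degenerate threshold set: any
  deviation from μ classifies as above/below, while a level exactly at μ
  classifies mid (so a perfectly constant user keeps earning the mid-band
  reward rather than being punished by ties).

**Band boundaries.** The partition is half-open with ties falling downward:
a level must *strictly exceed* a cut point to move up a band
(`level > highest` → +10; `high < level ≤ highest` → +5;
`low < level ≤ high` → +2.5; `lowest < level ≤ low` → −5;
`level ≤ lowest` → −10). Tie behavior at an exact cut point is unobservable
with continuous levels; a single documented convention is used and tested
explicitly.

**Bar dynamics.** Deltas are absolute percentage points of full bar width
(not relative to current fill), clamped to [0, 100]. The bar starts at 50,
which must be yellow; color cut points are red < 40, yellow 40–60 inclusive,
green > 60 (configurable, constrained only by the start color and the
endpoint colors). Two forced trajectories follow arithmetically and serve
as fixed points of the design: sustained mid-band activity saturates
50 → 100 in exactly 20 minutes, and total idleness drains 50 → 0 in exactly
5 minutes. The per-minute update is monotone in the input level, so a
session that dominates another minute-by-minute can never end with a lower
fill.

With feedback disabled (the A phases of the ABA schedule) the replay still
records levels and bands — the probe logs during all sessions — but no
fill/color is produced.

## The synthetic-data generator

**Interaction streams.** No interaction-level distributions were published;
streams are generated by a discrete-state Markov chain over behavioral
states (typing, reading, browsing, idle) with geometric dwell times (means
4, 3, 2, 1.5 minutes) and independent Poisson counts per 10-second bin at
per-state rates. The state rates are labelled stand-ins chosen to separate
focused work from idling and to reproduce the probe's known blind spot:
reading emits little keyboard input (5 keys/min vs 220 for typing) yet
nonzero scroll/cursor activity, so a keystroke-heavy weighting can misread
reading as disengagement. Real keystroke dynamics (diurnal rhythm,
autocorrelated bursts within a state, inter-key timing) are not modeled;
passing tests demonstrate the pipeline's correctness and discrimination
between archetypes, not behavioral realism.

A consequence of per-user calibration worth noting: a single-archetype
stream calibrated against *its own* levels puts its mean at μ, making the
bar a near-symmetric random walk. Discrimination between behaviors is only
meaningful against thresholds from heterogeneous prior behavior, which is
how both the deployment and the tests use the engine (calibrate on a mixed
work-session history, then replay pure archetypes).

**Cohorts.** The default cohort reproduces the study design's structure:
27 participants; baseline plus up to 12 sessions; feedback on sessions
6–10 only; a fixed attrition pattern (10 completers, 16 participants with
at least two feedback sessions, 200 sessions in total, mean 7.4). Scale
scores are drawn from normals with the published condition moments
(e.g. concentration 15.63 ± 5.20 at baseline vs 3.73 ± 3.12 in-session),
coupled within participant by a shared standard-normal effect at
correlation ρ = 0.5 (unreported in the source; configurable), clipped into
the scale range, rounded, and spread across the 7 items as evenly as
possible with a randomized remainder. The published VR-condition motivation
(23.72) and effort (22.48) means sit *above* the 21-point ceiling of their
own scale; the generator treats condition moments as latent (pre-clipping)
parameters, so realized scores for those cells pile up near 21. SUS scores
are generated the same way on the 0–100 scale and decomposed into 10 raw
items through the standard odd/even contribution scheme.

`simulate_item_responses`, the public single-scale generator, instead uses
a proper truncated normal for the target sum; its realized moments match
the truncated distribution's moments (not the untruncated targets), which
is what the tests assert against a `truncnorm` oracle. Dropout is a fixed
truncation schedule, not an outcome-dependent process.

## Statistics

* **Test selection:** Shapiro–Wilk per side and median-centered Levene
  across sides at α = 0.05 (both choices where the source is silent:
  sides rather than differences for normality; the robust Levene variant).
  Non-normality takes precedence over variance heterogeneity because the
  Welch test still assumes normality. Constant data are treated as
  non-normal (Shapiro–Wilk is undefined there).
* **Wilcoxon signed-rank:** zero differences are dropped (wilcox
  convention). For n ≤ 12 the two-sided p is computed by the package's own
  full enumeration of all 2^n sign assignments with midranks, which is
  exact also under tied |differences| (library "exact" modes typically
  round against the untied null there); above n = 12 a normal
  approximation with continuity correction is used. The reported statistic
  is min(W⁺, W⁻).
* **Cohen's d:** paired convention (mean difference / SD of differences)
  by default, pooled-SD convention for independent groups; the convention
  is recorded in every result, and degenerate (zero-SD) cases raise rather
  than return ±∞.
* **RM-ANOVA:** one-way within-subjects sums of squares computed directly,
  with listwise deletion of incomplete participants and dfs
  (k−1, (k−1)(n−1)). The direct computation pins the degenerate case (zero
  between-session sum of squares → F = 0, p = 1) that packaged fitters
  return as NaN; statsmodels' `AnovaRM` is the cross-check in the tests.
  No sphericity correction by default; Greenhouse–Geisser ε is available
  as an option.
* **Inclusion rules** mirror the study: the baseline-vs-VR contrast pairs
  each baseline score with the participant's mean over all their VR
  sessions (everyone with baseline + session 1); the feedback contrast
  includes participants with ≥ 2 feedback sessions; completers vs
  non-completers is an independent t on per-participant VR means. An empty
  contrast is reported, not fatal. No multiple-testing correction is
  applied across the report, matching the analysis being reproduced.

## Problem sizes and determinism

Every stochastic component takes an explicit integer seed
(`numpy.random.default_rng`); identical (config, seed) pairs give
byte-identical outputs end to end. The shipped simulations use 1,000
random sessions for replay-oracle equivalence, 10,000 fuzzed histories for
calibration exactness, 2,000 replicates for the decision-tree type-I
check, 100 replicate cohorts for power, and 200 paired samples for the
exact-Wilcoxon enumeration check; together they run in well under a minute
on one CPU.

## Known limitations

* The band-time split reported by the acceptance script depends entirely
  on the stand-in behavioral archetypes and calibration policy; it is a
  property of the simulator, not an estimate of any real cohort's split.
* The regression of concentration on mean input level is exercised as
  parameter recovery on synthetically coupled data; the cohort generator
  itself does not couple questionnaire scores to interaction streams.
* Negative paired-score correlations are not representable by the
  shared-effect construction and are treated as ρ = 0.
* The engine is an offline replayer; live OS event capture, rendering and
  any VR integration are out of scope.
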