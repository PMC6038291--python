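# Methods

## The measure and percentile model

A prescribing measure is a monthly ratio per entity (practice or
commissioning body): numerator prescriptions over a denominator set of
related prescriptions, with the numerator drugs a subset of the denominator
drugs, so the ratio lies in [0, 1]. Using a drug-set denominator rather than
list size cancels population-level variation in how much of the drug class
is prescribed at all. A month with a zero denominator carries no information
about prescribing choice and is treated as missing, not zero; by default a
ratio above 1 is rejected as a data error (`check_subset=False` disables
this for measures without the subset guarantee).

Within each month, reporting entities are ranked: an entity at average rank
r among n reporting peers (ties share the mean rank) gets percentile
100·(r−1)/(n−1), so the unique extremes sit exactly at 0 and 100. A lone
reporter gets the neutral 50 — any other convention would fabricate an
extreme position from no peer information. Percentiles are a monotone
function of the month's ratios, invariant to entity order, and unaffected by
entities with missing ratios. Orientation (whether high ratio means worse
care) belongs to the measure definition, not to this engine: it ranks
low ratio → low percentile, always.

The percentile trajectory of one entity is the observation stream x_i the
detector consumes. Ranking is what makes detection peer-comparative: shared
seasonality and population-wide trends move every entity together and cancel
out of the ranks, while an entity that stands still during a population
transition *does* change percentile — a real, reportable change in relative
position.

## The detector

Reference statistics are the arithmetic mean μ₀ and the population standard
deviation σ (divide by n, not n−1) of the first 12 observed months. The
population form was chosen because the window is a complete description of
the baseline period, not a sample from a larger one; at n = 12 the numerical
difference is small, but a single convention is needed for reproducibility.
The allowance is K = 0.5σ and the decision interval H = 5σ, standard
choices for detecting a shift of about one σ with a long in-control run
length. Triggering is inclusive (C ≥ H).

The two-sided recursions and the alert rule are given in the README. Design
points that required a decision:

* **Reset window includes the trigger month.** After any trigger the
  reference is re-estimated from the 12 most recent observed months
  *including* the month that triggered. This lets the refreshed mean absorb
  the drift as fast as possible, so a completed change stops alerting
  sooner.
* **Continuing-change runs restart the accumulation each month.** During a
  continuing run the reference is re-reset every month from the preceding
  12 observed months. An accumulator carried over from before the re-reset
  would mix deviations measured against different references — and, in
  practice, would keep a run alive for about half a window after a drift
  stalls, defeating the purpose of the exit rule. So within a run, C for
  the triggering direction is recomputed from zero against each month's
  refreshed reference (it equals that month's deviation beyond the
  allowance) and the run persists only while this quantity strictly grows.
  The first month it fails to grow, both accumulators reset, the reference
  is refreshed (including that month), and the detector returns to normal.
  Consequence: an accelerating or steadily climbing drift re-alerts
  monthly; a drift that levels off goes quiet within a month or two —
  though a later "echo" trigger can follow via the standard mechanism if
  the refreshed window still straddles the old level.
* **The opposite-direction accumulator cannot trigger during a run.** One
  run describes one directional episode; the opposite side resumes when the
  run exits.
* **Ties.** If both sides cross H in the same month (pathological), the
  larger magnitude wins; an exact tie counts as an increase.
* **σ = 0 windows.** A perfectly flat window gives K = H = 0: any nonzero
  deviation triggers immediately (zero deviation does not). This is the
  intended behaviour — an entity whose rank never moves should alert on the
  smallest real movement — but users monitoring ultra-stable series can set
  `sigma_floor` to damp it.
* **Data sufficiency.** At least 13 observed months (window + 1) are
  required; below that the entity is logged and skipped, producing no
  alerts but still counting in summary denominators.

Missing months are dropped before the algorithm runs, so gaps shift alert
*dates* but never change which observations trigger. `detection_delay_closed_form`
gives the exact first-alert month, ⌈H/(Δ−K)⌉, for a clean step Δ > K on a
noiseless baseline; it serves as an analytic cross-check on the detector.

## Known behaviour under noise-regime change

H adapts to the σ estimated from 12 months. Two consequences worth knowing:

* With a noisy series, a 12-month σ estimate is itself noisy; windows that
  underestimate σ set H too low and produce false alarms. On a stationary
  series with independent Gaussian-like rank noise, the chance of at least
  one alert over ~5 years is roughly one in two. Alert summaries, not
  individual alerts, are the right tool for judging background rates.
* If the variability of a series changes over time (e.g. peer ratios spread
  out during a population transition, then re-bunch), a reference window
  estimated in a quiet phase can make ordinary noise in a later phase look
  like change. This is a property of the method, visible in the synthetic
  transition scenario, and is the reason `sigma_floor` exists.

## The synthetic generator

`ScenarioSpec`/`generate` emulate what the detector assumes about real
prescribing measures. Per entity-month, a denominator volume is drawn
Poisson around the entity's characteristic volume (lognormal with scale 0.4
around `mean_denominator`, zeroed with probability `dropout_prob`); the
target ratio is

    clip(baseline + trend·t + seasonal(t) + offset + interventions(t)
         + noise(t)·sqrt(mean_denominator / volume), 0, 1)

and the numerator is binomial at that target — guaranteeing integer counts,
numerator ≤ denominator, and sampling noise that grows as volume shrinks
(small practices have erratic percentiles). Entity offsets are uniform on
±`entity_spread`: a uniform peer distribution makes the ratio→percentile map
approximately linear away from the extremes (a ratio shift of d moves an
entity by about 100·d/(2·spread) points), which makes planted effect sizes
interpretable in percentile units. Seasonality is a shared sinusoid, so it
cancels out of the percentiles. Everything is deterministic under the seed.

Defaults (100 entities, 48 months, baseline ratio 0.5, mean denominator 500,
spread 0.25, monthly disturbance SD 0.01) describe a mid-sized indicator
panel: denominators of a few hundred give binomial rank noise of a few
percentile points, comparable to a typical practice-level measure.

Two canned scenarios:

* `step_recovery_scenario` — 5 entities at known mid-range offsets step
  +0.125 in ratio (≈ +25 percentile points) at month 24 among 95 unchanged
  peers; used to measure detection timing and the background alert rate.
* `fig1_like_scenario` — a population-wide transition with staggered
  adoption times over 72 months. The focal entity E000 lags, then catches
  up abruptly with an overshoot; the tracker E001 follows the population-
  *median* ratio path at zero offset (realised exactly by telescoping
  monthly steps), so its rank stays mid-pack. The tracker stays alert-free
  in most replicates but not all — the σ-estimation false-alarm mode above
  is part of the method, and the transition's changing peer spread
  exercises it.

What the generator does **not** emulate: real measures' heavy-tailed volume
distributions across practices, serially correlated prescribing habits
(noise here is independent month to month), entity-specific seasonality,
data-revision artefacts, or entities entering/leaving the roster. Passing
tests on this generator show the detector behaves correctly under its own
model assumptions; they do not certify alert quality on any particular real
measure.

## Summaries

`summarize` aggregates alert events against a full roster and month range:
per (measure, month), the percentage of entities with at least one alert of
each direction (an entity alerting twice in a month counts once); per
(entity, month), event counts on the complete grid with zeros, ready for
histograms; and overall means, total events over (entities × months), with
retriggers counted as events since the continuing method emits them
deliberately. Entities with no alerts — including those skipped for
insufficient data — count in every denominator.

## Problem sizes

The test suite and the acceptance script use 1,000 random series for the
oracle comparison, a 12-point (Δ, σ) grid for the closed-form delay, 100
random confinements for the deadband, 100 gap-insertion replicates, the
100-entity × 48-month step scenario, and the 50-entity × 72-month transition
scenario — sizes at which every check runs in seconds while leaving no
corner of the state machine unexercised.
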