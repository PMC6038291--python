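# peercusum

Two-sided CUSUM change detection on peer-comparative percentile measures.

Health systems track prescribing quality with ratio indicators: a numerator
count of prescriptions (say, a branded drug) over a denominator count of
related prescriptions (all forms of that drug), per practice or commissioning
body, per month. Each month every entity is ranked 0–100 among its peers on
each measure. A single bad month says little; what matters is a *sustained*
shift in an entity's position relative to its peers — including the case
where an entity stands still while everyone else moves.

`peercusum` implements a change detector for exactly that stream, for
analysts and service operators who run alerting over many entities and
measures at once, plus the measure/percentile engine it consumes, a
synthetic-population generator for testing, and alert-frequency summaries.

## The detector

For one entity's monthly percentile series x_i, the reference mean μ₀ and
standard deviation σ are estimated over the first 12 observed months; the
allowance is K = 0.5σ and the decision interval H = 5σ. Two accumulators
track deviations beyond the allowance:

    C⁺_i = max(0, x_i − (μ₀ + K) + C⁺_{i−1})
    C⁻_i = min(0, x_i − (μ₀ − K) + C⁻_{i−1})

When C⁺ ≥ H an **increase** alert fires; when |C⁻| ≥ H a **decrease** alert
fires. Because K and H scale with σ, noisy series (small prescribing volumes)
demand larger sustained shifts, while very stable series alert on small ones.
Missing months — usually a zero denominator — are dropped; an entity with
fewer than 13 observed months is not scored.

Two post-trigger behaviours:

* **standard** — reset C to 0 and re-estimate (μ₀, σ, K, H) from the 12 most
  recent observed months, then continue;
* **continuing change** — after the reset, re-estimate the reference from the
  preceding 12 months *every* month and re-alert each month the deviation
  beyond the allowance (relative to that rolling reference) keeps strictly
  growing; the first month it stalls, reset as in the standard method. An
  ongoing drift therefore produces a monthly stream of alerts — useful when
  subscribers join mid-drift — while a change that levels off goes quiet
  within a month or two.

## Worked example

```python
from peercusum import CusumParams, detect, detection_delay_closed_form

window = [6.0, 14.0] * 6          # 12 quiet months: mean 10, population SD 4
series = window + [22.0] * 10     # a sustained step of +12 percentile points

for a in detect(series, CusumParams(mode="standard")):
    print(a.month, a.direction, round(a.cusum_magnitude, 1),
          round(a.reference_mean, 1), round(a.reference_sd, 2))
print(detection_delay_closed_form(delta=12.0, k=2.0, h=20.0))
```

prints

```
13 increase 20.0 10.0 4.0
18 increase 35.6 12.0 5.77
2
```

The reference window gives μ₀ = 10, σ = 4, so K = 2 and H = 20. Each
post-step month adds 22 − 12 = 10 points to C⁺, so the alert lands in the
second post-step month (series index 13) — matching the closed form
⌈H/(Δ−K)⌉ = 2. The refreshed window still straddles the step, so one echo
alert follows at month 18 before the new level is absorbed.

The `examples/` directory has one short script per capability: percentiles
from raw counts, detection on a single series, an end-to-end population
transition, and alert-frequency summaries. Each prints the numbers it
computes and a line on what they mean.

## Command line

The same pipeline is scriptable from a shell:

```bash
peercusum simulate --out measures.csv --scenario fig1-like --seed 7
peercusum percentiles --input measures.csv --out percentiles.csv
peercusum detect --input percentiles.csv --out alerts.csv --mode continuing
peercusum summarize --alerts alerts.csv --roster roster.csv \
    --months 2010-01:2015-12 --out-dir summaries/
peercusum run-all --input measures.csv --out-dir out/   # all of the above
```

Measure CSVs carry `measure_id,entity_id,month,numerator,denominator` with
ISO `YYYY-MM` months; percentile CSVs carry `measure_id,entity_id,month,
percentile` with an empty field for missing. Exit code 2 signals a
validation error. `run-all` writes a manifest (config, versions, seed)
alongside its outputs so any run can be reproduced exactly.

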