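"""A population-wide change of practice, end to end.

Simulates 50 entities on one measure during a system-wide transition (every
entity ramps its ratio down at a staggered adoption time, like the move from
a branded drug to its generic). The focal entity E000 lags the pack and then
catches up abruptly; the detector sees its percentile climb (increase alerts)
and then crash (decrease alerts). Entity E001 moves with the population
median, so its rank barely changes and it normally stays silent.
"""

from peercusum import CusumParams, compute_percentiles, compute_ratios, detect
from peercusum.synthetic import fig1_like_scenario, generate

spec = fig1_like_scenario()
table = generate(spec)
percentiles = compute_percentiles(compute_ratios(table))

params = CusumParams(mode="continuing")
for entity, label in [("E000", "focal (lags, then catches up)"),
                      ("E001", "tracker (moves with the population)")]:
    alerts = detect(percentiles[entity], params, entity_id=entity)
    print(f"{entity} — {label}: {len(alerts)} alerts")
    for a in alerts:
        tag = "re-alert" if a.is_retrigger else "ALERT"
        print(f"  {a.month}  {a.direction:8s} {tag:8s} at percentile {a.percentile_at_trigger:5.1f}")
    print()

print(
    "The focal entity produces an increase episode while the population falls "
    "around it, then a decrease episode when it overshoots below its peers. "
    "The tracker's ratio changes just as much in absolute terms, but its peer "
    "rank does not, so no alert is appropriate — and (usually) none fires."
)
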