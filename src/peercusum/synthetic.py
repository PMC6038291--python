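"""Seeded synthetic measure populations.

Generates long-format numerator/denominator tables with the statistical
structure the detector assumes about real prescribing measures:

* many entities tracked monthly on a ratio measure;
* a shared population trend (e.g. a whole health system moving off a branded
  drug) plus optional shared sinusoidal seasonality — both cancel out of the
  percentile, which is the point of peer ranking;
* static entity offsets spreading the peer distribution;
* entity-level interventions (step or ramp changes to the target ratio);
* sampling noise that grows as prescribing volume shrinks: counts are drawn
  binomially at the target ratio and an extra disturbance scales with
  1/sqrt(volume), so small entities have erratic percentiles;
* occasional denominator-zero months (dropout), which downstream become
  missing percentiles.

Everything is deterministic under the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Intervention",
    "ScenarioSpec",
    "generate",
    "fig1_like_scenario",
    "step_recovery_scenario",
]


@dataclass(frozen=True)
class Intervention:
    """A change in one entity's underlying prescribing behaviour.

    ``kind="step"`` adds ``delta`` to the target ratio from ``start_month``
    on; ``kind="ramp"`` phases ``delta`` in linearly over ``duration`` months
    and then holds. ``delta`` is in ratio units and may be negative.
    """

    entity_id: str
    start_month: int
    kind: str  # "step" | "ramp"
    delta: float
    duration: int = 1

    def __post_init__(self) -> None:
        if self.kind not in ("step", "ramp"):
            raise ValueError("intervention kind must be 'step' or 'ramp'")
        if self.start_month < 0:
            raise ValueError("start_month must be non-negative")
        if self.duration < 1:
            raise ValueError("duration must be a positive integer")

    def effect(self, t: int) -> float:
        """Additive ratio effect at month index ``t``."""
        if t < self.start_month:
            return 0.0
        if self.kind == "step":
            return self.delta
        frac = min(1.0, (t - self.start_month + 1) / self.duration)
        return self.delta * frac


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic population.

    entity_spread
        Half-width of the uniform distribution of static entity offsets
        (ratio units). A uniform spread keeps the ratio-to-percentile map
        approximately linear away from the extremes: a ratio shift of d moves
        an entity by about 100 * d / (2 * entity_spread) percentile points.
    entity_noise_sd
        SD (ratio units) of the extra monthly disturbance at the mean
        prescribing volume; it is scaled by sqrt(mean_denominator / volume)
        so low-volume entities are noisier.
    dropout_prob
        Per entity-month probability of a zero denominator (a month with no
        qualifying prescribing), which yields a missing percentile downstream.
    entity_offsets
        Optional explicit offsets (one per entity, ratio units) overriding
        the uniform draw — useful for placing specific entities at known
        positions in the peer distribution.
    """

    n_entities: int = 100
    n_months: int = 48
    baseline_ratio: float = 0.5
    population_trend: float = 0.0
    seasonal_amplitude: float = 0.0
    entity_noise_sd: float = 0.01
    mean_denominator: int = 500
    entity_spread: float = 0.25
    dropout_prob: float = 0.0
    interventions: tuple[Intervention, ...] = ()
    seed: int = 0
    measure_id: str = "synthetic"
    start_month: str = "2010-01"
    entity_offsets: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_entities < 0 or self.n_months < 0:
            raise ValueError("n_entities and n_months must be non-negative")
        if not 0.0 <= self.baseline_ratio <= 1.0:
            raise ValueError("baseline_ratio must lie in [0, 1]")
        if not 0.0 <= self.seasonal_amplitude < 1.0:
            raise ValueError("seasonal_amplitude must lie in [0, 1)")
        if self.entity_noise_sd < 0 or self.entity_spread < 0:
            raise ValueError("entity_noise_sd and entity_spread must be non-negative")
        if self.mean_denominator <= 0:
            raise ValueError("mean_denominator must be positive")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout_prob must lie in [0, 1]")
        if self.entity_offsets is not None and len(self.entity_offsets) != self.n_entities:
            raise ValueError("entity_offsets must have one value per entity")
        object.__setattr__(self, "interventions", tuple(self.interventions))

    def entity_ids(self) -> list[str]:
        return [f"E{i:03d}" for i in range(self.n_entities)]


def generate(spec: ScenarioSpec) -> pd.DataFrame:
    """Realise a scenario as a long-format measure table.

    Per entity-month, a denominator volume is drawn Poisson around the
    entity's characteristic volume (lognormal around ``mean_denominator``,
    zeroed with probability ``dropout_prob``); the target ratio is

        clip(baseline + trend*t + seasonal(t) + offset + interventions(t)
             + noise(t) * sqrt(mean_denominator / volume), 0, 1)

    and the numerator is a binomial draw at that target, guaranteeing
    integer counts with numerator <= denominator. Identical specs (same
    seed) give bit-identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    ids = spec.entity_ids()
    months = pd.period_range(spec.start_month, periods=spec.n_months, freq="M")

    if spec.entity_offsets is not None:
        offsets = np.asarray(spec.entity_offsets, dtype=float)
    else:
        offsets = rng.uniform(-spec.entity_spread, spec.entity_spread, spec.n_entities)
    volume_factor = rng.lognormal(mean=0.0, sigma=0.4, size=spec.n_entities)

    by_entity: dict[str, list[Intervention]] = {e: [] for e in ids}
    for iv in spec.interventions:
        if iv.entity_id not in by_entity:
            raise ValueError(f"intervention references unknown entity {iv.entity_id!r}")
        by_entity[iv.entity_id].append(iv)

    t = np.arange(spec.n_months)
    shared = (
        spec.baseline_ratio
        + spec.population_trend * t
        + spec.seasonal_amplitude * np.sin(2 * np.pi * t / 12.0)
    )

    records = []
    for j, entity in enumerate(ids):
        lam = spec.mean_denominator * volume_factor[j]
        denom = rng.poisson(lam, size=spec.n_months)
        if spec.dropout_prob > 0:
            denom = np.where(rng.random(spec.n_months) < spec.dropout_prob, 0, denom)
        noise = rng.normal(0.0, spec.entity_noise_sd, size=spec.n_months)
        scale = np.sqrt(spec.mean_denominator / np.maximum(denom, 1))
        effect = np.array(
            [sum(iv.effect(ti) for iv in by_entity[entity]) for ti in t], dtype=float
        )
        target = np.clip(shared + offsets[j] + effect + noise * scale, 0.0, 1.0)
        numer = rng.binomial(denom, target)
        for m, nn, dd in zip(months, numer, denom):
            records.append((spec.measure_id, entity, m, int(nn), int(dd)))

    return pd.DataFrame.from_records(
        records, columns=["measure_id", "entity_id", "month", "numerator", "denominator"]
    )


def fig1_like_scenario(seed: int = 20160) -> ScenarioSpec:
    """A canned population-transition scenario for end-to-end demos.

    Emulates a measure during a system-wide change of practice (like the move
    from a branded drug to its generic): every entity eventually ramps its
    ratio down, but at staggered ("adoption") times. The focal entity
    ``E000`` lags the population — its ratio stays high while peers fall, so
    its percentile climbs and increase alerts fire — and then catches up
    abruptly, overshooting below the pack, so decrease alerts follow. Entity
    ``E001`` follows the population-median ratio path at zero offset, so its
    peer rank stays mid-pack; it alerts far less often than the focal entity
    (though not never: a 12-month window sometimes underestimates sigma and
    sets the decision interval too low, the method's known false-alarm mode).

    Calling with the same seed returns an identical (frozen) spec.
    """
    n_entities = 50
    n_months = 72
    drop = -0.45
    spread = 0.06
    # staggered adoption starts (months 10..33) and static offsets are drawn
    # once from the scenario seed; the tracker E001 is pinned at offset 0 so
    # that following the mean adoption path keeps its percentile mid-pack
    rng = np.random.default_rng(seed)
    starts = rng.integers(10, 34, size=n_entities)
    offsets = rng.uniform(-spread, spread, size=n_entities)
    offsets[1] = 0.0

    def ramp_effect(t: int, s: int, duration: int = 12) -> float:
        return drop * min(1.0, max(0.0, (t - s + 1) / duration))

    # the population-median ratio path (offsets + staggered ramps), which the
    # tracker reproduces via telescoping monthly steps so its rank stays ~50
    median_path = [
        float(np.median([offsets[i] + ramp_effect(t, int(starts[i]))
                         for i in range(n_entities) if i not in (0, 1)]))
        for t in range(n_months)
    ]
    interventions = []
    for i in range(n_entities):
        if i == 0:
            # focal: lags the pack, then converts fast and overshoots
            interventions.append(
                Intervention("E000", start_month=48, kind="ramp", delta=drop - 0.12, duration=4)
            )
        elif i == 1:
            prev = median_path[0]
            for t in range(1, n_months):
                d = median_path[t] - prev
                if d != 0.0:
                    interventions.append(
                        Intervention("E001", start_month=t, kind="step", delta=d)
                    )
                prev = median_path[t]
        else:
            interventions.append(
                Intervention(
                    f"E{i:03d}",
                    start_month=int(starts[i]),
                    kind="ramp",
                    delta=drop,
                    duration=12,
                )
            )
    return ScenarioSpec(
        n_entities=n_entities,
        n_months=n_months,
        baseline_ratio=0.62,
        population_trend=0.0,
        seasonal_amplitude=0.0,
        entity_noise_sd=0.012,
        mean_denominator=800,
        entity_spread=spread,
        entity_offsets=tuple(float(o) for o in offsets),
        dropout_prob=0.0,
        interventions=tuple(interventions),
        seed=seed,
        measure_id="population-transition",
    )


def step_recovery_scenario(seed: int = 42) -> tuple[ScenarioSpec, list[str], int]:
    """A 100-entity population with 5 abrupt step-change entities.

    Five entities placed at known mid-range offsets step their target ratio
    up by 0.125 at month 24; with uniform peer offsets of half-width 0.25
    that maps to roughly +25 percentile points. Returns
    ``(spec, step_entity_ids, step_month_index)`` — the ids and step month
    let callers check detection timing and measure the alert rate among the
    95 unchanged entities.
    """
    n_entities, n_months, step_month = 100, 48, 24
    rng = np.random.default_rng(seed)
    offsets = rng.uniform(-0.25, 0.25, n_entities)
    step_slots = (10, 30, 50, 70, 90)
    for slot, off in zip(step_slots, (-0.10, -0.05, 0.0, 0.05, 0.10)):
        offsets[slot] = off  # mid-range, so the +0.125 step cannot clip
    step_ids = [f"E{i:03d}" for i in step_slots]
    spec = ScenarioSpec(
        n_entities=n_entities,
        n_months=n_months,
        baseline_ratio=0.5,
        entity_noise_sd=0.01,
        mean_denominator=500,
        entity_spread=0.25,
        entity_offsets=tuple(float(o) for o in offsets),
        interventions=tuple(
            Intervention(e, step_month, "step", 0.125) for e in step_ids
        ),
        seed=seed,
        measure_id="step-recovery",
    )
    return spec, step_ids, step_month
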