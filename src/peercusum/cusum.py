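"""Two-sided CUSUM change detection on a peer-percentile series.

The detector watches one entity's monthly percentile x_i among its peers and
accumulates deviations from a reference mean mu0 estimated over a trailing
window (12 months by default):

    C+_i = max(0, x_i - (mu0 + K) + C+_{i-1})
    C-_i = min(0, x_i - (mu0 - K) + C-_{i-1})

K (the allowance) is 0.5 sigma and the decision interval H is 5 sigma, where
sigma is the population standard deviation of the reference window; because K
and H scale with sigma, noisy series demand larger sustained shifts while very
stable series alert on small ones. When C+ >= H an *increase* alert fires;
when |C-| >= H a *decrease* alert fires.

Two post-trigger behaviours are provided:

* **standard** — reset both accumulators to zero and refresh (mu0, sigma, K, H)
  from the most recent window (including the trigger month), then carry on.
* **continuing** — after the refresh, keep re-estimating the reference from
  the preceding window each month; since the reference is re-reset monthly,
  C restarts from zero against it, so C is the current deviation beyond the
  allowance. Re-alert each month this deviation strictly grows; the first
  month it stalls, reset as in the standard method. This makes an
  accelerating drift produce a monthly stream of alerts instead of a single
  one, while a drift that levels off stops alerting within a month or two.

Missing months (no percentile, typically a zero denominator) are dropped
before the algorithm runs; an entity with fewer than ``min_observations``
non-missing months produces no alerts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CusumParams",
    "DetectorState",
    "AlertEvent",
    "reference_stats",
    "cusum_update",
    "detect",
    "detection_delay_closed_form",
]

logger = logging.getLogger(__name__)

MODES = ("standard", "continuing")


@dataclass(frozen=True)
class CusumParams:
    """Tuning knobs for the detector.

    window_months
        Length of the reference window over which mu0 and sigma are
        estimated (months of non-missing data).
    k_multiplier, h_multiplier
        Allowance K = k_multiplier * sigma and decision interval
        H = h_multiplier * sigma.
    mode
        ``"standard"`` or ``"continuing"`` (see module docstring).
    min_observations
        Minimum number of non-missing months required to run at all;
        defaults to ``window_months + 1`` (a full window plus one month to
        score).
    sigma_floor
        Lower bound applied to the estimated sigma. The default 0 preserves
        the property that a perfectly flat window alerts on any deviation;
        raise it to damp alerts on ultra-stable series.
    """

    window_months: int = 12
    k_multiplier: float = 0.5
    h_multiplier: float = 5.0
    mode: str = "standard"
    min_observations: int | None = None
    sigma_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.window_months < 1:
            raise ValueError("window_months must be a positive integer")
        if self.k_multiplier < 0:
            raise ValueError("k_multiplier must be non-negative")
        if self.h_multiplier <= self.k_multiplier:
            raise ValueError("h_multiplier must exceed k_multiplier")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.sigma_floor < 0:
            raise ValueError("sigma_floor must be non-negative")
        if self.min_observations is None:
            object.__setattr__(self, "min_observations", self.window_months + 1)
        if self.min_observations < self.window_months + 1:
            raise ValueError("min_observations must be at least window_months + 1")


@dataclass
class DetectorState:
    """Mutable state of a running detector (mainly for introspection)."""

    mu0: float
    sigma: float
    k: float
    h: float
    c_pos: float = 0.0
    c_neg: float = 0.0
    mode_flag: str = "normal"  # normal | continuing_increase | continuing_decrease
    window_buffer: list[float] = field(default_factory=list)


@dataclass(frozen=True)
class AlertEvent:
    """One dated, directional trigger.

    ``cusum_magnitude`` is |C| of the triggering accumulator at the trigger;
    for an initial trigger it is at least the H then in force.
    ``reference_mean``/``reference_sd`` are the mu0/sigma against which the
    triggering deviation was accumulated. ``is_retrigger`` marks the monthly
    re-alerts of the continuing method after the initial trigger of a run.
    """

    month: Hashable
    direction: str  # "increase" | "decrease"
    percentile_at_trigger: float
    cusum_magnitude: float
    reference_mean: float
    reference_sd: float
    is_retrigger: bool = False


def reference_stats(
    values: Sequence[float], window_months: int = 12, sigma_floor: float = 0.0
) -> tuple[float, float]:
    """Mean and population SD of one full reference window.

    Exactly ``window_months`` non-missing values are required; sigma is
    floored at ``sigma_floor``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size != window_months:
        raise ValueError(
            f"reference window must hold exactly {window_months} values, got {arr.size}"
        )
    if np.isnan(arr).any():
        raise ValueError("reference window must not contain missing values")
    mu0 = float(arr.mean())
    sigma = max(float(arr.std(ddof=0)), float(sigma_floor))
    return mu0, sigma


def cusum_update(
    c_pos: float, c_neg: float, x: float, mu0: float, k: float
) -> tuple[float, float]:
    """One step of the two-sided recursion; returns the new (C+, C-)."""
    new_pos = max(0.0, x - (mu0 + k) + c_pos)
    new_neg = min(0.0, x - (mu0 - k) + c_neg)
    return new_pos, new_neg


def detection_delay_closed_form(delta: float, k: float, h: float) -> int:
    """Months to first alert for a clean constant step on a noiseless baseline.

    A step of ``delta`` percentile points above mu0 adds ``delta - k`` to C+
    each month starting from 0, so the threshold ``h`` is reached after
    ``ceil(h / (delta - k))`` months. Requires ``delta > k`` (otherwise the
    accumulator never grows) and ``h > 0``.
    """
    if h <= 0:
        raise ValueError("h must be positive")
    if delta <= k:
        raise ValueError("delta must exceed the allowance k for guaranteed detection")
    return math.ceil(h / (delta - k))


def _trigger_direction(c_pos: float, c_neg: float, h: float) -> str | None:
    """Which side trips, if any. Larger |C| wins a double crossing; an exact
    tie is called an increase (the pathological case)."""
    # the `> 0` guard matters only when sigma (hence h) is 0: a flat window
    # should alert on any nonzero deviation, not on no deviation at all
    pos_hit = c_pos >= h and c_pos > 0
    neg_hit = -c_neg >= h and -c_neg > 0
    if pos_hit and neg_hit:
        return "increase" if c_pos >= -c_neg else "decrease"
    if pos_hit:
        return "increase"
    if neg_hit:
        return "decrease"
    return None


def detect(
    series: "pd.Series | Sequence[float]",
    params: CusumParams | None = None,
    entity_id: str | None = None,
) -> list[AlertEvent]:
    """Run the detector over one entity's percentile series.

    ``series`` is a pandas Series indexed by month (missing months as NaN) or
    a plain sequence (indexed 0..n-1). Observations must lie in [0, 100].
    Returns the chronologically ordered alerts; an entity with fewer than
    ``params.min_observations`` non-missing months returns an empty list
    (logged, not an error: such entities simply cannot be scored).
    """
    params = params or CusumParams()
    if not isinstance(series, pd.Series):
        series = pd.Series(np.asarray(series, dtype=float))
    obs = series.dropna()
    values = obs.to_numpy(dtype=float)
    months = list(obs.index)

    if ((values < 0) | (values > 100)).any():
        bad = values[(values < 0) | (values > 100)][0]
        raise ValueError(f"percentile {bad} outside [0, 100]")
    if len(values) < params.min_observations:
        logger.info(
            "insufficient data for %s: %d non-missing months < %d required; "
            "no alerts triggered",
            entity_id or "series",
            len(values),
            params.min_observations,
        )
        return []

    w = params.window_months
    mu0, sigma = reference_stats(values[:w], w, params.sigma_floor)
    state = DetectorState(
        mu0=mu0,
        sigma=sigma,
        k=params.k_multiplier * sigma,
        h=params.h_multiplier * sigma,
        window_buffer=list(values[:w]),
    )
    prev_run_magnitude = 0.0
    alerts: list[AlertEvent] = []

    def refresh(upto: int) -> None:
        """Re-estimate the reference from the window ending at index `upto`."""
        state.window_buffer = list(values[upto - w + 1 : upto + 1])
        state.mu0, state.sigma = reference_stats(
            state.window_buffer, w, params.sigma_floor
        )
        state.k = params.k_multiplier * state.sigma
        state.h = params.h_multiplier * state.sigma

    for i in range(w, len(values)):
        x = values[i]
        if state.mode_flag == "normal":
            state.c_pos, state.c_neg = cusum_update(
                state.c_pos, state.c_neg, x, state.mu0, state.k
            )
            direction = _trigger_direction(state.c_pos, state.c_neg, state.h)
            if direction is None:
                continue
            magnitude = state.c_pos if direction == "increase" else -state.c_neg
            alerts.append(
                AlertEvent(
                    month=months[i],
                    direction=direction,
                    percentile_at_trigger=x,
                    cusum_magnitude=magnitude,
                    reference_mean=state.mu0,
                    reference_sd=state.sigma,
                )
            )
            refresh(i)
            state.c_pos = state.c_neg = 0.0
            if params.mode == "continuing":
                state.mode_flag = f"continuing_{direction}"
                prev_run_magnitude = 0.0
        else:
            # Continuing run: the reference rolls over the window preceding
            # this month (on the first post-trigger month this is exactly the
            # window refreshed at the trigger, which included the trigger
            # month). Because the reference is re-reset every month, the
            # accumulation restarts from 0 against it: C is the current
            # month's deviation beyond the allowance, and the run persists
            # only while that deviation keeps strictly growing — so a drift
            # that stalls exits promptly.
            running_direction = state.mode_flag.removeprefix("continuing_")
            state.window_buffer = list(values[i - w : i])
            state.mu0, state.sigma = reference_stats(
                state.window_buffer, w, params.sigma_floor
            )
            state.k = params.k_multiplier * state.sigma
            state.h = params.h_multiplier * state.sigma
            state.c_pos, state.c_neg = cusum_update(
                0.0, 0.0, x, state.mu0, state.k
            )
            magnitude = (
                state.c_pos if running_direction == "increase" else -state.c_neg
            )
            if magnitude > prev_run_magnitude:
                alerts.append(
                    AlertEvent(
                        month=months[i],
                        direction=running_direction,
                        percentile_at_trigger=x,
                        cusum_magnitude=magnitude,
                        reference_mean=state.mu0,
                        reference_sd=state.sigma,
                        is_retrigger=True,
                    )
                )
                prev_run_magnitude = magnitude
            else:
                # drift stalled: reset as per the standard method
                state.c_pos = state.c_neg = 0.0
                refresh(i)
                state.mode_flag = "normal"
                prev_run_magnitude = 0.0
    return alerts


def detect_panel(
    percentile_panel: pd.DataFrame,
    params: CusumParams | None = None,
    measure_id: str = "measure",
) -> pd.DataFrame:
    """Run :func:`detect` on every entity column of a percentile panel.

    Returns a long DataFrame of alerts with columns
    ``measure_id, entity_id, month, direction, percentile, cusum_magnitude,
    reference_mean, reference_sd, is_retrigger`` (empty but well-formed when
    nothing triggers).
    """
    params = params or CusumParams()
    records = []
    for entity in percentile_panel.columns:
        for ev in detect(percentile_panel[entity], params, entity_id=str(entity)):
            records.append(
                {
                    "measure_id": measure_id,
                    "entity_id": entity,
                    "month": ev.month,
                    "direction": ev.direction,
                    "percentile": ev.percentile_at_trigger,
                    "cusum_magnitude": ev.cusum_magnitude,
                    "reference_mean": ev.reference_mean,
                    "reference_sd": ev.reference_sd,
                    "is_retrigger": ev.is_retrigger,
                }
            )
    columns = [
        "measure_id",
        "entity_id",
        "month",
        "direction",
        "percentile",
        "cusum_magnitude",
        "reference_mean",
        "reference_sd",
        "is_retrigger",
    ]
    return pd.DataFrame.from_records(records, columns=columns)


__all__.append("detect_panel")
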