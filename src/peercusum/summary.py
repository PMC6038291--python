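"""Alert-frequency summaries.

Aggregates alert events into the reporting surfaces used to judge whether the
alerting level is appropriate: the percentage of entities receiving increase
and decrease alerts per measure per month (a "percentage of institutions
receiving alerts" table), per-entity monthly alert counts (histogram input),
and overall mean alerts per entity per month.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = ["AlertSummary", "summarize"]


@dataclass(frozen=True)
class AlertSummary:
    """Aggregate view of a set of alert events over a roster and month range.

    per_measure_month
        One row per (measure_id, month): ``pct_entities_with_increase`` /
        ``pct_entities_with_decrease`` — the percentage of roster entities
        with at least one alert of that direction in that month.
    per_entity_month
        One row per (entity_id, month) over the full roster x month grid:
        ``n_increase`` / ``n_decrease`` event counts (zeros included, so the
        frame is directly histogram-ready).
    mean_increase_per_entity_month, mean_decrease_per_entity_month
        Total events of each direction divided by (roster size x number of
        months considered), pooled across measures.
    """

    per_measure_month: pd.DataFrame
    per_entity_month: pd.DataFrame
    mean_increase_per_entity_month: float
    mean_decrease_per_entity_month: float


def summarize(
    alerts: pd.DataFrame,
    roster: Sequence[str],
    months: Iterable,
) -> AlertSummary:
    """Summarise alert events against an entity roster and month range.

    ``alerts`` is the long alert frame produced by
    :func:`peercusum.cusum.detect_panel` (retriggers count as events, since
    the continuing method deliberately emits them monthly). Entities with no
    alerts still count in every denominator. Alerts referencing entities
    outside the roster are an error; alerts dated outside ``months`` are
    ignored.
    """
    roster = list(dict.fromkeys(roster))
    if not roster:
        raise ValueError("roster must be non-empty")
    months = list(months)
    if not months:
        raise ValueError("months must be non-empty")

    if len(alerts):
        unknown = set(alerts["entity_id"]) - set(roster)
        if unknown:
            raise ValueError(f"alerts reference entities not on the roster: {sorted(unknown)}")
        alerts = alerts[alerts["month"].isin(months)]

    n_entities = len(roster)
    n_months = len(months)
    measures = sorted(alerts["measure_id"].unique()) if len(alerts) else []

    # per (measure, month): % of entities with >=1 alert of each direction
    pm_rows = []
    for measure in measures or ["measure"]:
        sub = alerts[alerts["measure_id"] == measure] if len(alerts) else alerts
        for month in months:
            in_month = sub[sub["month"] == month] if len(sub) else sub
            row = {"measure_id": measure, "month": month}
            for direction in ("increase", "decrease"):
                if len(in_month):
                    hit = in_month.loc[in_month["direction"] == direction, "entity_id"].nunique()
                else:
                    hit = 0
                row[f"pct_entities_with_{direction}"] = 100.0 * hit / n_entities
            pm_rows.append(row)
    per_measure_month = pd.DataFrame(pm_rows)

    # per (entity, month) event counts on the full grid, zeros included
    grid = pd.MultiIndex.from_product([roster, months], names=["entity_id", "month"])
    per_entity_month = pd.DataFrame(0, index=grid, columns=["n_increase", "n_decrease"])
    if len(alerts):
        counts = (
            alerts.groupby(["entity_id", "month", "direction"], observed=True)
            .size()
            .unstack("direction", fill_value=0)
        )
        for direction in ("increase", "decrease"):
            if direction in counts.columns:
                col = counts[direction]
                per_entity_month.loc[col.index, f"n_{direction}"] = col.to_numpy()
    per_entity_month = per_entity_month.reset_index()

    total_inc = int(per_entity_month["n_increase"].sum())
    total_dec = int(per_entity_month["n_decrease"].sum())
    denom = n_entities * n_months
    return AlertSummary(
        per_measure_month=per_measure_month,
        per_entity_month=per_entity_month,
        mean_increase_per_entity_month=total_inc / denom,
        mean_decrease_per_entity_month=total_dec / denom,
    )
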