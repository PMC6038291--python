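"""Ratio measures and peer-percentile ranking.

A *measure* is a ratio indicator: a numerator count of prescribing events over
a denominator count of related events, computed per entity (practice, CCG, ...)
per calendar month. Because the numerator set is a subset of the denominator
set, the ratio lives in [0, 1]; months with a zero denominator carry no
information and become missing.

Each month, every entity is placed on a 0-100 percentile scale among the peers
reporting that month. The percentile trajectory of one entity is the
observation stream consumed by :mod:`peercusum.cusum`.

In-memory conventions
---------------------
* A **measure table** is a long-format :class:`pandas.DataFrame` with columns
  ``entity_id``, ``month``, ``numerator``, ``denominator`` (and optionally
  ``measure_id``); ``month`` is a :class:`pandas.Period` with monthly
  frequency, or an ISO ``YYYY-MM`` string coercible to one.
* A **panel** (ratio or percentile) is a wide DataFrame indexed by a monthly
  :class:`pandas.PeriodIndex` with one column per entity; ``NaN`` marks a
  missing month.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "MeasureValidationError",
    "validate_measure_table",
    "compute_ratios",
    "percentile_rank",
    "compute_percentiles",
]


class MeasureValidationError(ValueError):
    """A measure table or ratio panel violates its contract."""


_REQUIRED_COLUMNS = ("entity_id", "month", "numerator", "denominator")


def _coerce_months(months: pd.Series) -> pd.PeriodIndex:
    try:
        return pd.PeriodIndex(months, freq="M")
    except Exception as exc:  # noqa: BLE001 - surface as validation error
        raise MeasureValidationError(
            f"months must be ISO YYYY-MM (or monthly Periods): {exc}"
        ) from exc


def validate_measure_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format measure table and normalise its dtypes.

    Returns a copy with ``month`` as a monthly Period column, sorted by
    (entity, month). Raises :class:`MeasureValidationError` on missing
    columns, negative counts, or duplicate (entity, month) rows.
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise MeasureValidationError(f"measure table missing columns: {missing}")

    out = table.copy()
    out["month"] = _coerce_months(out["month"])
    for col in ("numerator", "denominator"):
        values = pd.to_numeric(out[col], errors="coerce")
        if values.isna().any():
            bad = out.index[values.isna()][0]
            raise MeasureValidationError(f"non-numeric {col} at row {bad}")
        if (values < 0).any():
            bad = out.index[values < 0][0]
            raise MeasureValidationError(f"negative {col} at row {bad}")
        out[col] = values

    dup = out.duplicated(subset=["entity_id", "month"])
    if dup.any():
        first = out.loc[dup, ["entity_id", "month"]].iloc[0]
        raise MeasureValidationError(
            f"duplicate row for entity {first['entity_id']!r} in {first['month']}"
        )
    return out.sort_values(["entity_id", "month"]).reset_index(drop=True)


def compute_ratios(table: pd.DataFrame, check_subset: bool = True) -> pd.DataFrame:
    """Turn a measure table into a wide ratio panel.

    The ratio is numerator/denominator where the denominator is positive and
    ``NaN`` where the denominator is zero or the (entity, month) row is
    absent. With ``check_subset`` (the default) a ratio above 1 is rejected:
    real measures define the numerator drugs as a subset of the denominator
    drugs, so a ratio above 1 signals a data error.
    """
    table = validate_measure_table(table)
    ratio = np.where(
        table["denominator"] > 0,
        table["numerator"] / table["denominator"].where(table["denominator"] > 0),
        np.nan,
    )
    if check_subset:
        over = ratio > 1
        if over.any():
            row = table.loc[np.flatnonzero(over)[0]]
            raise MeasureValidationError(
                "numerator exceeds denominator for entity "
                f"{row['entity_id']!r} in {row['month']} "
                f"({row['numerator']:g}/{row['denominator']:g}); "
                "the numerator must be a subset of the denominator "
                "(pass check_subset=False to allow)"
            )
    panel = (
        table.assign(ratio=ratio)
        .pivot(index="month", columns="entity_id", values="ratio")
        .sort_index()
    )
    # contiguous monthly axis: absent months become all-missing rows
    if len(panel):
        panel = panel.reindex(
            pd.period_range(panel.index[0], panel.index[-1], freq="M")
        )
        panel.index.name = "month"
    return panel


def percentile_rank(ratios: "pd.Series | Mapping[str, float]") -> pd.Series:
    """Rank one month's entities on a 0-100 percentile scale.

    Entities with a missing ratio keep a missing percentile. Among the ``n``
    reporting entities, an entity at average rank ``r`` (ties share the mean
    rank) is assigned ``100 * (r - 1) / (n - 1)``, so the unique minimum sits
    at 0 and the unique maximum at 100. A lone reporting entity is placed at
    the neutral 50.
    """
    s = pd.Series(ratios, dtype=float)
    if s.empty:
        raise MeasureValidationError("percentile_rank requires at least one entity")
    mask = s.notna()
    n = int(mask.sum())
    out = pd.Series(np.nan, index=s.index, name="percentile")
    if n == 0:
        raise MeasureValidationError("percentile_rank requires a non-missing ratio")
    if n == 1:
        out[mask] = 50.0
        return out
    ranks = rankdata(s[mask].to_numpy(), method="average")
    out[mask] = 100.0 * (ranks - 1.0) / (n - 1.0)
    return out


def compute_percentiles(ratio_panel: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`percentile_rank` month by month to a ratio panel.

    Months in which no entity reports stay all-missing (they contribute no
    peer comparison).
    """
    rows = {}
    for month, row in ratio_panel.iterrows():
        if row.notna().any():
            rows[month] = percentile_rank(row)
        else:
            rows[month] = pd.Series(np.nan, index=ratio_panel.columns)
    panel = pd.DataFrame.from_dict(rows, orient="index")
    panel.index = ratio_panel.index
    panel.index.name = "month"
    panel.columns.name = "entity_id"
    return panel
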