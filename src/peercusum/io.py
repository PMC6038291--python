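"""CSV readers/writers, configuration, and the end-to-end pipeline.

All core I/O is file-based: measure tables and percentile panels travel as
long-format CSV with ISO ``YYYY-MM`` months, entities as opaque strings (NHS
codes such as ``05D`` pass through untouched), and an empty percentile field
meaning missing. A pipeline run writes a manifest (config echo, package
version, seed) next to its outputs so any run can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cusum import CusumParams, detect_panel
from .measures import (
    MeasureValidationError,
    compute_percentiles,
    compute_ratios,
    validate_measure_table,
)
from .summary import summarize

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_measure_table",
    "read_percentile_panel",
    "write_percentile_panel",
    "write_alerts",
    "read_alerts",
    "load_params",
    "run_pipeline",
]

ALERT_COLUMNS = [
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


def read_measure_table(path: "str | Path") -> pd.DataFrame:
    """Read and validate a measure-table CSV.

    Expected columns: ``measure_id,entity_id,month,numerator,denominator``
    (``measure_id`` optional). Malformed rows raise with the offending row
    named.
    """
    df = pd.read_csv(path, dtype={"entity_id": str, "measure_id": str})
    return validate_measure_table(df)


def write_percentile_panel(
    panel: pd.DataFrame, path: "str | Path", measure_id: str = "measure"
) -> None:
    """Write a wide percentile panel as long CSV (empty field = missing)."""
    long = panel.stack(future_stack=True).rename("percentile").reset_index()
    long.columns = ["month", "entity_id", "percentile"]
    long.insert(0, "measure_id", measure_id)
    long["month"] = long["month"].astype(str)
    long.to_csv(path, index=False)


def read_percentile_panel(path: "str | Path") -> pd.DataFrame:
    """Read a long percentile CSV back into a wide panel (months x entities)."""
    df = pd.read_csv(path, dtype={"entity_id": str})
    required = {"entity_id", "month", "percentile"}
    missing = required - set(df.columns)
    if missing:
        raise MeasureValidationError(f"percentile CSV missing columns: {sorted(missing)}")
    df["month"] = pd.PeriodIndex(df["month"], freq="M")
    panel = df.pivot(index="month", columns="entity_id", values="percentile").sort_index()
    return panel


def write_alerts(alerts: pd.DataFrame, path: "str | Path") -> None:
    out = alerts.copy()
    out["month"] = out["month"].astype(str)
    out.to_csv(path, index=False, columns=ALERT_COLUMNS)


def read_alerts(path: "str | Path") -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"entity_id": str, "measure_id": str})
    df["month"] = pd.PeriodIndex(df["month"], freq="M")
    return df


def load_params(path: "str | Path") -> CusumParams:
    """Load detector parameters from a YAML (or JSON) config file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    allowed = {f.name for f in dataclasses.fields(CusumParams)}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return CusumParams(**raw)


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs: inputs, outputs, and parameters."""

    input_measures: Path
    output_dir: Path
    params: CusumParams = CusumParams()
    seed: int | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        object.__setattr__(self, "input_measures", Path(self.input_measures))
        object.__setattr__(self, "output_dir", Path(self.output_dir))
        if not self.input_measures.exists():
            raise FileNotFoundError(self.input_measures)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """measures CSV -> percentiles -> alerts -> summaries, plus a manifest.

    Entities with insufficient data are logged and skipped (they still count
    in summary denominators). Outputs are deterministic given identical
    inputs and config. Returns the paths written.
    """
    logging.basicConfig(level=config.log_level)
    config.output_dir.mkdir(parents=True, exist_ok=True)

    table = read_measure_table(config.input_measures)
    measure_id = (
        str(table["measure_id"].iloc[0]) if "measure_id" in table.columns and len(table) else "measure"
    )
    ratios = compute_ratios(table)
    percentiles = compute_percentiles(ratios)
    alerts = detect_panel(percentiles, config.params, measure_id=measure_id)

    roster = list(percentiles.columns)
    months = list(percentiles.index)
    summary = summarize(alerts, roster, months)

    paths = {
        "percentiles": config.output_dir / "percentiles.csv",
        "alerts": config.output_dir / "alerts.csv",
        "summary_measure": config.output_dir / "summary_by_measure_month.csv",
        "summary_entity": config.output_dir / "alert_counts_by_entity_month.csv",
        "manifest": config.output_dir / "manifest.json",
    }
    write_percentile_panel(percentiles, paths["percentiles"], measure_id)
    write_alerts(alerts, paths["alerts"])
    pm = summary.per_measure_month.copy()
    pm["month"] = pm["month"].astype(str)
    pm.to_csv(paths["summary_measure"], index=False)
    pe = summary.per_entity_month.copy()
    pe["month"] = pe["month"].astype(str)
    pe.to_csv(paths["summary_entity"], index=False)

    manifest = {
        "peercusum_version": __version__,
        "input_measures": str(config.input_measures),
        "params": dataclasses.asdict(config.params),
        "seed": config.seed,
        "n_entities": len(roster),
        "n_months": len(months),
        "n_alerts": int(len(alerts)),
        "mean_increase_per_entity_month": summary.mean_increase_per_entity_month,
        "mean_decrease_per_entity_month": summary.mean_decrease_per_entity_month,
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2) + "\n")
    return paths
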