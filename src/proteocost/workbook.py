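"""Workbook and configuration I/O, and report-layer tables.

The workbook is a plain CSV with one row per resource item; the model
configuration is a YAML (or JSON) mapping mirroring :class:`ModelConfig`.
All whole-dollar / whole-percent rounding happens here, never in the model.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from .model import (
    STAGE_LABELS,
    STAGES,
    BatchConfig,
    Category,
    CostBreakdown,
    ModelConfig,
    ResourceItem,
    ThroughputConfig,
    category_shares,
    round_half_up,
)

__all__ = [
    "WORKBOOK_COLUMNS",
    "read_workbook",
    "write_workbook",
    "read_config",
    "write_config",
    "config_from_dict",
    "config_to_dict",
    "breakdown_table",
    "summary_dict",
]

WORKBOOK_COLUMNS = [
    "name", "stage", "category", "basis", "quantity", "unit", "unit_cost",
    "min", "max", "flags", "lifetime", "annual_maintenance",
    "sharing_fraction", "reanalysis_fraction",
]


def _item_to_row(item: ResourceItem) -> dict[str, Any]:
    lo, hi = item.uncertainty if item.uncertainty is not None else ("", "")
    return {
        "name": item.name,
        "stage": item.stage,
        "category": item.category.value,
        "basis": item.basis.value,
        "quantity": item.quantity,
        "unit": item.unit,
        "unit_cost": item.unit_cost,
        "min": lo,
        "max": hi,
        "flags": "|".join(sorted(item.flags)),
        "lifetime": item.lifetime if item.lifetime is not None else "",
        "annual_maintenance": item.annual_maintenance,
        "sharing_fraction": item.sharing_fraction,
        "reanalysis_fraction": item.reanalysis_fraction,
    }


def write_workbook(items: Sequence[ResourceItem], path: str | Path) -> None:
    frame = pd.DataFrame([_item_to_row(i) for i in items], columns=WORKBOOK_COLUMNS)
    frame.to_csv(path, index=False)


def _opt_float(value: Any) -> float | None:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    return float(value)


def read_workbook(path: str | Path) -> list[ResourceItem]:
    """Read a workbook CSV; parse errors carry the offending line number."""
    frame = pd.read_csv(path, dtype={"flags": str, "unit": str},
                        keep_default_na=True, float_precision="round_trip")
    missing = [c for c in WORKBOOK_COLUMNS[:7] if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing workbook columns: {', '.join(missing)}")
    items: list[ResourceItem] = []
    for pos, row in frame.iterrows():
        line = pos + 2  # header is line 1
        try:
            lo = _opt_float(row.get("min"))
            hi = _opt_float(row.get("max"))
            if (lo is None) != (hi is None):
                raise ValueError("min/max must be given together")
            flags = row.get("flags")
            item = ResourceItem(
                name=str(row["name"]),
                stage=str(row["stage"]),
                category=str(row["category"]),
                basis=str(row["basis"]),
                quantity=float(row["quantity"]),
                unit="" if pd.isna(row.get("unit")) else str(row.get("unit")),
                unit_cost=float(row["unit_cost"]),
                uncertainty=None if lo is None else (lo, hi),
                flags="" if pd.isna(flags) else str(flags),
                lifetime=_opt_float(row.get("lifetime")),
                annual_maintenance=_opt_float(row.get("annual_maintenance")) or 0.0,
                sharing_fraction=_opt_float(row.get("sharing_fraction")) or 1.0,
                reanalysis_fraction=_opt_float(row.get("reanalysis_fraction")) or 1.0,
            )
            item.validate()
        except (ValueError, KeyError) as exc:
            raise ValueError(f"{path}, line {line}: {exc}") from exc
        items.append(item)
    return items


def config_to_dict(config: ModelConfig) -> dict[str, Any]:
    return dataclasses.asdict(config)


def config_from_dict(data: dict[str, Any] | None) -> ModelConfig:
    """Build a configuration from a (possibly partial) mapping; missing
    fields take the base-case defaults."""
    data = dict(data or {})
    batch = BatchConfig(**data.pop("batch", {}))
    throughput = ThroughputConfig(**data.pop("throughput", {}))
    unknown = set(data) - {f.name for f in dataclasses.fields(ModelConfig)}
    if unknown:
        raise ValueError(f"unknown config fields: {', '.join(sorted(unknown))}")
    config = ModelConfig(batch=batch, throughput=throughput, **data)
    config.validate()
    return config


def read_config(path: str | Path) -> ModelConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data)


def write_config(config: ModelConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def breakdown_table(
    breakdown: CostBreakdown,
    currency: str = "aud",
    display_rate: float = 0.6682,
) -> pd.DataFrame:
    """Publication-style stage x category table with totals and shares.

    Values are rounded half-up to whole dollars (percent to whole percent);
    ``currency="usd"`` converts displayed values with the fixed display rate
    while the underlying model stays in AUD.
    """
    if currency not in ("aud", "usd"):
        raise ValueError("currency must be 'aud' or 'usd'")
    fx = display_rate if currency == "usd" else 1.0
    cats = [c.value for c in Category]
    rows = []
    for stage in STAGES:
        row = {"stage": STAGE_LABELS[stage]}
        for c in cats:
            row[c] = round_half_up(float(breakdown.matrix.loc[stage, c]) * fx)
        row["total"] = round_half_up(float(breakdown.stage_totals[stage]) * fx)
        rows.append(row)
    totals = {"stage": "Total cost excluding overheads"}
    for c in cats:
        totals[c] = round_half_up(float(breakdown.category_totals[c]) * fx)
    totals["total"] = round_half_up(breakdown.pre_overhead_total * fx)
    rows.append(totals)
    shares = category_shares(breakdown)
    rows.append({
        "stage": "Proportion of total cost",
        **{c: f"{round_half_up(shares[c] * 100):.0f}%" for c in cats},
        "total": "",
    })
    rows.append({
        "stage": f"Total cost including {breakdown.overhead_rate:.0%} overheads",
        **{c: "" for c in cats},
        "total": round_half_up(breakdown.post_overhead_total * fx),
    })
    return pd.DataFrame(rows, columns=["stage", *cats, "total"])


def summary_dict(breakdown: CostBreakdown, currency_display_rate: float = 0.6682) -> dict:
    """Machine-readable summary (full precision, canonical AUD)."""
    shares = category_shares(breakdown)
    return {
        "currency": "AUD",
        "per_stage": {s: float(breakdown.stage_totals[s]) for s in STAGES},
        "per_category": {c: float(breakdown.category_totals[c])
                         for c in breakdown.category_totals.index},
        "category_shares": shares,
        "pre_overhead_total": breakdown.pre_overhead_total,
        "overhead_rate": breakdown.overhead_rate,
        "post_overhead_total": breakdown.post_overhead_total,
        "post_overhead_total_usd_display": breakdown.post_overhead_total
        * currency_display_rate,
    }
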