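"""Deterministic sensitivity analyses.

One-way analyses rebuild the model with exactly one change — either a global
parameter (overhead rate, utilization, discount rate, annual throughput) or a
multiplicative change to a filtered subset of workbook items — and report the
recomputed post-overhead total and its percent change against the base case.
Two-way analyses take the cross-product of two variation axes.  The
throughput scenario sweep exploits the model's structure: per-patient totals
are exactly linear in 1/T because only ``annual_fixed`` allocations re-divide
when the annual volume T changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, is_dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import (
    Basis,
    Category,
    CostBreakdown,
    ModelConfig,
    ResourceItem,
    aggregate,
    allocate_item_cost,
    apply_overheads,
    round_half_up,
)
from .psa import run_psa

__all__ = [
    "Variation",
    "SensitivityResult",
    "ScenarioCurve",
    "apply_variation",
    "one_way",
    "two_way",
    "scenario_throughput",
    "fit_fixed_variable",
    "standard_variations",
]


@dataclass(frozen=True)
class Variation:
    """A labelled single change to the model.

    Either a config change (``path`` = dotted field path into
    :class:`ModelConfig`, with ``value``) or an item change (``multiplier``
    applied to ``item_field`` of every item matching the ``stage`` /
    ``category`` / ``name_contains`` filters).
    """

    label: str
    path: str | None = None
    value: float | None = None
    multiplier: float | None = None
    stage: str | None = None
    category: Category | str | None = None
    name_contains: str | None = None
    item_field: str = "unit_cost"

    def __post_init__(self) -> None:
        if (self.path is None) == (self.multiplier is None):
            raise ValueError(
                f"variation {self.label!r}: give exactly one of path/value "
                "or multiplier"
            )
        if self.path is not None and self.value is None:
            raise ValueError(f"variation {self.label!r}: path requires a value")
        if self.item_field not in ("unit_cost", "quantity"):
            raise ValueError("item_field must be 'unit_cost' or 'quantity'")


@dataclass(frozen=True)
class SensitivityResult:
    """Recomputed total for one variation, versus the base case."""

    label: str
    total: float
    base_total: float
    ci95: tuple[float, float] | None = None

    @property
    def percent_change(self) -> float:
        return (self.total - self.base_total) / self.base_total * 100.0

    @property
    def percent_change_rounded(self) -> int:
        return int(round_half_up(self.percent_change))


def _set_config_path(config, path: str, value):
    head, _, rest = path.partition(".")
    if not hasattr(config, head):
        raise ValueError(f"unknown parameter path {path!r}")
    if rest:
        sub = getattr(config, head)
        if not is_dataclass(sub):
            raise ValueError(f"unknown parameter path {path!r}")
        return replace(config, **{head: _set_config_path(sub, rest, value)})
    current = getattr(config, head)
    if isinstance(current, int) and not isinstance(current, bool):
        value = int(value)
    return replace(config, **{head: value})


def _matches(item: ResourceItem, v: Variation) -> bool:
    if v.stage is not None and item.stage != v.stage:
        return False
    if v.category is not None and item.category is not Category(v.category):
        return False
    if v.name_contains is not None and v.name_contains.lower() not in item.name.lower():
        return False
    return True


def apply_variation(
    items: Sequence[ResourceItem], config: ModelConfig, variation: Variation
) -> tuple[list[ResourceItem], ModelConfig]:
    """Return the (items, config) pair with one variation applied."""
    if variation.path is not None:
        return list(items), _set_config_path(config, variation.path, variation.value)
    new_items = []
    for item in items:
        if _matches(item, variation):
            old = getattr(item, variation.item_field)
            kwargs = {variation.item_field: old * variation.multiplier}
            if variation.item_field == "unit_cost" and item.uncertainty is not None:
                lo, hi = item.uncertainty
                kwargs["uncertainty"] = (lo * variation.multiplier, hi * variation.multiplier)
            item = replace(item, **kwargs)
        new_items.append(item)
    return new_items, config


def one_way(
    items: Sequence[ResourceItem],
    config: ModelConfig,
    variation: Variation | Sequence[Variation],
    *,
    psa_draws: int = 0,
    seed: int = 0,
) -> SensitivityResult:
    """Rebuild the model under one variation (or a combined list of them)."""
    base_total = aggregate(items, config).post_overhead_total
    variations = [variation] if isinstance(variation, Variation) else list(variation)
    new_items, new_config = list(items), config
    for v in variations:
        new_items, new_config = apply_variation(new_items, new_config, v)
    total = aggregate(new_items, new_config).post_overhead_total
    ci = None
    if psa_draws > 0:
        ci = run_psa(new_items, new_config, n_draws=psa_draws, seed=seed).ci95
    label = " + ".join(v.label for v in variations)
    return SensitivityResult(label=label, total=total, base_total=base_total, ci95=ci)


def two_way(
    items: Sequence[ResourceItem],
    config: ModelConfig,
    axis1: Sequence[Variation],
    axis2: Sequence[Variation],
) -> pd.DataFrame:
    """Cross-product of two variation axes; cells are post-overhead totals.

    Row/column margins (obtained by pairing an axis with a null variation)
    reproduce the corresponding one-way totals.
    """
    if not axis1 or not axis2:
        raise ValueError("both axes must be non-empty")
    table = pd.DataFrame(
        index=[v.label for v in axis1],
        columns=[v.label for v in axis2],
        dtype=float,
    )
    for v1 in axis1:
        for v2 in axis2:
            table.loc[v1.label, v2.label] = one_way(items, config, [v1, v2]).total
    table.index.name = "axis1"
    table.columns.name = "axis2"
    return table


@dataclass(frozen=True)
class ScenarioCurve:
    """Per-patient totals over an annual-throughput grid.

    ``fixed_component`` F is the post-overhead sum of all ``annual_fixed``
    allocations at the base throughput; ``variable_component`` V collects the
    throughput-invariant per-batch / per-sample / per-patient allocations.
    Totals obey ``total(T) = V + F * base_patients / T`` exactly.
    """

    frame: pd.DataFrame  # columns: annual_patients, total[, ci_low, ci_high]
    fixed_component: float
    variable_component: float
    base_patients: int


def scenario_throughput(
    items: Sequence[ResourceItem],
    config: ModelConfig,
    grid: Iterable[int],
    *,
    psa_draws: int = 0,
    seed: int = 0,
) -> ScenarioCurve:
    """Recompute the per-patient total at each annual throughput in ``grid``."""
    grid = [int(t) for t in grid]
    capacity = config.throughput.max_platform_capacity * config.throughput.platforms
    for t in grid:
        if t <= 0:
            raise ValueError("throughput grid values must be > 0")
        if t > capacity:
            raise ValueError(
                f"throughput {t} exceeds the maximum annual capacity "
                f"({capacity}) of the configured platform(s)"
            )

    fixed_pre = sum(
        allocate_item_cost(it, config)
        for it in items
        if it.basis is Basis.ANNUAL_FIXED
    )
    variable_pre = aggregate(items, config).pre_overhead_total - fixed_pre

    rows = []
    for t in grid:
        cfg_t = _set_config_path(config, "throughput.annual_patients", t)
        total = aggregate(items, cfg_t).post_overhead_total
        row = {"annual_patients": t, "total": total}
        if psa_draws > 0:
            ci = run_psa(items, cfg_t, n_draws=psa_draws, seed=seed).ci95
            row["ci_low"], row["ci_high"] = ci
        rows.append(row)
    return ScenarioCurve(
        frame=pd.DataFrame(rows),
        fixed_component=apply_overheads(fixed_pre, config.overhead_rate),
        variable_component=apply_overheads(variable_pre, config.overhead_rate),
        base_patients=config.throughput.annual_patients,
    )


def fit_fixed_variable(
    points: Sequence[tuple[float, float]], base_patients: int
) -> tuple[float, float]:
    """Least-squares fit of ``total = V + F * base/T`` to (T, total) points.

    Returns ``(V, F)``; with two points the fit is exact.  This recovers the
    fixed/variable decomposition implied by published totals at different
    annual volumes.
    """
    if len(points) < 2:
        raise ValueError("need at least two (throughput, total) points")
    t = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    x = base_patients / t
    design = np.column_stack([np.ones_like(x), x])
    (v, f), *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(v), float(f)


def standard_variations() -> list[Variation]:
    """The shipped one-way analysis set (bioinformatics time, overheads,
    utilization, discount rate, throughput, equipment and consumable
    discounts)."""
    return [
        Variation("25% less bioinformatics time", multiplier=0.75,
                  stage="bioinformatics", category=Category.LABOR,
                  item_field="quantity"),
        Variation("10% less bioinformatics time", multiplier=0.90,
                  stage="bioinformatics", category=Category.LABOR,
                  item_field="quantity"),
        Variation("Overheads 10%", path="overhead_rate", value=0.10),
        Variation("Overheads 30%", path="overhead_rate", value=0.30),
        Variation("50% equipment utilization",
                  path="throughput.utilization_rate", value=0.50),
        Variation("100% equipment utilization",
                  path="throughput.utilization_rate", value=1.00),
        Variation("1.5% equipment discount rate", path="discount_rate", value=0.015),
        Variation("3.5% equipment discount rate", path="discount_rate", value=0.035),
        Variation("Throughput 500 patients per annum",
                  path="throughput.annual_patients", value=500),
        Variation("Throughput 1500 patients per annum",
                  path="throughput.annual_patients", value=1500),
        Variation("25% lower cost of the Orbitrap mass spectrometer",
                  multiplier=0.75, name_contains="orbitrap"),
        Variation("25% lower consumable costs", multiplier=0.75,
                  category=Category.CONSUMABLE),
    ]
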