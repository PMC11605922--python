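"""Core cost model: resource items, configuration, and per-patient aggregation.

The model follows standard laboratory micro-costing practice: every costed
resource (a consumable, a share of an equipment item, or staff minutes) is a
:class:`ResourceItem` attached to one workflow stage, and per-patient costs
are obtained by allocating each item's cost according to its *basis*:

``per_batch``
    cost is incurred once per processing batch and divided by the number of
    patients a batch accommodates;
``per_sample``
    cost is incurred per analytical sample and multiplied by the number of
    replicate samples per patient;
``per_patient``
    cost maps one-to-one to a patient;
``annual_fixed``
    cost is incurred per year (annualized equipment, maintenance contracts,
    annually-amortized labor such as instrument troubleshooting) and divided
    by the annual patient throughput, so it scales inversely with volume.

All internal arithmetic is carried out in full precision, in Australian
dollars; rounding to whole dollars or whole percent happens only in the
reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .equipment import equivalent_annual_cost

__all__ = [
    "STAGES",
    "STAGE_LABELS",
    "Category",
    "Basis",
    "ResourceItem",
    "BatchConfig",
    "ThroughputConfig",
    "ModelConfig",
    "CostBreakdown",
    "allocate_item_cost",
    "aggregate",
    "apply_overheads",
    "category_shares",
    "batches_for_throughput",
    "round_half_up",
]

#: The seven workflow stages of the costed pipeline, in processing order.
STAGES: tuple[str, ...] = (
    "pbmc_isolation",
    "protein_quantification",
    "spin_column_digestion",
    "lcms",
    "bioinformatics",
    "reporting",
    "data_archiving",
)

STAGE_LABELS: dict[str, str] = {
    "pbmc_isolation": "PBMCs isolation",
    "protein_quantification": "Protein quantification (BCA assay)",
    "spin_column_digestion": "Spin column digestion",
    "lcms": "LC-MS/MS",
    "bioinformatics": "Bioinformatics",
    "reporting": "Reporting",
    "data_archiving": "Data archiving",
}


class Category(str, Enum):
    """Cost category of a resource item."""

    CONSUMABLE = "consumable"
    EQUIPMENT = "equipment"
    LABOR = "labor"


class Basis(str, Enum):
    """Allocation basis mapping an item's natural cost unit to a patient."""

    PER_SAMPLE = "per_sample"
    PER_BATCH = "per_batch"
    PER_PATIENT = "per_patient"
    ANNUAL_FIXED = "annual_fixed"


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero (the convention of printed cost tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ResourceItem:
    """One costed line item of the workflow.

    ``quantity`` is in the item's natural unit (count of units, staff minutes,
    GB-years, ...) per basis event; ``unit_cost`` is AUD per unit.  Equipment
    items carrying a ``lifetime`` are interpreted as acquisitions: their
    annual cost is the equivalent annual cost of ``quantity * unit_cost``
    plus ``annual_maintenance``, scaled by ``sharing_fraction`` (the share of
    the instrument's time attributed to this pipeline).

    ``uncertainty`` is an optional ``(min, max)`` range on ``unit_cost`` used
    by the probabilistic sensitivity analysis.  The flag ``"reanalysis"``
    marks labor whose expected time includes the fraction of cases requiring
    re-analysis.
    """

    name: str
    stage: str
    category: Category
    basis: Basis
    quantity: float
    unit_cost: float
    unit: str = ""
    uncertainty: tuple[float, float] | None = None
    flags: frozenset[str] = frozenset()
    lifetime: float | None = None
    annual_maintenance: float = 0.0
    sharing_fraction: float = 1.0
    reanalysis_fraction: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", Category(self.category))
        object.__setattr__(self, "basis", Basis(self.basis))
        if isinstance(self.flags, str):
            object.__setattr__(
                self,
                "flags",
                frozenset(f for f in self.flags.split("|") if f),
            )
        else:
            object.__setattr__(self, "flags", frozenset(self.flags))

    def validate(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(
                f"item {self.name!r}: unknown stage {self.stage!r}; "
                f"expected one of {', '.join(STAGES)}"
            )
        if self.quantity < 0:
            raise ValueError(f"item {self.name!r}: quantity must be >= 0")
        if self.unit_cost < 0:
            raise ValueError(f"item {self.name!r}: unit_cost must be >= 0")
        if not 0 < self.sharing_fraction <= 1:
            raise ValueError(f"item {self.name!r}: sharing_fraction must be in (0, 1]")
        if self.lifetime is not None:
            if self.lifetime <= 0:
                raise ValueError(f"item {self.name!r}: lifetime must be > 0")
            if self.basis is not Basis.ANNUAL_FIXED:
                raise ValueError(
                    f"item {self.name!r}: annualized acquisitions (lifetime set) "
                    "must use basis=annual_fixed"
                )
        if self.annual_maintenance < 0:
            raise ValueError(f"item {self.name!r}: annual_maintenance must be >= 0")
        if self.uncertainty is not None:
            lo, hi = self.uncertainty
            if not lo <= self.unit_cost <= hi:
                raise ValueError(
                    f"item {self.name!r}: uncertainty range ({lo}, {hi}) must "
                    f"bracket the point estimate {self.unit_cost}"
                )
        if not 0 <= self.reanalysis_fraction <= 1:
            raise ValueError(f"item {self.name!r}: reanalysis_fraction must be in [0, 1]")


@dataclass(frozen=True)
class BatchConfig:
    """Composition of one processing batch.

    The default batch holds 24 samples: 6 quality-control samples plus
    6 patients at 3 replicate samples each.
    """

    samples_per_batch: int = 24
    control_samples: int = 6
    replicates_per_patient: int = 3

    @property
    def patients_per_batch(self) -> int:
        return (self.samples_per_batch - self.control_samples) // self.replicates_per_patient

    def validate(self) -> None:
        if min(self.samples_per_batch, self.replicates_per_patient) <= 0:
            raise ValueError("batch sizes must be positive")
        if self.control_samples < 0:
            raise ValueError("control_samples must be >= 0")
        if (
            self.control_samples
            + self.patients_per_batch * self.replicates_per_patient
            != self.samples_per_batch
        ):
            raise ValueError(
                "batch does not partition: controls + patients x replicates "
                "must equal samples_per_batch"
            )


@dataclass(frozen=True)
class ThroughputConfig:
    """Annual throughput and equipment utilization.

    ``annual_patients`` is the yearly patient volume over which annual fixed
    costs are spread (base case 986, the platform capacity at 75%
    utilization).  ``reference_utilization`` is the utilization rate embedded
    in the base-case unit costs; changing ``utilization_rate`` rescales every
    equipment allocation by ``reference_utilization / utilization_rate``.
    """

    annual_patients: int = 986
    utilization_rate: float = 0.75
    reference_utilization: float = 0.75
    max_platform_capacity: int = 1500
    platforms: int = 1

    def validate(self) -> None:
        if self.annual_patients < 0:
            raise ValueError("annual_patients must be >= 0")
        for name in ("utilization_rate", "reference_utilization"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.platforms <= 0 or self.max_platform_capacity <= 0:
            raise ValueError("platform counts must be positive")
        if self.annual_patients > self.max_platform_capacity * self.platforms:
            raise ValueError(
                f"annual_patients={self.annual_patients} exceeds capacity of "
                f"{self.platforms} platform(s) x {self.max_platform_capacity}"
            )


@dataclass(frozen=True)
class ModelConfig:
    """All global model parameters (base case defaults)."""

    batch: BatchConfig = field(default_factory=BatchConfig)
    throughput: ThroughputConfig = field(default_factory=ThroughputConfig)
    overhead_rate: float = 0.20
    discount_rate: float = 0.05
    reanalysis_rate: float = 0.02
    storage_gb_per_patient: float = 9.0
    storage_years: float = 5.0
    currency_display_rate: float = 0.6682  # AUD -> USD, display only
    depreciation: str = "annuity"  # or "straight_line"
    range_rule: str = "ci95"  # how a (min, max) range maps to an sd; see psa

    def validate(self) -> None:
        self.batch.validate()
        self.throughput.validate()
        for name in ("overhead_rate", "reanalysis_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.discount_rate < 0:
            raise ValueError("discount_rate must be >= 0")
        if self.storage_gb_per_patient <= 0 or self.storage_years <= 0:
            raise ValueError("storage parameters must be > 0")
        if self.depreciation not in ("annuity", "straight_line"):
            raise ValueError("depreciation must be 'annuity' or 'straight_line'")
        if self.range_rule not in ("ci95", "quarter"):
            raise ValueError("range_rule must be 'ci95' or 'quarter'")


@dataclass(frozen=True)
class CostBreakdown:
    """Per-patient stage x category cost matrix with totals.

    ``matrix`` is indexed by stage (all seven stages, in order) with one
    column per cost category, in AUD per patient, before overheads.
    """

    matrix: pd.DataFrame
    overhead_rate: float

    @property
    def stage_totals(self) -> pd.Series:
        return self.matrix.sum(axis=1)

    @property
    def category_totals(self) -> pd.Series:
        return self.matrix.sum(axis=0)

    @property
    def pre_overhead_total(self) -> float:
        return float(self.matrix.to_numpy().sum())

    @property
    def post_overhead_total(self) -> float:
        return apply_overheads(self.pre_overhead_total, self.overhead_rate)


def allocate_item_cost(item: ResourceItem, config: ModelConfig) -> float:
    """Allocate one item's cost to a single patient, in AUD.

    Raises :class:`ValueError` for an unknown basis or when the allocation
    would divide by zero (no patients per batch, zero annual throughput).
    """
    item.validate()
    config.validate()

    if item.basis is Basis.PER_BATCH:
        per_batch = config.batch.patients_per_batch
        if per_batch == 0:
            raise ValueError(
                f"item {item.name!r}: cannot allocate per-batch cost with "
                "0 patients per batch"
            )
        factor = 1.0 / per_batch
    elif item.basis is Basis.PER_SAMPLE:
        factor = float(config.batch.replicates_per_patient)
    elif item.basis is Basis.PER_PATIENT:
        factor = 1.0
    elif item.basis is Basis.ANNUAL_FIXED:
        if config.throughput.annual_patients == 0:
            raise ValueError(
                f"item {item.name!r}: cannot allocate annual cost with "
                "0 patients per year"
            )
        factor = 1.0 / config.throughput.annual_patients
    else:  # pragma: no cover - Enum coercion makes this unreachable
        raise ValueError(f"item {item.name!r}: unknown basis {item.basis!r}")

    if item.lifetime is not None:
        annual = (
            equivalent_annual_cost(
                item.quantity * item.unit_cost,
                item.lifetime,
                config.discount_rate,
                method=config.depreciation,
            )
            + item.annual_maintenance
        ) * item.sharing_fraction
        cost = annual * factor
    else:
        cost = item.quantity * item.unit_cost * item.sharing_fraction * factor

    if item.category is Category.EQUIPMENT:
        cost *= config.throughput.reference_utilization / config.throughput.utilization_rate
    if item.category is Category.LABOR and "reanalysis" in item.flags:
        cost *= 1.0 + config.reanalysis_rate * item.reanalysis_fraction
    return cost


def aggregate(items: Sequence[ResourceItem], config: ModelConfig) -> CostBreakdown:
    """Aggregate items into the per-patient stage x category cost matrix."""
    if not items:
        raise ValueError("cannot aggregate an empty item list")
    matrix = pd.DataFrame(
        0.0, index=list(STAGES), columns=[c.value for c in Category]
    )
    for item in items:
        cost = allocate_item_cost(item, config)
        matrix.loc[item.stage, item.category.value] += cost
    matrix.index.name = "stage"
    return CostBreakdown(matrix=matrix, overhead_rate=config.overhead_rate)


def apply_overheads(pre_overhead_total: float, overhead_rate: float) -> float:
    """Add the overhead supplement: ``total * (1 + rate)``."""
    if overhead_rate < 0:
        raise ValueError("overhead_rate must be >= 0")
    return pre_overhead_total * (1.0 + overhead_rate)


def category_shares(breakdown: CostBreakdown) -> dict[str, float]:
    """Fractions of the pre-overhead total by category (sum to 1 exactly)."""
    total = breakdown.pre_overhead_total
    if total <= 0:
        raise ValueError("category shares undefined for a non-positive total")
    cat = breakdown.category_totals
    return {name: float(cat[name]) / total for name in cat.index}


def batches_for_throughput(annual_patients: int, batch: BatchConfig) -> int:
    """Number of full batches needed for an annual patient volume."""
    if annual_patients < 0:
        raise ValueError("annual_patients must be >= 0")
    batch.validate()
    return annual_patients // batch.patients_per_batch
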