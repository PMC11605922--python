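"""Synthetic cost workbook generation.

The published study reports per-patient costs only at the stage x category
level; the underlying item-level unit costs live in supplementary tables
that are not machine-readable.  This module generates a *synthetic* item
workbook with the structural features of the real one — named cost drivers
(SepMate/Ficoll density-gradient consumables, S-Trap digestion columns,
PepMap LC columns, the Orbitrap mass spectrometer and nanoHPLC, salary-scale
labor in minutes) plus seeded random filler items — and then calibrates unit
costs multiplicatively per cell so that deterministic aggregation reproduces
the printed stage x category matrix exactly.  Item-level values are
synthetic throughout; only the cell totals (and, loosely, the stage-level
uncertainty ranges) are faithful.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .equipment import equivalent_annual_cost
from .model import (
    Basis,
    Category,
    ModelConfig,
    ResourceItem,
    allocate_item_cost,
)
from .psa import sd_from_range

__all__ = [
    "CalibrationTarget",
    "WorkbookSpec",
    "TABLE1_TARGETS",
    "STAGE_CIS",
    "generate_workbook",
    "calibrate_to_targets",
    "attach_uncertainty",
    "calibration_report",
]


@dataclass(frozen=True)
class CalibrationTarget:
    """A per-patient AUD target for one (stage, category) cell."""

    stage: str
    category: Category
    value: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", Category(self.category))
        if self.value < 0:
            raise ValueError("calibration targets must be >= 0")


def _targets(cells: Mapping[tuple[str, str], float]) -> tuple[CalibrationTarget, ...]:
    return tuple(CalibrationTarget(s, Category(c), v) for (s, c), v in cells.items())


#: Published per-patient cost matrix (AUD, pre-overhead) used as the default
#: calibration target set.
TABLE1_TARGETS: tuple[CalibrationTarget, ...] = _targets({
    ("pbmc_isolation", "consumable"): 45.0,
    ("pbmc_isolation", "equipment"): 1.0,
    ("pbmc_isolation", "labor"): 8.0,
    ("protein_quantification", "consumable"): 7.0,
    ("protein_quantification", "equipment"): 2.0,
    ("protein_quantification", "labor"): 12.0,
    ("spin_column_digestion", "consumable"): 49.0,
    ("spin_column_digestion", "equipment"): 2.0,
    ("spin_column_digestion", "labor"): 10.0,
    ("lcms", "consumable"): 42.0,
    ("lcms", "equipment"): 192.0,
    ("lcms", "labor"): 109.0,
    ("bioinformatics", "equipment"): 4.0,
    ("bioinformatics", "labor"): 122.0,
    ("reporting", "equipment"): 0.3,
    ("reporting", "labor"): 135.0,
    ("data_archiving", "equipment"): 8.0,
})

#: Published stage-total 95% intervals (AUD, pre-overhead), used to attach
#: item-level uncertainty ranges.
STAGE_CIS: dict[str, tuple[float, float]] = {
    "pbmc_isolation": (35.0, 93.0),
    "protein_quantification": (16.0, 30.0),
    "spin_column_digestion": (43.0, 88.0),
    "lcms": (253.0, 482.0),
    "bioinformatics": (77.0, 188.0),
    "reporting": (69.0, 237.0),
    "data_archiving": (3.0, 15.0),
}

#: Representative annual salaries (AUD) by staff grade, mapped to per-minute
#: rates over 46 working weeks of 38 hours.
SALARY_SCALE: dict[str, float] = {
    "technical_grade2": 78_000.0,
    "scientist_grade3": 92_000.0,
    "doctoral_scientist": 118_000.0,
}
WORK_MINUTES_PER_YEAR: float = 46 * 38 * 60


def minute_rate(grade: str) -> float:
    """AUD per minute for a salary grade."""
    return SALARY_SCALE[grade] / WORK_MINUTES_PER_YEAR


@dataclass(frozen=True)
class WorkbookSpec:
    """Structural parameters of the synthetic workbook.

    The per-patient design values are the study conditions: they place the
    named cost drivers at their reported magnitudes (the Orbitrap at $135
    per patient, SepMate + Ficoll at $30 of the $45 PBMC consumables, PepMap
    columns at $30 of the $42 LC-MS/MS consumables, 98 bioinformatician
    minutes per patient) and put the annually-amortized labor — instrument
    troubleshooting and pipeline maintenance — in the LC-MS/MS and
    bioinformatics stages, about $37 per patient at the base throughput.
    """

    orbitrap_acquisition: float = 980_000.0
    orbitrap_lifetime: float = 10.0
    orbitrap_per_patient: float = 135.0
    hplc_acquisition: float = 330_000.0
    hplc_lifetime: float = 10.0
    hplc_per_patient: float = 50.0
    hpc_per_patient: float = 0.60
    fixed_labor_lcms: float = 25.0
    fixed_labor_bioinformatics: float = 12.0
    bioinformatician_minutes: float = 98.0
    reporting_minutes: float = 117.0
    sepmate_per_patient: float = 18.0
    ficoll_per_patient: float = 12.0
    strap_per_patient: float = 33.0
    pepmap_analytical_per_patient: float = 22.0
    pepmap_trap_per_patient: float = 8.0
    filler_items_range: tuple[int, int] = (2, 4)

    def validate(self) -> None:
        if self.filler_items_range[0] < 1 or self.filler_items_range[1] < self.filler_items_range[0]:
            raise ValueError("filler_items_range must be (lo, hi) with 1 <= lo <= hi")
        for f in (
            "orbitrap_per_patient", "hplc_per_patient", "hpc_per_patient",
            "fixed_labor_lcms", "fixed_labor_bioinformatics",
            "bioinformatician_minutes", "reporting_minutes",
        ):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be > 0")


def _equipment_item(
    name: str,
    stage: str,
    design_per_patient: float,
    acquisition: float,
    lifetime: float,
    config: ModelConfig,
    annual_maintenance: float | None = None,
    sharing_fraction: float | None = None,
) -> ResourceItem:
    """Build an annualized equipment item hitting a per-patient design value.

    Exactly one of maintenance / sharing fraction is back-derived so that
    (EAC + maintenance) * share / annual_patients equals the design value at
    the base configuration.
    """
    t = config.throughput.annual_patients
    eac = equivalent_annual_cost(acquisition, lifetime, config.discount_rate,
                                 method=config.depreciation)
    if annual_maintenance is None and sharing_fraction is not None:
        annual_maintenance = design_per_patient * t / sharing_fraction - eac
        if annual_maintenance < 0:
            raise ValueError(
                f"{name}: acquisition too large for design value "
                f"{design_per_patient}/patient"
            )
    elif sharing_fraction is None:
        annual_maintenance = annual_maintenance or 0.0
        sharing_fraction = design_per_patient * t / (eac + annual_maintenance)
        if not 0 < sharing_fraction <= 1:
            raise ValueError(f"{name}: derived sharing fraction {sharing_fraction:.3f} not in (0, 1]")
    return ResourceItem(
        name=name, stage=stage, category=Category.EQUIPMENT,
        basis=Basis.ANNUAL_FIXED, quantity=1.0, unit_cost=acquisition,
        unit="instrument", lifetime=lifetime,
        annual_maintenance=annual_maintenance, sharing_fraction=sharing_fraction,
    )


def _fillers(
    names: Sequence[str],
    stage: str,
    category: Category,
    basis: Basis,
    remainder: float,
    rng: np.random.Generator,
    config: ModelConfig,
    unit: str = "unit",
    k_range: tuple[int, int] = (2, 4),
) -> list[ResourceItem]:
    """Split a cell remainder across seeded random filler items."""
    k = min(len(names), int(rng.integers(k_range[0], k_range[1] + 1)))
    weights = rng.dirichlet(np.ones(k) * 2.0)
    if basis is Basis.PER_BATCH:
        factor = 1.0 / config.batch.patients_per_batch
    elif basis is Basis.PER_SAMPLE:
        factor = float(config.batch.replicates_per_patient)
    else:
        factor = 1.0
    items = []
    for name, w in zip(names[:k], weights):
        design = remainder * float(w)
        quantity = float(rng.integers(1, 49))
        items.append(ResourceItem(
            name=name, stage=stage, category=category, basis=basis,
            quantity=quantity, unit=unit,
            unit_cost=design / (quantity * factor),
        ))
    return items


def generate_workbook(
    spec: WorkbookSpec | None = None,
    seed: int = 0,
    config: ModelConfig | None = None,
    calibrate: bool = True,
    uncertainty: bool = True,
) -> list[ResourceItem]:
    """Generate a reproducible synthetic item workbook.

    With ``calibrate=True`` (default) cell totals are rescaled to the
    published matrix exactly; with ``uncertainty=True`` item-level
    (min, max) ranges are attached so stage-level simulation intervals land
    near the published ones.
    """
    spec = spec or WorkbookSpec()
    spec.validate()
    config = config or ModelConfig()
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))
    ppb = config.batch.patients_per_batch
    reps = config.batch.replicates_per_patient
    t = config.throughput.annual_patients
    items: list[ResourceItem] = []

    # --- consumables -----------------------------------------------------
    items += [
        ResourceItem("SepMate-15 (IVD) density gradient tubes", "pbmc_isolation",
                     Category.CONSUMABLE, Basis.PER_SAMPLE, 1.0,
                     spec.sepmate_per_patient / reps, unit="tube"),
        ResourceItem("Ficoll-Paque Plus gradient medium", "pbmc_isolation",
                     Category.CONSUMABLE, Basis.PER_SAMPLE, 1.0,
                     spec.ficoll_per_patient / reps, unit="aliquot"),
    ]
    items += _fillers(
        ["PBS and wash buffers", "Cryovials and freezing medium",
         "Pipette tips (PBMC isolation)", "Conical tubes"],
        "pbmc_isolation", Category.CONSUMABLE, Basis.PER_BATCH,
        45.0 - spec.sepmate_per_patient - spec.ficoll_per_patient,
        rng, config, k_range=spec.filler_items_range)
    items.append(ResourceItem(
        "BCA protein assay kit (per-batch share)", "protein_quantification",
        Category.CONSUMABLE, Basis.PER_BATCH, 1.0, 4.0 * ppb, unit="kit share"))
    items += _fillers(
        ["Microplates (BCA)", "Pipette tips (BCA)", "Reagent reservoirs"],
        "protein_quantification", Category.CONSUMABLE, Basis.PER_BATCH,
        3.0, rng, config, k_range=spec.filler_items_range)
    items.append(ResourceItem(
        "S-Trap micro spin columns", "spin_column_digestion",
        Category.CONSUMABLE, Basis.PER_SAMPLE, 1.0,
        spec.strap_per_patient / reps, unit="column"))
    items += _fillers(
        ["Digestion reagents (DTT, IAA, trypsin)", "Protein LoBind tubes",
         "Pipette tips (digestion)"],
        "spin_column_digestion", Category.CONSUMABLE, Basis.PER_BATCH,
        49.0 - spec.strap_per_patient, rng, config,
        k_range=spec.filler_items_range)
    items += [
        ResourceItem("Acclaim PepMap 100 analytical column (amortized)", "lcms",
                     Category.CONSUMABLE, Basis.PER_PATIENT, 1.0,
                     spec.pepmap_analytical_per_patient, unit="column share"),
        ResourceItem("Acclaim PepMap 100 trap column (amortized)", "lcms",
                     Category.CONSUMABLE, Basis.PER_PATIENT, 1.0,
                     spec.pepmap_trap_per_patient, unit="column share"),
    ]
    items += _fillers(
        ["LC solvents (acetonitrile, formic acid)", "Autosampler vials and caps"],
        "lcms", Category.CONSUMABLE, Basis.PER_SAMPLE,
        42.0 - spec.pepmap_analytical_per_patient - spec.pepmap_trap_per_patient,
        rng, config, k_range=spec.filler_items_range)

    # --- equipment (annualized acquisitions; shares reflect pooled use) ---
    items += [
        _equipment_item("Benchtop centrifuge (shared)", "pbmc_isolation",
                        1.0, 15_000.0, 10.0, config, annual_maintenance=200.0),
        _equipment_item("CO2 incubator (shared)", "protein_quantification",
                        1.2, 9_000.0, 5.0, config, annual_maintenance=100.0),
        _equipment_item("Pipette set (shared, BCA)", "protein_quantification",
                        0.8, 5_000.0, 5.0, config),
        _equipment_item("Vacuum concentrator (shared)", "spin_column_digestion",
                        1.3, 18_000.0, 10.0, config, annual_maintenance=150.0),
        _equipment_item("Pipette set (shared, digestion)", "spin_column_digestion",
                        0.7, 5_000.0, 5.0, config),
        _equipment_item("Orbitrap Exploris 480 mass spectrometer", "lcms",
                        spec.orbitrap_per_patient, spec.orbitrap_acquisition,
                        spec.orbitrap_lifetime, config, sharing_fraction=1.0),
        _equipment_item("UltiMate 3000 nanoHPLC", "lcms",
                        spec.hplc_per_patient, spec.hplc_acquisition,
                        spec.hplc_lifetime, config, sharing_fraction=1.0),
        _equipment_item("Nitrogen generator and column oven", "lcms",
                        192.0 - spec.orbitrap_per_patient - spec.hplc_per_patient,
                        40_000.0, 5.0, config, annual_maintenance=500.0),
        _equipment_item("High-performance computing system (30-core, shared)",
                        "bioinformatics", spec.hpc_per_patient,
                        30_000.0, 5.0, config, annual_maintenance=1_000.0),
        _equipment_item("Data security and backup infrastructure (shared)",
                        "bioinformatics", 4.0 - spec.hpc_per_patient,
                        25_000.0, 5.0, config, annual_maintenance=800.0),
        _equipment_item("Reporting workstation (shared)", "reporting",
                        0.3, 4_000.0, 5.0, config),
        ResourceItem("Digital data storage (9 GB/patient, 5-year retention)",
                     "data_archiving", Category.EQUIPMENT, Basis.ANNUAL_FIXED,
                     quantity=config.storage_gb_per_patient * config.storage_years * t,
                     unit_cost=8.0 / (config.storage_gb_per_patient * config.storage_years),
                     unit="GB-year"),
    ]

    # --- labor (minutes at salary-scale rates) ---------------------------
    def batch_labor(name: str, stage: str, design: float, grade: str) -> ResourceItem:
        rate = minute_rate(grade)
        minutes = round(design * ppb / rate)
        return ResourceItem(name, stage, Category.LABOR, Basis.PER_BATCH,
                            float(minutes), rate, unit="minute")

    r3 = minute_rate("scientist_grade3")
    rd = minute_rate("doctoral_scientist")
    items += [
        batch_labor("Technical scientist - PBMC isolation", "pbmc_isolation",
                    8.0, "technical_grade2"),
        batch_labor("Technical scientist - BCA assay", "protein_quantification",
                    12.0, "technical_grade2"),
        batch_labor("Technical scientist - column digestion", "spin_column_digestion",
                    10.0, "technical_grade2"),
        ResourceItem("MS operation, QC and gradient loading", "lcms",
                     Category.LABOR, Basis.PER_SAMPLE,
                     float(round((109.0 - spec.fixed_labor_lcms) / reps / r3)),
                     r3, unit="minute"),
        ResourceItem("Instrument calibration and troubleshooting (annualized)",
                     "lcms", Category.LABOR, Basis.ANNUAL_FIXED,
                     float(round(spec.fixed_labor_lcms * t / r3)), r3,
                     unit="minute/year"),
        ResourceItem("Bioinformatician - data analysis", "bioinformatics",
                     Category.LABOR, Basis.PER_PATIENT,
                     spec.bioinformatician_minutes,
                     (122.0 - spec.fixed_labor_bioinformatics)
                     / (spec.bioinformatician_minutes * (1 + config.reanalysis_rate)),
                     unit="minute", flags=frozenset({"reanalysis"})),
        ResourceItem("Pipeline maintenance and automation scripting (annualized)",
                     "bioinformatics", Category.LABOR, Basis.ANNUAL_FIXED,
                     float(round(spec.fixed_labor_bioinformatics * t / rd)), rd,
                     unit="minute/year"),
        ResourceItem("Report generation, review and dispatch", "reporting",
                     Category.LABOR, Basis.PER_PATIENT, spec.reporting_minutes,
                     135.0 / spec.reporting_minutes, unit="minute"),
    ]

    for item in items:
        item.validate()
    if calibrate:
        items = calibrate_to_targets(items, TABLE1_TARGETS, config)
    if uncertainty:
        items = attach_uncertainty(items, STAGE_CIS, config)
    return items


def calibrate_to_targets(
    items: Sequence[ResourceItem],
    targets: Sequence[CalibrationTarget] = TABLE1_TARGETS,
    config: ModelConfig | None = None,
) -> list[ResourceItem]:
    """Rescale unit costs per cell so aggregated cell totals hit the targets.

    Scaling is multiplicative (unit cost and, for annualized equipment, the
    maintenance contract) so relative item proportions within a cell are
    preserved; calibration is idempotent.
    """
    config = config or ModelConfig()
    achieved: dict[tuple[str, Category], float] = {}
    for item in items:
        key = (item.stage, item.category)
        achieved[key] = achieved.get(key, 0.0) + allocate_item_cost(item, config)
    factors: dict[tuple[str, Category], float] = {}
    for tgt in targets:
        key = (tgt.stage, tgt.category)
        got = achieved.get(key, 0.0)
        if got == 0.0:
            if tgt.value == 0.0:
                continue
            raise ValueError(
                f"cannot calibrate empty cell ({tgt.stage}, {tgt.category.value}) "
                f"to a nonzero target"
            )
        factors[key] = tgt.value / got
    out = []
    for item in items:
        f = factors.get((item.stage, item.category))
        if f is None or f == 1.0:
            out.append(item)
            continue
        kwargs = {
            "unit_cost": item.unit_cost * f,
            "annual_maintenance": item.annual_maintenance * f,
        }
        if item.uncertainty is not None:
            lo, hi = item.uncertainty
            kwargs["uncertainty"] = (lo * f, hi * f)
        out.append(replace(item, **kwargs))
    return out


def attach_uncertainty(
    items: Sequence[ResourceItem],
    stage_cis: Mapping[str, tuple[float, float]] = STAGE_CIS,
    config: ModelConfig | None = None,
) -> list[ResourceItem]:
    """Attach (min, max) unit-cost ranges targeting stage-level intervals.

    The published intervals are stage totals.  The stage-implied standard
    deviation is distributed across items so that the variance of a sum of
    independent item draws matches it: item i receives
    ``sd_i = sd_stage * m_i / ||m||_2`` of allocated-cost spread, converted
    to the unit-cost scale through the (linear) allocation.  Ranges are the
    implied central 95% intervals, floored at zero, so reproduced stage
    intervals are approximate by construction.
    """
    config = config or ModelConfig()
    by_stage: dict[str, list[int]] = {}
    for i, item in enumerate(items):
        by_stage.setdefault(item.stage, []).append(i)
    out = list(items)
    for stage, (lo, hi) in stage_cis.items():
        idxs = by_stage.get(stage, [])
        if not idxs:
            continue
        sd_stage = sd_from_range(lo, hi, config.range_rule)
        alloc = {i: allocate_item_cost(items[i], config) for i in idxs}
        norm = math.sqrt(sum(m * m for m in alloc.values()))
        if norm == 0 or sd_stage == 0:
            continue
        for i in idxs:
            item, m = items[i], alloc[i]
            if m <= 0 or item.unit_cost <= 0:
                continue
            base = allocate_item_cost(
                replace(item, unit_cost=0.0, uncertainty=None), config)
            slope = (m - base) / item.unit_cost
            if slope <= 0:
                continue
            sd_unit = sd_stage * (m / norm) / slope
            rng_lo = max(0.0, item.unit_cost - 1.96 * sd_unit)
            rng_hi = item.unit_cost + 1.96 * sd_unit
            out[i] = replace(item, uncertainty=(rng_lo, rng_hi))
    return out


def calibration_report(
    items: Sequence[ResourceItem],
    targets: Sequence[CalibrationTarget] = TABLE1_TARGETS,
    config: ModelConfig | None = None,
) -> dict:
    """Target vs achieved per-patient cell totals, for audit output."""
    config = config or ModelConfig()
    achieved: dict[tuple[str, Category], float] = {}
    for item in items:
        key = (item.stage, item.category)
        achieved[key] = achieved.get(key, 0.0) + allocate_item_cost(item, config)
    cells = []
    for tgt in targets:
        got = achieved.get((tgt.stage, tgt.category), 0.0)
        cells.append({
            "stage": tgt.stage,
            "category": tgt.category.value,
            "target": tgt.value,
            "achieved": got,
            "abs_error": abs(got - tgt.value),
        })
    return {
        "cells": cells,
        "n_items": len(items),
        "max_abs_error": max(c["abs_error"] for c in cells) if cells else 0.0,
    }
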