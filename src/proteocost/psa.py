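"""Probabilistic sensitivity analysis.

Each uncertain unit cost is described by a point estimate and a (min, max)
range.  The range is converted to a standard deviation, a gamma distribution
is fitted by the method of moments (shape ``k = mean^2 / sd^2``, scale
``theta = sd^2 / mean``, so the fitted mean and variance match the inputs
exactly), and the model is propagated by Monte Carlo: every draw resamples
all uncertain inputs independently, rebuilds the cost breakdown, and records
the post-overhead per-patient total.  Uncertainty is summarized with
non-parametric 2.5th/97.5th percentile intervals.

Reproducibility: a single master seed is combined with a stable per-item key
(a CRC-32 of stage, category and name) so that adding or removing one item
never perturbs the draws of the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .model import Category, ModelConfig, ResourceItem, allocate_item_cost, apply_overheads

__all__ = [
    "GammaParams",
    "Degenerate",
    "PSAResult",
    "sd_from_range",
    "fit_gamma_mom",
    "run_psa",
]


def sd_from_range(lo: float, hi: float, rule: str = "ci95") -> float:
    """Standard deviation implied by a (min, max) range.

    ``ci95`` treats the range as a central 95% interval, ``sd = (hi-lo)/3.92``;
    ``quarter`` uses the cruder ``(hi-lo)/4`` convention.
    """
    if hi < lo:
        raise ValueError(f"range max {hi} < min {lo}")
    width = hi - lo
    if rule == "ci95":
        return width / 3.92
    if rule == "quarter":
        return width / 4.0
    raise ValueError("rule must be 'ci95' or 'quarter'")


@dataclass(frozen=True)
class GammaParams:
    """Gamma distribution in shape/scale form."""

    shape: float
    scale: float

    @property
    def mean(self) -> float:
        return self.shape * self.scale

    @property
    def variance(self) -> float:
        return self.shape * self.scale**2


@dataclass(frozen=True)
class Degenerate:
    """Point mass used when an input has no uncertainty (sd = 0)."""

    value: float


def fit_gamma_mom(mean: float, sd: float) -> GammaParams | Degenerate:
    """Method-of-moments gamma fit; returns a point mass when sd = 0."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return Degenerate(mean)
    if mean <= 0:
        raise ValueError("gamma method-of-moments requires mean > 0 when sd > 0")
    return GammaParams(shape=mean**2 / sd**2, scale=sd**2 / mean)


@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo summary of the per-patient total (post-overhead, AUD)."""

    draws: np.ndarray
    mean: float
    ci95: tuple[float, float]
    seed: int
    n_draws: int
    stage_draws: dict[str, np.ndarray]  # pre-overhead stage totals


def _item_rng(seed: int, item: ResourceItem) -> np.random.Generator:
    key = zlib.crc32(f"{item.stage}|{item.category.value}|{item.name}".encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def _linearize(item: ResourceItem, config: ModelConfig) -> tuple[float, float]:
    """Allocated cost as ``a + b * unit_cost`` (allocation is linear in it)."""
    a = allocate_item_cost(replace(item, unit_cost=0.0, uncertainty=None), config)
    full = allocate_item_cost(item, config)
    if item.unit_cost == 0:
        return a, 0.0
    return a, (full - a) / item.unit_cost


def run_psa(
    items: Sequence[ResourceItem],
    config: ModelConfig,
    n_draws: int = 10_000,
    seed: int = 0,
) -> PSAResult:
    """Propagate unit-cost uncertainty through the cost model.

    Items without an uncertainty range (or with a zero-width one) contribute
    deterministically; with *all* inputs degenerate the result collapses to
    the deterministic total with a zero-width interval.
    """
    if not items:
        raise ValueError("cannot run a PSA on an empty item list")
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    config.validate()

    stage_draws: dict[str, np.ndarray] = {}
    for item in items:
        item.validate()
        if item.uncertainty is None or item.uncertainty[0] == item.uncertainty[1]:
            contribution = np.full(1, allocate_item_cost(item, config))
        else:
            lo, hi = item.uncertainty
            sd = sd_from_range(lo, hi, config.range_rule)
            dist = fit_gamma_mom(item.unit_cost, sd)
            a, b = _linearize(item, config)
            unit_draws = _item_rng(seed, item).gamma(dist.shape, dist.scale, size=n_draws)
            contribution = a + b * unit_draws
        prev = stage_draws.get(item.stage, 0.0)
        stage_draws[item.stage] = prev + contribution

    totals_pre = np.zeros(n_draws)
    for stage, arr in stage_draws.items():
        stage_draws[stage] = np.broadcast_to(arr, (n_draws,)).copy() if arr.size == 1 else arr
        totals_pre += stage_draws[stage]
    totals = apply_overheads(totals_pre, config.overhead_rate)
    lo, hi = np.percentile(totals, [2.5, 97.5])
    return PSAResult(
        draws=totals,
        mean=float(totals.mean()),
        ci95=(float(lo), float(hi)),
        seed=int(seed),
        n_draws=int(n_draws),
        stage_draws=stage_draws,
    )
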