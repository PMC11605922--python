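# Methods

## Scope and perspective

`proteocost` estimates the per-patient delivery cost of an LC-MS/MS
quantitative proteomics diagnostic test from the laboratory provider
perspective, in 2023 Australian dollars. It covers the seven operational
stages from PBMC isolation to data archiving. Out of scope by design:
sample collection/reception (available only as a one-way variation),
diagnostic yield and cost-effectiveness, start-up and validation costs,
long-term research data banking, and any wet-lab protocol logic — stages
are cost buckets only.

## Cost allocation

The unit of processing is a 24-sample batch: 6 quality-control samples plus
6 patients at 3 replicates each (`BatchConfig`); 986 patients/year
(164 full batches) is the base-case throughput, corresponding to 75%
utilization of a single platform with a 1,500-patient/year ceiling.
Each item's cost reaches the patient through one of four bases (per batch,
per sample, per patient, annual fixed). Two multipliers apply after basis
allocation:

- **Utilization.** Base-case unit costs embed the 75% reference
  utilization; running at utilization *u* rescales every equipment
  allocation by 0.75/*u*. The rule is applied uniformly to all equipment
  items. Under it a 50% utilization raises the total by 14.0%; a 100%
  utilization lowers it by 7.0%. (A published figure of −6% for the 100%
  case suggests the original analysis exempted some equipment from the
  rescaling; no simple exemption rule reproduces it, so the uniform rule is
  kept and the discrepancy documented here.)
- **Re-analysis.** About 2% of cases need bioinformatic re-analysis. This
  is an expected-value multiplier (1 + 0.02 × time fraction) on labor items
  flagged `reanalysis`, not a stochastic event.

Labor is stored as minutes with per-minute rates derived from an annual
salary scale (46 working weeks × 38 h); representative grades span
technical (~$0.74/min) to doctoral (~$1.13/min) staff.

## Equipment, depreciation and storage

Acquisitions are annuitized with the equivalent annual cost
A = P·r/(1 − (1+r)^−L) at a 5% discount rate over 5- or 10-year lifetimes;
plain straight-line P/L is available as `depreciation: straight_line` and
is the exact r → 0 limit. ("Straight-line depreciation with a discount
rate" is internally ambiguous as a specification — straight-line has no
discounting — so the annuity is the default, which is standard
health-technology-assessment practice and gives the discount-rate
sensitivity analyses well-defined meaning.) Maintenance contracts are
annual costs added to the EAC; shared instruments (centrifuges, incubators,
pipette sets) carry a sharing fraction in (0, 1]. Data archiving is costed
as GB per patient × retention years × price per GB-year (9 GB, 5 years;
the unit price ≈ $0.178/GB-year is back-solved from the published $8 per
patient and is a synthetic calibration value).

## Probabilistic sensitivity analysis

Uncertain unit costs carry (min, max) ranges. The default range→sd rule
treats the range as a central 95% interval, sd = (max − min)/3.92; a
(max − min)/4 rule is selectable (`range_rule: quarter`). A gamma
distribution is fitted by the method of moments (k = mean²/sd²,
θ = sd²/mean; sd = 0 degenerates to a point mass), and 10,000 Monte Carlo
draws resample all inputs independently — no correlation structure is
imposed — rebuilding the breakdown each draw (the allocation is linear in
unit cost, so this is computed exactly in vectorized form). Summaries are
the empirical mean and the non-parametric 2.5th/97.5th percentile interval.
Seeding: one master seed plus a CRC-32 of (stage, category, name) yields an
independent substream per item, so adding or removing an item never
perturbs the draws of the others.

## Deterministic sensitivity analyses

A `Variation` is either a config change (dotted parameter path) or a
multiplicative change to a filtered item subset (by stage, category or name
substring, acting on unit cost or quantity). One-way analyses report the
recomputed post-overhead total and percent change versus base (rounded to
whole percent only at the reporting layer); two-way analyses take the
cross-product of two axes, whose margins against a null variation reproduce
the one-way results. The "lower Orbitrap cost" variation scales the
acquisition price only, not the maintenance contract — a modelling choice,
since the published −4% is consistent with it. The throughput scenario
re-divides only `annual_fixed` allocations, so the curve is exactly
total(T) = V + F·(986/T); `fit_fixed_variable` recovers (V, F) from any two
(T, total) points. The grid refuses T beyond the 1,500-patient single-
platform capacity.

## The synthetic workbook

The real item-level workbook (supplier prices, salary steps) is not public.
The generator emulates its structure: named anchor items at their reported
magnitudes — the Orbitrap Exploris 480 at $980k/10 years annuitized to
$135/patient with its service contract, SepMate + Ficoll at $30 of the $45
PBMC consumables, S-Trap columns in digestion, PepMap columns at $30 of the
$42 LC-MS/MS consumables, a shared 30-core computing system at $0.60, 98
bioinformatician minutes per patient (the 215 min of analysis-plus-
reporting labor splits as 98 bioinformatics + 117 reporting) — plus seeded
random filler items, with multiplicative per-cell calibration forcing every
stage × category total onto the published matrix to machine precision.
About $37/patient of labor (pre-overhead, at base throughput) is placed as
`annual_fixed` instrument troubleshooting and pipeline maintenance in the
LC-MS/MS and bioinformatics stages: annualized equipment alone
under-predicts the published scenario totals at 500 and 1,500
patients/year, and this fixed-labor share makes the model's own
fixed/variable decomposition (F ≈ $296 including overheads) match the
decomposition implied by those published points.

Uncertainty ranges are assigned from the published *stage-level* intervals:
the stage sd is distributed over items as sd_i = sd_stage·m_i/‖m‖₂ so that
the variance of a sum of independent item draws equals the stage target,
then converted to the unit-cost scale and expressed as a central 95% range
floored at zero. Reproduced stage intervals are therefore approximate
(tests use a 25% band on endpoints); whether the original analysis fitted
gammas at item or stage level is unknown, and the published total interval
($734–$1,111) is reproduced only to within that band (typically ~2%).

What the synthetic data do **not** emulate: true supplier price lists,
actual salary steps, item counts of the real workbook, any input
correlation, and price–volume discounts. Passing tests therefore validate
the *model arithmetic* and the published aggregate behaviour, not the
confidentiality-protected item detail.

## Numerical conventions and degenerate inputs

All computation is in full double precision; rounding (half-up, ties away
from zero) to whole dollars/percent happens only in the reporting layer.
The published tables carry ±$1 rounding artifacts which the model does not
try to reverse-engineer: 748 × 1.2 = 897.6 prints as $897; the printed
LC-MS/MS cells (42 + 192 + 109 = 343) and digestion cells (49 + 2 + 10 =
61) differ by $1 from their printed stage totals (342, 62). Calibration
follows the cells, so the model's stage totals sit within $1 of the printed
ones and the pre-overhead total is 748.3. The printed US$ figures use an
unclear conversion basis; USD is display-only at 0.6682 and never enters
the model. Zero patients per batch or per year are division-guard errors;
a zero-width uncertainty range is a point mass; gamma fitting rejects a
nonpositive mean with positive sd.

## Problem sizes

The shipped analyses run at the study's own scale — 37 workbook items,
10,000 PSA draws, 15-point scenario grids — and complete in about a second;
property tests use 10³–10⁶ draws where a sampling check needs them.

## Known limitations

- The −6% published effect of 100% utilization is not reproduced (see
  above); the model gives −7%.
- The published scenario total at 100 patients/year ($3,510) deviates ~0.2%
  from an exact 1/T model; the model gives $3,517 and a 292% increase
  versus the printed 291%.
- Stage-level uncertainty calibration is loose by construction.
- Costs are 2023 AUD with no indexation machinery.
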