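# Methods

## Model overview

`ncsim` estimates annual and cumulative greenhouse-gas reductions
attributable to natural climate solutions (NCS) relative to current
("baseline") implementation rates, over the calendar horizon 2020–2050
(31 annual steps). Twelve activities are modeled in three groups —
avoided conversion, land management, restoration — each reduced to a small
flux model driven by (a) a baseline implementation rate, (b) one or two
per-unit flux distributions, and (c) a scenario schedule expressing the
implementation level as a signed fraction of baseline change.

Uncertainty is propagated by Monte Carlo simulation: per-unit rates are
drawn from normal or uniform distributions parameterized by published means
and uncertainty ranges, 1000 iterations by default, and every reported
series is summarized as the median with the empirical 5th–95th percentile
band (the "90% CI"). All randomness flows from one master seed through an
independent substream per (activity, iteration) — keyed by a CRC-32 of the
activity id — so results are bit-reproducible and adding or removing an
activity never perturbs the draws of the others.

## Benefit accounting

Every activity's benefit is computed as the difference between the scenario
path and the baseline counterfactual, with common random numbers (the same
draws feed both paths), so a zero-change schedule yields exactly zero
benefit in every iteration.

**Avoided conversion.** The avoided area in year *y* is
`baseline × max(−level(y), 0)`. Each newly avoided hectare books a one-time
committed-emission credit in that year; all cumulatively avoided hectares
book an ongoing foregone-sequestration credit every year. Cohort
accumulation of the ongoing term is the only reading consistent with
"sequestration that would have been lost": land whose conversion was
avoided in 2025 is still sequestering in 2045. One-time committed
emissions are booked entirely in the avoidance year (not amortized).

For the two forest-conversion activities the per-hectare distributions are
derived at bundle-load time from regional carbon pools: committed emissions
`(AGB·0.54 + BGB + L + WD) × 44/12` for urban conversion and half that for
rural, and foregone sequestration as 84% (urban) or 50% (rural) of gross
growth; regional values are mixed 70% coastal / 30% interior and given a
15% relative standard deviation. Soil organic carbon is excluded from
forest conversion (its response is too uncertain), and grassland conversion
assumes complete loss of perennial root biomass (67.6 ± 7.66 Mg CO₂e ha⁻¹)
with no ongoing term.

**Deferred timber harvest.** Scenario deferment is specified per ownership
class as a fraction of that ownership's baseline volume, then passed through
two constraints each year: private-industrial deferment is clamped at 25%
of its baseline, and if total remaining harvest would fall below 40% of the
overall baseline, non-industrial deferments are scaled down proportionally
until the floor holds exactly. Deferred volume earns the committed-emission
factor per m³ (0.5506 coastal / 0.5168 interior); deferred private-
industrial volume is additionally converted to deferred clearcut area
(baseline clearcut area ÷ baseline industrial volume) which accrues the
rotation-extension sequestration gain ΔC_seq — 108.16 ± 21.17 Mg CO₂e ha⁻¹
coastal, 30.04 ± 18.03 interior — amortized as ΔC_seq/30 per hectare per
year on the cumulative deferred area. The printed ΔC_seq values are
30-year per-hectare totals; the amortization conserves them exactly over a
30-year extension. Whether the gain should apply to the full cumulative
deferred area or only post-rotation-age stands is not resolvable from the
source material; the amortized-cumulative rule is our assumption.

**Agricultural activities.** Cover crops and no-till are stock-type: the
benefit is (enrolled area above baseline) × a per-hectare soil-carbon rate
(normal 1.17 ± 0.29 and uniform 0.12–0.53 Mg CO₂e ha⁻¹ yr⁻¹ respectively).
Nutrient management converts "reduce N use by X% on Y% of acres" into
ΔN = baseline N × eligible fraction (40% of cropland) × scheduled reduction,
and credits ΔN × EF × 44/28 × 298 with the total N₂O emission factor drawn
uniformly from 1–2.54%. The 44/28 step reflects the default `n2o_n`
convention (IPCC Tier 1 EFs are N₂O-N per unit N); a `n2o_direct`
convention without the mass conversion is selectable because the source
text does not state which was applied.

**Restoration.** Annual enrollment above baseline accumulates cohorts whose
per-hectare rates persist through 2050; cumulative enrolled area (baseline
plus scenario) is clamped at the activity's opportunity cap (tidal 5205 ha;
riparian 76,635 ha east / 125,780 ha west; sagebrush 906,000 ha). Once a
cap binds, no further area enrolls on either path, and the credit is the
flux difference between the capped scenario and baseline ledgers. Riparian
rates (12.17 ± 0.43 interior, 15.81 ± 0.45 coastal) are treated as constant
annual per-hectare rates, appropriate because they were already averaged
over stand ages 0–30 — the simulation length.

Post-fire replanting is age-dependent. The planted stand follows a
two-segment growth curve rising linearly from zero to a productivity-class
peak rate at 35 years (canopy closure) and holding; natural regeneration
follows the same curve lagged by the 10-year regeneration delay. The
credit per cohort hectare at age *a* is planted(a) − natural(a): the full
planted rate within the delay window, a constant lag difference afterwards.
Burned area available for replanting is redrawn each simulation year per
productivity class (interannual fire variability), shared between scenario
and baseline paths; the replanted proportion (uniform 9–12%) and a ±20%
per-class rate multiplier are drawn once per iteration. Scenario replanting
fractions are clamped at 100% of burned area.

## Sampling and summaries

Per-unit rates are drawn **once per iteration** and held across years
(default), keeping year-to-year trajectories coherent within an iteration;
a per-year redraw mode is available for sensitivity analysis (under it
cohort fluxes apply the current-year rate to all standing cohorts). Normal
draws are *not* truncated at zero: truncation would bias medians relative
to the published means the distributions are calibrated to; a
`truncate_at_zero` flag exists per distribution for users who prefer
otherwise. (Burned area, a physical area, is clamped at zero.)
Percentiles use linear interpolation between order statistics — the choice
matters for CI endpoints at n = 1000 and is applied consistently in
`summarize` and the aggregation step. Cumulative series are accumulated
within each iteration and then summarized, because quantiles are not
additive.

## Scenario schedules

Schedules are lists of (year, level) anchors interpolated linearly from
(2020, 0); levels hold after the last anchor. Step interpolation is
available per schedule for sensitivity checks. The three shipped scenarios
follow the published verbal descriptions; two cells of the source schedule
table are internally inconsistent (sagebrush activities quoting one percent
change and a contradictory absolute rate) and are encoded by their
percent-change readings, noted inline in the bundle. Per-activity level
orderings between scenarios are not globally monotone in the source
schedules (tidal restoration ramps faster mid-horizon under Moderate than
Ambitious); the monotonicity that is asserted — and holds — is of the
median *total* annual reduction (ambitious ≥ moderate ≥ limited from 2025).

## Oregon fixture: assumed entries

Several inputs behind the original assessment are not published. They were
fixed once, from the public record, tagged `assumed: true` in
`data/oregon.yaml`, and are deliberate entry points for sensitivity sweeps:

| entry | value | rationale |
|---|---|---|
| MBF→m³ factor | 5.66 | Scribner log-scale conversion (~5 bf per ft³) typical of PNW sawtimber; Oregon harvest statistics are log-scale, so the lumber-tally 2.36 would understate volume ≈2.4× |
| harvest region split | 80% coastal / 20% interior | westside dominance of eligible-county harvest |
| ownership shares | 72 / 9.3 / 9.2 / 7.0 / 2.5 % | published shares for industrial, non-industrial, federal; state/local split assumed |
| Limited-scenario deferment CVs | 10 / 35 / 25 / 80 / 50 % | historical harvest variability by ownership; leaves ~79% of baseline harvest, matching the "no less than ~80%" constraint |
| industrial clearcut area | 50,000 ha yr⁻¹ | forest-change-derived clearcut extent in eligible counties |
| forest pools / gross growth | see bundle | representative regional private-land inventory stocks; committed emissions land at 385 (urban) / 192 (rural) Mg CO₂e ha⁻¹, inside the reported 125–400 range |
| replanting classes | burned 20k/14k/6k ± 50% ha yr⁻¹; peaks 3.5/7/10.5 Mg CO₂e ha⁻¹ yr⁻¹ | federal moderate/high-severity burned area by productivity class and yield-table peak increments |

## Problem sizes

Simulations run 1000 iterations per scenario (the conventional choice for this analysis); the
engine-verification test against the synthetic closed-form oracle uses
10,000 iterations for the 3-standard-error normal-rate check and exact
comparison for point rates. A full three-scenario Oregon run completes in
a few seconds on one CPU.

## What the synthetic generator does and does not emulate

`generate_synthetic_bundle` produces bundles with the same structural
shapes as the fixture — stock, cohort (optionally capped), and avoided-
conversion activities under single-anchor linear ramps — with rates whose
expected totals have closed forms computed by independent year-by-year
summation. Passing the oracle tests demonstrates that the engine's
scheduling, cohort accumulation, cap clamping, and aggregation are correct.
It does not exercise the deferred-harvest constraint machinery, the
age-dependent replanting kernel, or multi-anchor schedules (those are
covered by targeted unit tests), and it says nothing about whether the
fixture's parameter values describe any real landscape.

## Known limitations

- Activities are sampled independently; correlated uncertainty (e.g. shared
  productivity drivers between riparian and harvest models) is not modeled.
- No leakage: deferred harvest is not allowed to shift out of region, and
  wood-product substitution is excluded by design.
- Wildfire interacts with the models only through replanting burned-area
  draws; elevated-stock fire risk from deferral is handled upstream by the
  fixture's county eligibility and not modeled here.
- The tidal benefit distribution (8.84 ± 3.92 Mg CO₂e ha⁻¹ yr⁻¹) combines
  sequestration and avoided methane as published; it is not recomputed from
  CH₄ mass because the implied CH₄ GWP in the source is nonstandard.
- Committed-emission factors for harvest are treated as fixed constants;
  only ΔC_seq carries sampling uncertainty, so deferred-harvest CIs are
  narrow relative to activities with uncertain per-unit rates.
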