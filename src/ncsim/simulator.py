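"""Monte Carlo orchestration across activities, years, and iterations.

For each iteration the per-unit rates of every activity are drawn once
(default; a per-year redraw mode exists) from independent seeded substreams,
the scenario schedules are evaluated year by year from 2020 to 2050, and
each activity's annual GHG reduction relative to the baseline is recorded.
Summaries report the median and empirical 90% CI across iterations;
cumulative series are accumulated within each iteration before summarizing
because quantiles are not additive.

Random-stream layout: one substream per (activity, iteration), keyed by a
CRC-32 of the activity id, so adding or removing an activity never perturbs
the draws of the others and results are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .avoided_conversion import avoided_conversion_annual_benefit
from .bundle import ParameterBundle
from .errors import BundleValidationError, InvalidQuantityError
from .land_management import harvest_committed_emissions, per_area_rate_benefit
from .restoration import replanting_delta_seq, stand_growth_rate
from .sampling import draw
from .scenarios import END_YEAR, START_YEAR, Scenario, enforce_harvest_constraints
from .units import n_to_n2o_co2e

__all__ = ["SimulationResult", "run", "aggregate", "simulation_years"]


def simulation_years() -> np.ndarray:
    """Calendar years of the simulation horizon (2020..2050 inclusive)."""
    return np.arange(START_YEAR, END_YEAR + 1)


def _activity_rng(seed: int, activity_id: str, iteration: int) -> np.random.Generator:
    key = zlib.crc32(activity_id.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), key, int(iteration)]))


def _rate_vector(spec, n_years: int, rng, redraw: bool):
    """One rate draw held for the whole iteration, or one per year."""
    if redraw:
        return draw(spec, n_years, rng)
    return draw(spec, 1, rng)[0]


def capped_cumulative_enrollment(requested: np.ndarray, cap: float) -> np.ndarray:
    """Cumulative enrolled area when annual requests clamp at ``cap``.

    Equivalent to enrolling year by year through a CohortLedger with the
    same cap (requests are nonnegative, so clamping the running total and
    clamping each request agree).
    """
    return np.minimum(np.cumsum(requested), cap)


# ---------------------------------------------------------------------------
# per-activity simulation kernels (one iteration each, vectorized over years)


def _avoided_series(params, levels, n_years, rng, redraw):
    one_time = _rate_vector(params.one_time, n_years, rng, redraw)
    ongoing = _rate_vector(params.ongoing, n_years, rng, redraw)
    baseline = params.baseline_conversion_rate
    scenario_rate = np.maximum(baseline * (1.0 + levels), 0.0)
    new_avoided = np.clip(baseline - scenario_rate, 0.0, None)
    cum_avoided = np.cumsum(new_avoided)
    return avoided_conversion_annual_benefit(new_avoided, cum_avoided, one_time, ongoing)


def _per_area_series(params, levels, n_years, rng, redraw):
    rate = _rate_vector(params.rate, n_years, rng, redraw)
    extra = np.clip(params.baseline_area_ha * levels, 0.0, None)
    return per_area_rate_benefit(extra, rate)


def _cohort_series(params, levels, n_years, rng, redraw):
    """Restoration-type activity: benefit of scenario enrollment over the
    baseline enrollment path, both honoring the same cumulative-area cap."""
    rate = _rate_vector(params.rate, n_years, rng, redraw)
    baseline = params.baseline_rate_ha
    scen_requests = np.maximum(baseline * (1.0 + levels), 0.0)
    base_requests = np.full(n_years, baseline)
    cum_scen = capped_cumulative_enrollment(scen_requests, params.cap_ha)
    cum_base = capped_cumulative_enrollment(base_requests, params.cap_ha)
    return (cum_scen - cum_base) * rate


def _nutrient_flux(delta_n, ef, convention):
    """Avoided N2O in CO2e for per-draw EF values (scalar or per-year)."""
    ef = np.asarray(ef, dtype=float)
    if ef.ndim == 0:
        return n_to_n2o_co2e(delta_n, float(ef), convention=convention)
    # per-year redraw: apply the unit conversion per element
    unit = n_to_n2o_co2e(1.0, 1.0, convention=convention)
    return np.asarray(delta_n, dtype=float) * ef * unit


def _replanting_series(params, levels, n_years, rng, redraw):
    """Post-fire replanting: age-dependent cohort credit via convolution.

    Burned area is redrawn every year (interannual fire variability) with
    draws shared between the scenario and baseline paths; the replanting
    proportion and per-class rate multipliers are drawn once per iteration.
    """
    p_base = draw(params.p_replanted, 1, rng)[0]
    delay = params.natural_regen_delay
    ages = np.arange(n_years)
    total = np.zeros(n_years)
    for name in sorted(params.classes):
        cls = params.classes[name]
        mult = rng.normal(1.0, cls["rate_rel_sd"]) if cls["rate_rel_sd"] > 0 else 1.0
        burned = np.clip(draw(cls["burned_area"], n_years, rng), 0.0, None)
        kernel_unit = np.array(
            [
                replanting_delta_seq(
                    a,
                    stand_growth_rate(a, 1.0, params.ramp_age),
                    stand_growth_rate(a - delay, 1.0, params.ramp_age),
                    delay,
                )
                for a in ages
            ]
        )
        kernel = kernel_unit * cls["peak_rate"] * mult
        scen_frac = np.minimum(p_base * (1.0 + levels), 1.0)
        scen_area = scen_frac * burned
        base_area = p_base * burned
        total += np.convolve(scen_area - base_area, kernel)[:n_years]
    return total


def _deferred_series(params, deferment, n_years, rng, redraw):
    """Deferred harvest: avoided committed emissions plus amortized
    sequestration gain on cumulative deferred industrial clearcut area."""
    dcseq = {
        region: _rate_vector(spec, n_years, rng, redraw)
        for region, spec in sorted(params.delta_c_seq.items())
    }
    split_c = params.region_split_coastal
    total_deferred = np.zeros(n_years)
    for ownership, frac in deferment.items():
        total_deferred += params.ownership_shares[ownership] * params.baseline_volume_m3 * frac
    committed = split_c * harvest_committed_emissions(total_deferred, "coastal") + (
        1.0 - split_c
    ) * harvest_committed_emissions(total_deferred, "interior")
    industrial_deferred = (
        params.ownership_shares["private_industrial"]
        * params.baseline_volume_m3
        * deferment["private_industrial"]
    )
    clearcut_area = industrial_deferred * params.clearcut_area_per_volume
    cum_area = np.cumsum(clearcut_area)
    seq = cum_area * split_c * dcseq["coastal"] / params.amortization_years
    seq += cum_area * (1.0 - split_c) * dcseq["interior"] / params.amortization_years
    return committed + seq


# ---------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Per-iteration draws plus the reported summary series.

    ``draws`` has shape (n_iter, n_activities, n_years) in Mg CO2e yr-1.
    Summary frames carry median / ci_lo / ci_hi columns (90% CI).
    ``shares`` is each activity's percent of the final-year cumulative
    median (normalized over activity medians, summing to 100).
    """

    scenario_name: str
    years: np.ndarray
    activity_ids: list
    draws: np.ndarray
    n_iter: int
    seed: int
    totals_annual: pd.DataFrame = field(default=None, repr=False)
    totals_cumulative: pd.DataFrame = field(default=None, repr=False)
    per_activity_annual: pd.DataFrame = field(default=None, repr=False)
    per_activity_cumulative: pd.DataFrame = field(default=None, repr=False)
    shares: pd.Series = field(default=None, repr=False)

    def median_annual_total(self, year: int) -> float:
        """Median total annual reduction (Mg CO2e yr-1) in ``year``."""
        row = self.totals_annual.loc[self.totals_annual["year"] == year]
        if row.empty:
            raise InvalidQuantityError(f"year {year} outside simulated horizon")
        return float(row["median"].iloc[0])

    def median_cumulative_total(self, year: int) -> float:
        row = self.totals_cumulative.loc[self.totals_cumulative["year"] == year]
        if row.empty:
            raise InvalidQuantityError(f"year {year} outside simulated horizon")
        return float(row["median"].iloc[0])

    def write_csvs(self, outdir) -> None:
        """Write annual.csv, cumulative.csv, by_activity.csv under ``outdir``."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.totals_annual.to_csv(out / "annual.csv", index=False)
        self.totals_cumulative.to_csv(out / "cumulative.csv", index=False)
        by_activity = pd.concat(
            [
                self.per_activity_annual.assign(series="annual"),
                self.per_activity_cumulative.assign(series="cumulative"),
            ],
            ignore_index=True,
        )
        by_activity.to_csv(out / "by_activity.csv", index=False)


def _summary_frame(draws_2d: np.ndarray, years: np.ndarray, scenario: str) -> pd.DataFrame:
    lo, med, hi = np.percentile(draws_2d, [5.0, 50.0, 95.0], axis=0, method="linear")
    return pd.DataFrame(
        {
            "scenario": scenario,
            "year": years,
            "median": med,
            "ci_lo": lo,
            "ci_hi": hi,
        }
    )


def aggregate(
    draws: np.ndarray,
    years: np.ndarray,
    activity_ids,
    scenario_name: str,
    n_iter: int,
    seed: int,
) -> SimulationResult:
    """Summarize raw draws into the reported annual/cumulative series.

    Cumulative totals are accumulated within each iteration and then
    summarized across iterations.
    """
    if draws.ndim != 3:
        raise InvalidQuantityError("draws must have shape (n_iter, n_activities, n_years)")
    totals = draws.sum(axis=1)  # (n_iter, n_years)
    cum_totals = np.cumsum(totals, axis=1)
    cum_by_activity = np.cumsum(draws, axis=2)

    per_annual = []
    per_cum = []
    for ai, aid in enumerate(activity_ids):
        per_annual.append(_summary_frame(draws[:, ai, :], years, scenario_name).assign(activity=aid))
        per_cum.append(
            _summary_frame(cum_by_activity[:, ai, :], years, scenario_name).assign(activity=aid)
        )
    per_activity_annual = pd.concat(per_annual, ignore_index=True)
    per_activity_cumulative = pd.concat(per_cum, ignore_index=True)

    final_medians = np.median(cum_by_activity[:, :, -1], axis=0)
    total_final = final_medians.sum()
    shares = pd.Series(
        100.0 * final_medians / total_final if total_final != 0 else np.nan,
        index=list(activity_ids),
        name="share_pct",
    )

    return SimulationResult(
        scenario_name=scenario_name,
        years=years,
        activity_ids=list(activity_ids),
        draws=draws,
        n_iter=n_iter,
        seed=seed,
        totals_annual=_summary_frame(totals, years, scenario_name),
        totals_cumulative=_summary_frame(cum_totals, years, scenario_name),
        per_activity_annual=per_activity_annual,
        per_activity_cumulative=per_activity_cumulative,
        shares=shares,
    )


def constrained_deferment_levels(bundle: ParameterBundle, scenario: Scenario, years) -> dict:
    """Per-ownership deferment fractions after the harvest constraints.

    Applies the industrial cap and the overall harvest floor year by year.
    """
    params = bundle.deferred_harvest
    raw = scenario.deferment_levels(years)
    n_years = len(years)
    out = {o: np.empty(n_years) for o in raw}
    for i in range(n_years):
        clamped = enforce_harvest_constraints(
            {o: arr[i] for o, arr in raw.items()},
            params.ownership_shares,
            industrial_cap=params.industrial_deferment_cap,
            overall_floor=params.harvest_floor_overall,
        )
        for o, v in clamped.items():
            out[o][i] = v
    return out


def run(
    bundle: ParameterBundle,
    scenario,
    n_iter: int = 1000,
    seed: int = 0,
    redraw_each_year: bool = False,
) -> SimulationResult:
    """Run the Monte Carlo simulation for one scenario.

    Parameters
    ----------
    bundle:
        Validated parameter bundle.
    scenario:
        Scenario name (looked up in the bundle) or a :class:`Scenario`.
    n_iter:
        Monte Carlo iterations (1000 by convention).
    seed:
        Master seed; identical inputs and seed give bit-identical results.
    redraw_each_year:
        If true, per-unit rates are redrawn every simulation year instead
        of once per iteration (sensitivity mode; under it, cohort fluxes
        apply the current-year rate to all standing cohorts).
    """
    if n_iter < 1:
        raise InvalidQuantityError(f"n_iter must be >= 1, got {n_iter!r}")
    bundle.validate()
    scen = bundle.scenario(scenario)
    scen.validate_against(bundle.schedule_ids)
    if bundle.deferred_harvest is not None and not scen.deferment:
        raise BundleValidationError(
            f"scenario {scen.name!r} lacks harvest deferment schedules"
        )

    years = simulation_years()
    n_years = len(years)
    levels = {aid: scen.schedules[aid].levels(years) for aid in bundle.schedule_ids}
    deferment = (
        constrained_deferment_levels(bundle, scen, years)
        if bundle.deferred_harvest is not None
        else None
    )

    activity_ids = bundle.activity_ids
    draws_out = np.zeros((n_iter, len(activity_ids), n_years))

    for it in range(n_iter):
        for ai, aid in enumerate(activity_ids):
            rng = _activity_rng(seed, aid, it)
            if aid in bundle.avoided_conversion:
                series = _avoided_series(
                    bundle.avoided_conversion[aid], levels[aid], n_years, rng, redraw_each_year
                )
            elif aid == "deferred_harvest":
                series = _deferred_series(
                    bundle.deferred_harvest, deferment, n_years, rng, redraw_each_year
                )
            elif aid in bundle.per_area:
                series = _per_area_series(
                    bundle.per_area[aid], levels[aid], n_years, rng, redraw_each_year
                )
            elif aid == "nutrient":
                ef = _rate_vector(bundle.nutrient.ef, n_years, rng, redraw_each_year)
                delta_n = (
                    bundle.nutrient.baseline_n_mg
                    * bundle.nutrient.eligible_fraction
                    * np.clip(-levels[aid], 0.0, None)
                )
                series = _nutrient_flux(delta_n, ef, bundle.nutrient.convention)
            elif aid == "replanting":
                series = _replanting_series(
                    bundle.replanting, levels[aid], n_years, rng, redraw_each_year
                )
            else:  # cohort restoration activity
                series = _cohort_series(
                    bundle.cohort[aid], levels[aid], n_years, rng, redraw_each_year
                )
            draws_out[it, ai] = series

    return aggregate(draws_out, years, activity_ids, scen.name, n_iter, seed)
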