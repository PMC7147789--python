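"""Synthetic parameter bundles with analytically known expected totals.

The generator builds random but simple bundles of the same shape as the
shipped fixture -- per-area (stock) activities, cohort restoration
activities with optional area caps, and avoided-conversion activities with
one-time plus ongoing components -- each driven by a single-anchor linear
ramp.  Because every benefit is linear in its drawn rate, the expected
annual total has a closed form: direct summation of expected rate times
scheduled area.  That summation is performed here with plain year-by-year
loops, independent of the simulator's vectorized path, so it serves as a
brute-force oracle for engine verification.
"""

from __future__ import annotations

import math

import numpy as np

from .bundle import (
    CohortActivityParams,
    ParameterBundle,
    PerAreaParams,
)
from .avoided_conversion import AvoidedConversionParams
from .errors import InvalidQuantityError
from .sampling import DistributionSpec
from .scenarios import END_YEAR, START_YEAR, Scenario, ScenarioSchedule
from .units import EmissionFactors

__all__ = ["generate_synthetic_bundle", "expected_totals"]

_YEARS = list(range(START_YEAR, END_YEAR + 1))


def _ramp_level(year: int, anchor_year: int, target: float) -> float:
    """Linear ramp from (start, 0) to (anchor_year, target), then hold."""
    if year >= anchor_year:
        return target
    return target * (year - START_YEAR) / (anchor_year - START_YEAR)


def expected_totals(spec: dict) -> dict:
    """Closed-form expected annual and cumulative totals for a synthetic
    bundle description (as returned by :func:`generate_synthetic_bundle`).

    Uses direct summation of expected-rate x scheduled-area, with explicit
    year-by-year cap clamping for cohort activities.
    """
    per_activity = {}
    for aid, a in spec["activities"].items():
        series = []
        if a["kind"] == "per_area":
            for y in _YEARS:
                level = _ramp_level(y, a["anchor_year"], a["target_level"])
                series.append(max(a["baseline"] * level, 0.0) * a["rate_mean"])
        elif a["kind"] == "cohort":
            cum_s = cum_b = 0.0
            for y in _YEARS:
                level = _ramp_level(y, a["anchor_year"], a["target_level"])
                req_s = max(a["baseline"] * (1.0 + level), 0.0)
                cum_s = min(cum_s + req_s, a["cap"])
                cum_b = min(cum_b + a["baseline"], a["cap"])
                series.append((cum_s - cum_b) * a["rate_mean"])
        elif a["kind"] == "avoided":
            cum = 0.0
            for y in _YEARS:
                level = _ramp_level(y, a["anchor_year"], a["target_level"])
                new = a["baseline"] - max(a["baseline"] * (1.0 + level), 0.0)
                new = max(new, 0.0)
                cum += new
                series.append(new * a["one_time_mean"] + cum * a["ongoing_mean"])
        else:
            raise InvalidQuantityError(f"unknown synthetic activity kind {a['kind']!r}")
        per_activity[aid] = np.array(series)
    annual = np.sum(list(per_activity.values()), axis=0)
    return {
        "years": np.array(_YEARS),
        "per_activity": per_activity,
        "annual": annual,
        "cumulative": np.cumsum(annual),
    }


def generate_synthetic_bundle(
    n_activities: int,
    seed: int,
    families=("point", "normal"),
) -> tuple:
    """Generate a random synthetic bundle and its analytic expectations.

    Returns ``(bundle, expectations)`` where ``expectations`` carries the
    closed-form expected annual and cumulative totals per year (computed by
    :func:`expected_totals`, independent of the simulator).  Identical seed
    and arguments give an identical bundle.
    """
    if n_activities < 1:
        raise InvalidQuantityError(f"n_activities must be >= 1, got {n_activities!r}")
    rng = np.random.default_rng(np.random.SeedSequence([0x5EED, int(seed)]))
    kinds = ["cohort", "per_area", "avoided"]
    activities = {}
    avoided = {}
    per_area = {}
    cohort = {}
    schedules = {}

    def _rate_spec(mean):
        family = families[rng.integers(len(families))]
        if family == "normal":
            return DistributionSpec("normal", mean, 0.1 * abs(mean)), mean
        return DistributionSpec("point", mean), mean

    for i in range(n_activities):
        kind = kinds[i % len(kinds)]
        aid = f"synthetic_{kind}_{i}"
        baseline = float(rng.uniform(100.0, 2000.0))
        anchor_year = int(rng.integers(2025, 2046))
        if kind == "avoided":
            target = float(-rng.uniform(0.1, 1.0))
            one_time, ot_mean = _rate_spec(float(rng.uniform(10.0, 300.0)))
            ongoing, og_mean = _rate_spec(float(rng.uniform(0.0, 5.0)))
            avoided[aid] = AvoidedConversionParams(
                one_time=one_time, ongoing=ongoing, baseline_conversion_rate=baseline
            )
            activities[aid] = {
                "kind": kind,
                "baseline": baseline,
                "anchor_year": anchor_year,
                "target_level": target,
                "one_time_mean": ot_mean,
                "ongoing_mean": og_mean,
            }
        else:
            target = float(rng.uniform(0.5, 3.0))
            rate, rate_mean = _rate_spec(float(rng.uniform(0.5, 5.0)))
            if kind == "per_area":
                per_area[aid] = PerAreaParams(baseline_area_ha=baseline, rate=rate)
                cap = math.inf
            else:
                # a finite cap about half the time, sized so it can bind
                cap = (
                    float(baseline * (1.0 + target) * rng.uniform(5.0, 20.0))
                    if rng.random() < 0.5
                    else math.inf
                )
                cohort[aid] = CohortActivityParams(
                    baseline_rate_ha=baseline, rate=rate, cap_ha=cap
                )
            activities[aid] = {
                "kind": kind,
                "baseline": baseline,
                "anchor_year": anchor_year,
                "target_level": target,
                "rate_mean": rate_mean,
                "cap": cap,
            }
        schedules[aid] = ScenarioSchedule(aid, ((anchor_year, target),))

    scenario = Scenario(name="synthetic", schedules=schedules)
    bundle = ParameterBundle(
        emission_factors=EmissionFactors(),
        avoided_conversion=avoided,
        per_area=per_area,
        cohort=cohort,
        scenarios={"synthetic": scenario},
        metadata={"synthetic": True, "seed": int(seed)},
    )
    bundle.validate()
    expectations = expected_totals({"activities": activities})
    return bundle, expectations
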