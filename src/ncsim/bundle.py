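"""Parameter bundles: the structured configuration a simulation runs on.

A bundle collects everything a run needs -- emission factors, per-activity
baseline rates and per-unit flux distributions, scenario schedules, and the
state emission targets -- and is serializable to/from YAML.  The shipped
Oregon bundle (``data/oregon.yaml``) transcribes the published parameter
values; :func:`generate_synthetic_bundle` in :mod:`ncsim.synthetic` builds
bundles of the same shape with analytically known expected totals.

Forest avoided-conversion entries are stored as carbon pools plus gross
growth per region; the loader derives their per-hectare one-time and
ongoing flux distributions through the committed-emission and foregone-
sequestration models so those operations stay on the computation path.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Mapping

import yaml

from .avoided_conversion import (
    AvoidedConversionParams,
    ForestCarbonPools,
    committed_emissions_forest,
    foregone_sequestration,
)
from .errors import BundleValidationError
from .land_management import OWNERSHIPS, DeferredHarvestParams
from .restoration import ReplantingParams
from .sampling import DistributionSpec
from .scenarios import Scenario, ScenarioSchedule
from .units import EmissionFactors, mbf_to_m3

__all__ = [
    "PerAreaParams",
    "CohortActivityParams",
    "NutrientParams",
    "StateTargets",
    "ParameterBundle",
    "load_bundle",
    "load_oregon_bundle",
    "bundle_sha256",
]


@dataclass(frozen=True)
class PerAreaParams:
    """A stock-type activity: benefit = (area above baseline) x rate."""

    baseline_area_ha: float
    rate: DistributionSpec  # Mg CO2e ha-1 yr-1


@dataclass(frozen=True)
class CohortActivityParams:
    """A restoration-type activity: annual enrollment accumulates cohorts."""

    baseline_rate_ha: float  # ha yr-1 enrolled under the baseline
    rate: DistributionSpec  # Mg CO2e ha-1 yr-1 per enrolled hectare
    cap_ha: float = math.inf  # maximum cumulative enrolled area


@dataclass(frozen=True)
class NutrientParams:
    """Cropland nutrient management (N2O pathway)."""

    baseline_n_mg: float  # Mg N yr-1 applied statewide
    eligible_fraction: float  # fraction of cropland where reductions apply
    ef: DistributionSpec  # total N2O emission factor (fraction of applied N)
    convention: str = "n2o_n"


@dataclass(frozen=True)
class StateTargets:
    """Statutory emission reference and targets (MMT CO2e)."""

    reference_emissions_2017: float
    target_2035: float
    target_2050: float

    def __post_init__(self) -> None:
        if not (
            self.target_2035 < self.reference_emissions_2017
            and self.target_2050 < self.reference_emissions_2017
        ):
            raise BundleValidationError("targets must be below the reference emissions")


@dataclass
class ParameterBundle:
    """All inputs for a simulation run."""

    emission_factors: EmissionFactors
    avoided_conversion: dict = field(default_factory=dict)  # id -> AvoidedConversionParams
    per_area: dict = field(default_factory=dict)  # id -> PerAreaParams
    cohort: dict = field(default_factory=dict)  # id -> CohortActivityParams
    deferred_harvest: DeferredHarvestParams | None = None
    nutrient: NutrientParams | None = None
    replanting: ReplantingParams | None = None
    scenarios: dict = field(default_factory=dict)  # name -> Scenario
    targets: StateTargets | None = None
    metadata: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict, repr=False)  # source document, for hashing

    @property
    def activity_ids(self) -> list:
        """Canonical ordering of modeled activities (sorted within groups,
        so it does not depend on document key order)."""
        ids = sorted(self.avoided_conversion)
        if self.deferred_harvest is not None:
            ids.append("deferred_harvest")
        ids.extend(sorted(self.per_area))
        if self.nutrient is not None:
            ids.append("nutrient")
        if self.replanting is not None:
            ids.append("replanting")
        ids.extend(sorted(self.cohort))
        return ids

    @property
    def schedule_ids(self) -> list:
        """Activities that carry a rate schedule (deferred harvest is driven
        by per-ownership deferment schedules instead)."""
        return [a for a in self.activity_ids if a != "deferred_harvest"]

    def validate(self) -> None:
        for name, scenario in self.scenarios.items():
            scenario.validate_against(
                self.schedule_ids,
                ownerships=OWNERSHIPS if self.deferred_harvest is not None else (),
            )

    def scenario(self, name) -> Scenario:
        if isinstance(name, Scenario):
            return name
        try:
            return self.scenarios[name]
        except KeyError:
            raise BundleValidationError(
                f"unknown scenario {name!r}; bundle defines {sorted(self.scenarios)}"
            ) from None


def _dist(data: Mapping) -> DistributionSpec:
    try:
        return DistributionSpec.from_dict(data)
    except (KeyError, TypeError) as exc:
        raise BundleValidationError(f"malformed distribution {data!r}: {exc}") from exc


def _forest_params(entry: Mapping, factors: EmissionFactors) -> AvoidedConversionParams:
    """Derive per-hectare flux distributions for a forest avoided-conversion
    entry from regional carbon pools and gross growth."""
    destination = entry["destination"]
    weights = entry["region_weights"]
    rel_sd = float(entry.get("rel_sd", 0.0))
    one_time_mean = 0.0
    ongoing_mean = 0.0
    for region, weight in weights.items():
        pools = ForestCarbonPools(**entry["pools"][region])
        one_time_mean += weight * committed_emissions_forest(pools, destination, factors)
        ongoing_mean += weight * foregone_sequestration(
            float(entry["gross_growth_co2e"][region]), destination, factors
        )
    return AvoidedConversionParams(
        one_time=DistributionSpec(
            "normal", one_time_mean, rel_sd * one_time_mean, units="Mg CO2e/ha"
        ),
        ongoing=DistributionSpec(
            "normal", ongoing_mean, rel_sd * ongoing_mean, units="Mg CO2e/ha/yr"
        ),
        baseline_conversion_rate=float(entry["baseline_rate_ha"]),
    )


def _scenario_from_dict(name: str, data: Mapping) -> Scenario:
    schedules = {
        aid: ScenarioSchedule.from_dict(aid, sched)
        for aid, sched in data.get("schedules", {}).items()
    }
    deferment = {
        own: ScenarioSchedule.from_dict(own, sched)
        for own, sched in data.get("deferment", {}).items()
    }
    return Scenario(
        name=name,
        schedules=schedules,
        deferment=deferment,
        description=data.get("description", ""),
    )


def bundle_from_dict(doc: Mapping) -> ParameterBundle:
    """Build and validate a :class:`ParameterBundle` from a plain mapping
    (the YAML document structure)."""
    try:
        factors = EmissionFactors.from_dict(doc.get("emission_factors", {}))

        avoided = {}
        for aid, entry in doc.get("avoided_conversion", {}).items():
            if "pools" in entry:
                avoided[aid] = _forest_params(entry, factors)
            else:
                avoided[aid] = AvoidedConversionParams(
                    one_time=_dist(entry["one_time"]),
                    ongoing=_dist(entry["ongoing"]),
                    baseline_conversion_rate=float(entry["baseline_rate_ha"]),
                )

        lm = doc.get("land_management", {})
        deferred = None
        if "deferred_harvest" in lm:
            d = lm["deferred_harvest"]
            if "baseline_volume_m3" in d:
                volume = float(d["baseline_volume_m3"])
            else:
                volume = mbf_to_m3(float(d["baseline_volume_mbf"]), factors)
            industrial_volume = volume * float(d["ownership_shares"]["private_industrial"])
            if "clearcut_area_per_volume" in d:
                coeff = float(d["clearcut_area_per_volume"])
            else:
                coeff = float(d["baseline_clearcut_area_ha"]) / industrial_volume
            deferred = DeferredHarvestParams(
                baseline_volume_m3=volume,
                ownership_shares={k: float(v) for k, v in d["ownership_shares"].items()},
                region_split_coastal=float(d["region_split"]["coastal"]),
                clearcut_area_per_volume=coeff,
                delta_c_seq={r: _dist(s) for r, s in d["delta_c_seq"].items()},
                amortization_years=float(d.get("amortization_years", 30.0)),
                harvest_floor_overall=float(d.get("harvest_floor_overall", 0.40)),
                industrial_deferment_cap=float(d.get("industrial_deferment_cap", 0.25)),
            )

        per_area = {
            aid: PerAreaParams(
                baseline_area_ha=float(entry["baseline_area_ha"]),
                rate=_dist(entry["rate"]),
            )
            for aid, entry in lm.items()
            if aid not in ("deferred_harvest", "nutrient")
        }

        nutrient = None
        if "nutrient" in lm:
            n = lm["nutrient"]
            nutrient = NutrientParams(
                baseline_n_mg=float(n["baseline_n_mg"]),
                eligible_fraction=float(n["eligible_cropland_fraction"]),
                ef=_dist(n["ef"]),
                convention=n.get("convention", "n2o_n"),
            )

        rest = doc.get("restoration", {})
        replanting = None
        if "replanting" in rest:
            r = rest["replanting"]
            replanting = ReplantingParams(
                p_replanted=_dist(r["p_replanted"]),
                classes={
                    cname: {
                        "burned_area": _dist(c["burned_area"]),
                        "peak_rate": float(c["peak_rate"]),
                        "rate_rel_sd": float(c.get("rate_rel_sd", 0.0)),
                    }
                    for cname, c in r["classes"].items()
                },
                natural_regen_delay=int(r.get("natural_regen_delay", 10)),
                ramp_age=float(r.get("ramp_age", 35.0)),
            )

        cohort = {
            aid: CohortActivityParams(
                baseline_rate_ha=float(entry["baseline_rate_ha"]),
                rate=_dist(entry["rate"]),
                cap_ha=float(entry.get("cap_ha", math.inf)),
            )
            for aid, entry in rest.items()
            if aid != "replanting"
        }

        targets = None
        if "targets" in doc:
            t = doc["targets"]
            targets = StateTargets(
                reference_emissions_2017=float(t["reference_emissions_2017"]),
                target_2035=float(t["target_2035"]),
                target_2050=float(t["target_2050"]),
            )

        scenarios = {
            name: _scenario_from_dict(name, s)
            for name, s in doc.get("scenarios", {}).items()
        }
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, BundleValidationError):
            raise
        raise BundleValidationError(f"malformed parameter bundle: {exc!r}") from exc

    bundle = ParameterBundle(
        emission_factors=factors,
        avoided_conversion=avoided,
        per_area=per_area,
        cohort=cohort,
        deferred_harvest=deferred,
        nutrient=nutrient,
        replanting=replanting,
        scenarios=scenarios,
        targets=targets,
        metadata=doc.get("meta", {}),
        raw=dict(doc),
    )
    bundle.validate()
    return bundle


def load_bundle(path) -> ParameterBundle:
    """Load and validate a parameter bundle from a YAML file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise BundleValidationError(f"bundle file {path!r} does not contain a mapping")
    return bundle_from_dict(doc)


def load_oregon_bundle() -> ParameterBundle:
    """Load the Oregon parameter bundle shipped with the package."""
    ref = importlib.resources.files("ncsim").joinpath("data/oregon.yaml")
    doc = yaml.safe_load(ref.read_text())
    return bundle_from_dict(doc)


def bundle_sha256(bundle: ParameterBundle) -> str:
    """Content hash of the bundle's source document (for run manifests)."""
    canonical = yaml.safe_dump(bundle.raw, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()
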