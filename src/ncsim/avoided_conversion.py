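"""Flux models for avoided-conversion activities.

Avoiding conversion of an intact ecosystem (forest, sagebrush-steppe,
grassland) yields two benefit components per hectare:

- a one-time *committed emission* avoided in the year conversion would have
  happened (carbon stocks that would be emitted within ~20 years of the
  conversion event, booked at the event year), and
- an ongoing *foregone sequestration* avoided every year thereafter (annual
  uptake the converted land would no longer provide).

The ongoing component accumulates over cohorts: a hectare whose conversion
is avoided in year y keeps sequestering in every later year, so the annual
benefit scales with the cumulative avoided area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InvalidQuantityError
from .sampling import DistributionSpec
from .units import EmissionFactors

__all__ = [
    "ForestCarbonPools",
    "AvoidedConversionParams",
    "committed_emissions_forest",
    "foregone_sequestration",
    "sagebrush_conversion_rate",
    "avoided_conversion_annual_benefit",
]


@dataclass(frozen=True)
class ForestCarbonPools:
    """Pre-conversion forest carbon stocks (Mg C ha-1) and gross growth.

    ``agb``/``bgb``/``litter``/``wd`` are the aboveground biomass,
    belowground biomass, litter, and woody debris pools.  ``gross_growth``
    is annual gross growth already expressed in Mg CO2e ha-1 yr-1.  Soil
    organic matter is deliberately excluded (its response to conversion is
    too uncertain to book).
    """

    agb: float
    bgb: float
    litter: float
    wd: float
    gross_growth: float = 0.0

    def __post_init__(self) -> None:
        for name in ("agb", "bgb", "litter", "wd", "gross_growth"):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0.0:
                raise InvalidQuantityError(
                    f"ForestCarbonPools.{name} must be finite and >= 0, got {value!r}"
                )


@dataclass(frozen=True)
class AvoidedConversionParams:
    """One avoided-conversion activity: per-hectare flux distributions and
    the baseline conversion rate the scenarios act on."""

    one_time: DistributionSpec  # Mg CO2e ha-1, committed emissions avoided
    ongoing: DistributionSpec  # Mg CO2e ha-1 yr-1, foregone sequestration avoided
    baseline_conversion_rate: float  # ha yr-1

    def __post_init__(self) -> None:
        if not np.isfinite(self.baseline_conversion_rate) or self.baseline_conversion_rate < 0:
            raise InvalidQuantityError(
                "baseline_conversion_rate must be >= 0, got "
                f"{self.baseline_conversion_rate!r}"
            )


def committed_emissions_forest(
    pools: ForestCarbonPools,
    destination: str,
    factors: EmissionFactors | None = None,
) -> float:
    """Committed emissions (Mg CO2e ha-1) from converting forest.

    Urban conversion emits 54% of aboveground biomass (the remainder persists
    in wood products) plus the full belowground, litter, and woody-debris
    pools; rural (low-density/agricultural) conversion emits half of the
    urban total.  Pools are Mg C and converted to CO2e by 44/12.
    """
    factors = factors or EmissionFactors()
    if not isinstance(pools, ForestCarbonPools):
        raise InvalidQuantityError("pools must be a ForestCarbonPools instance")
    urban = (
        pools.agb * factors.agb_emission_fraction + pools.bgb + pools.litter + pools.wd
    ) * factors.co2_per_c
    if destination == "urban":
        return urban
    if destination == "rural":
        return urban * factors.rural_pool_fraction
    raise ConfigurationError(
        f"unknown destination {destination!r}; expected 'urban' or 'rural'"
    )


def foregone_sequestration(
    gross_growth, destination: str, factors: EmissionFactors | None = None
):
    """Annual sequestration lost to conversion (Mg CO2e ha-1 yr-1).

    Urban development removes 84% of forest sequestration capacity; rural
    development removes 50%.
    """
    factors = factors or EmissionFactors()
    growth = np.asarray(gross_growth, dtype=float)
    if not np.all(np.isfinite(growth)) or np.any(growth < 0.0):
        raise InvalidQuantityError(f"gross_growth must be finite and >= 0, got {gross_growth!r}")
    if destination == "urban":
        frac = factors.urban_seq_loss
    elif destination == "rural":
        frac = factors.rural_seq_loss
    else:
        raise ConfigurationError(
            f"unknown destination {destination!r}; expected 'urban' or 'rural'"
        )
    out = growth * frac
    return out if out.ndim else float(out)


def sagebrush_conversion_rate(
    burned_area_ha: float, invaded_frac_burned: float, background_frac: float
) -> float:
    """Annual sagebrush-steppe conversion to invasive annual grasses (ha yr-1).

    Post-fire invasion above the background invasion level is counted as
    conversion: burned_area x (invaded_frac_burned - background_frac).
    """
    if not np.isfinite(burned_area_ha) or burned_area_ha < 0:
        raise InvalidQuantityError(f"burned_area_ha must be >= 0, got {burned_area_ha!r}")
    for name, value in (
        ("invaded_frac_burned", invaded_frac_burned),
        ("background_frac", background_frac),
    ):
        if not np.isfinite(value) or not 0.0 <= value <= 1.0:
            raise InvalidQuantityError(f"{name} must be a fraction in [0, 1], got {value!r}")
    if background_frac > invaded_frac_burned:
        raise InvalidQuantityError(
            "background invasion fraction exceeds the post-burn invasion fraction; "
            "a negative conversion rate is undefined"
        )
    return burned_area_ha * (invaded_frac_burned - background_frac)


def avoided_conversion_annual_benefit(
    new_avoided_area, cumulative_avoided_area, one_time_draw, ongoing_draw
):
    """Annual benefit (Mg CO2e yr-1) from avoided conversion.

    new_avoided_area x one_time + cumulative_avoided_area x ongoing.
    Accepts scalars or aligned arrays (e.g. per-year series).
    """
    new = np.asarray(new_avoided_area, dtype=float)
    cum = np.asarray(cumulative_avoided_area, dtype=float)
    if np.any(new < 0.0) or np.any(cum < 0.0):
        raise InvalidQuantityError("areas must be >= 0")
    if np.any(cum < new):
        raise InvalidQuantityError(
            "cumulative_avoided_area must be >= new_avoided_area"
        )
    out = new * np.asarray(one_time_draw, dtype=float) + cum * np.asarray(
        ongoing_draw, dtype=float
    )
    return out if out.ndim else float(out)
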