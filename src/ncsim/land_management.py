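"""Flux models for deferred timber harvest and agricultural activities.

Deferred harvest has two components:

- *avoided committed emissions*: carbon that would have been emitted within
  ~20 years of harvest (unused mill residue, short-lived wood products,
  logging residue and root decay), booked in the deferral year; and
- *extra sequestration* on private industrial clearcut area left standing:
  older stands (45-75 yr) grow faster than freshly cut ones (0-30 yr), so
  each deferred-clearcut hectare gains DeltaC_seq over a 30-year extension,
  amortized here as DeltaC_seq/30 per hectare per year so the 30-year total
  per hectare equals the quoted stock difference.

The agricultural activities are simple per-area rates (cover crops, no-till)
or an N2O emission-factor pathway (nutrient management).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import ConfigurationError, InvalidQuantityError
from .sampling import DistributionSpec
from .units import EmissionFactors, n_to_n2o_co2e

__all__ = [
    "OWNERSHIPS",
    "DeferredHarvestParams",
    "harvest_committed_emissions",
    "deferred_harvest_annual_benefit",
    "per_area_rate_benefit",
    "nutrient_management_benefit",
]

#: Forest ownership classes used for harvest accounting.
OWNERSHIPS = (
    "private_industrial",
    "private_nonindustrial",
    "state",
    "federal",
    "local_tribal",
)


@dataclass(frozen=True)
class DeferredHarvestParams:
    """Deferred-harvest parameters.

    ``baseline_volume_m3`` is the statewide annual roundwood harvest in the
    counties eligible for deferral; ``ownership_shares`` partitions it and
    must sum to 1.  ``region_split_coastal`` is the coastal share of harvest
    volume (the interior share is its complement).
    ``clearcut_area_per_volume`` (ha per m3) converts deferred private
    industrial volume into deferred clearcut area for the sequestration term.
    """

    baseline_volume_m3: float
    ownership_shares: Mapping[str, float]
    region_split_coastal: float
    clearcut_area_per_volume: float
    delta_c_seq: Mapping[str, DistributionSpec]  # region -> Mg CO2e ha-1 (30-yr total)
    amortization_years: float = 30.0
    harvest_floor_overall: float = 0.40
    industrial_deferment_cap: float = 0.25

    def __post_init__(self) -> None:
        if self.baseline_volume_m3 < 0:
            raise InvalidQuantityError("baseline_volume_m3 must be >= 0")
        shares = dict(self.ownership_shares)
        unknown = set(shares) - set(OWNERSHIPS)
        if unknown:
            raise ConfigurationError(f"unknown ownerships: {sorted(unknown)}")
        total = sum(shares.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigurationError(
                f"ownership shares must sum to 1, got {total!r}"
            )
        if not 0.0 <= self.region_split_coastal <= 1.0:
            raise ConfigurationError("region_split_coastal must be in [0, 1]")
        for name in ("harvest_floor_overall", "industrial_deferment_cap"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value!r}")
        if self.clearcut_area_per_volume < 0:
            raise InvalidQuantityError("clearcut_area_per_volume must be >= 0")
        for region in ("interior", "coastal"):
            if region not in self.delta_c_seq:
                raise ConfigurationError(f"delta_c_seq missing region {region!r}")


def harvest_committed_emissions(
    roundwood_volume_m3, region: str, factors: EmissionFactors | None = None
):
    """Committed emissions (Mg CO2e) of harvesting ``roundwood_volume_m3``.

    Emitted within 20 years of harvest: unused mill residue plus retired
    short-lived products (fractions of roundwood volume), and the decaying
    fraction of logging residue and belowground biomass.  With residue ratio
    r and root:shoot ratio s, the biomass terms are r*V (residue) and
    s*(1+r)*V (roots under the whole aboveground biomass).  The volume total
    is converted to carbon by the regional specific gravity and carbon
    fraction, then to CO2e by 44/12.
    """
    f = factors or EmissionFactors()
    v = np.asarray(roundwood_volume_m3, dtype=float)
    if np.any(~np.isfinite(v)) or np.any(v < 0.0):
        raise InvalidQuantityError(
            f"roundwood_volume_m3 must be finite and >= 0, got {roundwood_volume_m3!r}"
        )
    sg = f.specific_gravity(region)  # raises ConfigurationError on bad region
    product_terms = (f.mill_residue_fraction + f.retired_products_fraction) * v
    residue = f.residue_roundwood_ratio * v
    roots = f.root_shoot_ratio * (1.0 + f.residue_roundwood_ratio) * v
    biomass_terms = f.residue_bgb_committed * (residue + roots)
    out = (product_terms + biomass_terms) * sg * f.carbon_fraction * f.co2_per_c
    return out if out.ndim else float(out)


def deferred_harvest_annual_benefit(
    deferred_volume_by_ownership: Mapping[str, float],
    deferred_clearcut_area_cumulative: Mapping[str, float],
    delta_c_seq_draws: Mapping[str, float],
    region_split_coastal: float,
    amortization_years: float = 30.0,
    factors: EmissionFactors | None = None,
) -> float:
    """Annual benefit (Mg CO2e yr-1) of one year's harvest deferral state.

    Sums avoided committed emissions over ownerships (volume split between
    coastal and interior by ``region_split_coastal``) plus the amortized
    sequestration gain on the cumulative deferred clearcut area by region.
    """
    f = factors or EmissionFactors()
    total = 0.0
    for ownership, volume in deferred_volume_by_ownership.items():
        if ownership not in OWNERSHIPS:
            raise ConfigurationError(f"unknown ownership {ownership!r}")
        if volume < 0:
            raise InvalidQuantityError(f"deferred volume for {ownership!r} must be >= 0")
        total += region_split_coastal * harvest_committed_emissions(volume, "coastal", f)
        total += (1.0 - region_split_coastal) * harvest_committed_emissions(
            volume, "interior", f
        )
    for region, area in deferred_clearcut_area_cumulative.items():
        if area < 0:
            raise InvalidQuantityError(f"cumulative area for {region!r} must be >= 0")
        total += area * delta_c_seq_draws[region] / amortization_years
    return float(total)


def per_area_rate_benefit(additional_area_cumulative, rate_draw):
    """Benefit (Mg CO2e yr-1) of enrolled area at a per-hectare annual rate.

    Used for cover crops and no-till, where ``additional_area_cumulative``
    is hectares enrolled above the baseline extent.
    """
    area = np.asarray(additional_area_cumulative, dtype=float)
    if np.any(~np.isfinite(area)) or np.any(area < 0.0):
        raise InvalidQuantityError("additional area must be finite and >= 0")
    out = area * np.asarray(rate_draw, dtype=float)
    return out if out.ndim else float(out)


def nutrient_management_benefit(
    delta_n_applied_mg,
    ef_draw: float,
    convention: str = "n2o_n",
    factors: EmissionFactors | None = None,
):
    """Avoided N2O emissions (Mg CO2e yr-1) from reducing N fertilizer.

    ``delta_n_applied_mg`` is the reduction in applied N (Mg N yr-1);
    ``ef_draw`` the sampled total emission factor.
    """
    return n_to_n2o_co2e(delta_n_applied_mg, ef_draw, convention=convention, factors=factors)
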