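"""Cohort-based sequestration models for restoration activities.

Restoration benefits accrue per enrolled hectare per year, so each year's
enrolled area is tracked as a cohort whose annual flux persists for the rest
of the simulation.  A :class:`CohortLedger` holds the cohorts and an area
cap (the total restorable opportunity, e.g. 5205 ha of high-salinity tidal
wetland); enrollment clamps at the cap rather than erroring.

Replanting after wildfire is the one activity whose per-hectare rate depends
on cohort age: replanted stands start sequestering immediately while natural
regeneration is delayed (~10 years), so the benefit of replanting is the
difference between the planted growth curve and the same curve lagged by the
regeneration delay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidQuantityError

__all__ = [
    "CohortLedger",
    "ReplantingParams",
    "enroll",
    "annual_flux",
    "replanting_delta_seq",
    "stand_growth_rate",
]


@dataclass
class CohortLedger:
    """Areas enrolled per year whose per-hectare fluxes accumulate over time.

    ``entries`` is a list of (year_enrolled, area_ha, rate_draw) tuples;
    ``cap`` bounds the cumulative enrolled area (``math.inf`` = unbounded).
    """

    cap: float = math.inf
    entries: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (self.cap >= 0.0):  # also rejects NaN
            raise InvalidQuantityError(f"cap must be >= 0, got {self.cap!r}")

    @property
    def total_area(self) -> float:
        return float(sum(area for _, area, _ in self.entries))

    def enroll(self, year: int, requested_area: float, rate_draw: float) -> float:
        """Enroll up to ``requested_area`` ha in ``year``; returns the area
        actually enrolled after clamping at the cap.  A zero request leaves
        the ledger unchanged."""
        if not np.isfinite(requested_area) or requested_area < 0.0:
            raise InvalidQuantityError(
                f"requested_area must be finite and >= 0, got {requested_area!r}"
            )
        headroom = self.cap - self.total_area
        enrolled = min(requested_area, max(headroom, 0.0))
        if enrolled > 0.0:
            self.entries.append((int(year), float(enrolled), float(rate_draw)))
        return enrolled

    def annual_flux(self, year: int, rate_fn=None) -> float:
        """Total flux (Mg CO2e yr-1) across cohorts enrolled by ``year``.

        By default each cohort contributes area x rate_draw.  ``rate_fn``
        overrides the per-cohort rate as ``rate_fn(rate_draw, age)`` with
        ``age = year - year_enrolled`` (used by replanting cohorts, whose
        marginal rate depends on stand age).
        """
        total = 0.0
        for year_enrolled, area, rate in self.entries:
            if year_enrolled <= year:
                if rate_fn is None:
                    total += area * rate
                else:
                    total += area * rate_fn(rate, year - year_enrolled)
        return total


def enroll(ledger: CohortLedger, year: int, requested_area: float, rate_draw: float):
    """Functional wrapper over :meth:`CohortLedger.enroll`.

    Returns ``(ledger, enrolled_area)``; the ledger is modified in place.
    """
    enrolled = ledger.enroll(year, requested_area, rate_draw)
    return ledger, enrolled


def annual_flux(ledger: CohortLedger, year: int, rate_fn=None) -> float:
    """Functional wrapper over :meth:`CohortLedger.annual_flux`."""
    return ledger.annual_flux(year, rate_fn=rate_fn)


@dataclass(frozen=True)
class ReplantingParams:
    """Post-wildfire replanting on federal land.

    ``p_replanted`` is the proportion of burned area available for
    replanting that is actually replanted under the baseline; per
    productivity class the annual moderate/high-severity burned area is
    drawn each simulation year and the stand sequestration curve peaks at
    ``peak_rate`` (Mg CO2e ha-1 yr-1) with relative uncertainty
    ``rate_rel_sd`` (one multiplicative draw per iteration per class).
    """

    p_replanted: "object"  # DistributionSpec; typed loosely to avoid an import cycle
    classes: dict  # name -> {"burned_area": DistributionSpec, "peak_rate": float, "rate_rel_sd": float}
    natural_regen_delay: int = 10
    ramp_age: float = 35.0

    def __post_init__(self) -> None:
        if self.natural_regen_delay < 0:
            raise InvalidQuantityError("natural_regen_delay must be >= 0")
        if self.ramp_age <= 0:
            raise InvalidQuantityError("ramp_age must be > 0")


def stand_growth_rate(age, peak_rate: float, ramp_age: float = 35.0):
    """Annual stand sequestration rate (Mg CO2e ha-1 yr-1) at ``age`` years.

    A two-segment curve: the rate climbs linearly from zero at stand
    initiation to ``peak_rate`` at ``ramp_age`` (canopy closure / peak
    increment), then holds.  Negative ages (pre-initiation) return zero.
    """
    a = np.asarray(age, dtype=float)
    out = peak_rate * np.clip(a / ramp_age, 0.0, 1.0)
    return out if out.ndim else float(out)


def replanting_delta_seq(
    years_since_fire: float,
    planted_rate: float,
    natural_rate: float,
    delay: float,
):
    """Marginal sequestration of replanting over natural regeneration.

    Within the regeneration delay window the natural term is zero (no
    natural regrowth yet), so the full planted rate is credited; afterwards
    the credit is planted minus natural.  Negative values are permitted
    after the delay (natural regrowth can, in principle, overtake).
    """
    for name, value in (
        ("planted_rate", planted_rate),
        ("natural_rate", natural_rate),
    ):
        if not np.isfinite(value) or value < 0.0:
            raise InvalidQuantityError(f"{name} must be finite and >= 0, got {value!r}")
    if years_since_fire <= delay:
        return float(planted_rate)
    return float(planted_rate - natural_rate)
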