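"""Unit and carbon-pool conversions shared by every activity model.

All conversions are linear maps on plain float magnitudes (or numpy arrays);
units are documented in field and argument names rather than enforced by a
runtime unit system.  The constants collected in :class:`EmissionFactors` are
the standard land-sector accounting factors: the CO2:C molar mass ratio
(44/12), the fraction of aboveground biomass emitted on forest conversion,
harvested-wood-product partitioning fractions, regional wood specific
gravities, and the N2O global warming potential.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace

import numpy as np

from .errors import ConfigurationError, InvalidQuantityError

__all__ = [
    "EmissionFactors",
    "c_to_co2e",
    "volume_to_carbon",
    "mbf_to_m3",
    "n_to_n2o_co2e",
]

#: Molar-mass ratio converting mass of carbon to mass of CO2.
CO2_PER_C = 44.0 / 12.0

#: Molar-mass ratio converting N2O-N to N2O.
N2O_PER_N2O_N = 44.0 / 28.0

_FRACTION_FIELDS = (
    "agb_emission_fraction",
    "rural_pool_fraction",
    "urban_seq_loss",
    "rural_seq_loss",
    "residue_bgb_committed",
    "mill_residue_fraction",
    "retired_products_fraction",
    "carbon_fraction",
)

_POSITIVE_FIELDS = (
    "co2_per_c",
    "residue_roundwood_ratio",
    "root_shoot_ratio",
    "specific_gravity_interior",
    "specific_gravity_coastal",
    "gwp_n2o",
    "n2o_n_to_n2o",
)


@dataclass(frozen=True)
class EmissionFactors:
    """Fixed emission and conversion factors.

    Fractions are dimensionless in [0, 1]; specific gravities are Mg m-3
    (oven-dry mass per green volume); ``mbf_to_m3`` converts thousand board
    feet of harvest volume to cubic metres and has no universal default --
    it must be set explicitly (board-foot log scales differ by region and
    measurement convention), so it defaults to ``None`` and raising on use.
    """

    co2_per_c: float = CO2_PER_C
    agb_emission_fraction: float = 0.54
    rural_pool_fraction: float = 0.5
    urban_seq_loss: float = 0.84
    rural_seq_loss: float = 0.50
    residue_roundwood_ratio: float = 0.25
    root_shoot_ratio: float = 0.2
    residue_bgb_committed: float = 0.56
    mill_residue_fraction: float = 0.15
    retired_products_fraction: float = 0.28
    specific_gravity_interior: float = 0.397
    specific_gravity_coastal: float = 0.423
    carbon_fraction: float = 0.5
    gwp_n2o: float = 298.0
    n2o_n_to_n2o: float = N2O_PER_N2O_N
    mbf_to_m3: float | None = None

    def __post_init__(self) -> None:
        for name in _FRACTION_FIELDS:
            value = getattr(self, name)
            if not np.isfinite(value) or not 0.0 <= value <= 1.0:
                raise ConfigurationError(
                    f"EmissionFactors.{name} must be a fraction in [0, 1], got {value!r}"
                )
        for name in _POSITIVE_FIELDS:
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0.0:
                raise ConfigurationError(
                    f"EmissionFactors.{name} must be strictly positive, got {value!r}"
                )
        if self.mbf_to_m3 is not None and (
            not np.isfinite(self.mbf_to_m3) or self.mbf_to_m3 <= 0.0
        ):
            raise ConfigurationError(
                f"EmissionFactors.mbf_to_m3 must be strictly positive, got {self.mbf_to_m3!r}"
            )

    def specific_gravity(self, region: str) -> float:
        """Wood specific gravity (Mg m-3) for ``region`` in {interior, coastal}."""
        try:
            return {
                "interior": self.specific_gravity_interior,
                "coastal": self.specific_gravity_coastal,
            }[region]
        except KeyError:
            raise ConfigurationError(
                f"unknown region {region!r}; expected 'interior' or 'coastal'"
            ) from None

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, data: dict) -> "EmissionFactors":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown emission_factors keys: {sorted(unknown)}"
            )
        return cls(**data)

    def with_overrides(self, **kwargs) -> "EmissionFactors":
        return replace(self, **kwargs)


def _require_finite(value, name: str):
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidQuantityError(f"{name} must be finite, got {value!r}")
    return arr if arr.ndim else float(arr)


def _require_nonnegative(value, name: str):
    arr = _require_finite(value, name)
    if np.any(np.asarray(arr) < 0.0):
        raise InvalidQuantityError(f"{name} must be >= 0, got {value!r}")
    return arr


def c_to_co2e(mass_c, factors: EmissionFactors | None = None):
    """Convert a carbon mass (Mg C) to CO2-equivalent mass (Mg CO2e).

    Multiplies by the molar mass ratio 44/12.  Linear and sign-preserving;
    accepts scalars or arrays.
    """
    factors = factors or EmissionFactors()
    mass_c = _require_finite(mass_c, "mass_c")
    return mass_c * factors.co2_per_c


def volume_to_carbon(volume_m3, region: str, factors: EmissionFactors | None = None):
    """Convert wood volume (m3) to carbon mass (Mg C).

    volume x specific_gravity(region) x carbon_fraction.  ``region`` is
    'interior' or 'coastal'.
    """
    factors = factors or EmissionFactors()
    volume_m3 = _require_nonnegative(volume_m3, "volume_m3")
    return volume_m3 * factors.specific_gravity(region) * factors.carbon_fraction


def mbf_to_m3(volume_mbf, factors: EmissionFactors):
    """Convert harvest volume in thousand board feet (MBF) to cubic metres.

    Raises :class:`ConfigurationError` if no conversion factor has been
    configured; there is deliberately no silent default.
    """
    if factors is None or factors.mbf_to_m3 is None:
        raise ConfigurationError(
            "mbf_to_m3 conversion factor is not configured; set "
            "EmissionFactors.mbf_to_m3 (m3 per MBF) explicitly"
        )
    volume_mbf = _require_nonnegative(volume_mbf, "volume_mbf")
    return volume_mbf * factors.mbf_to_m3


def n_to_n2o_co2e(
    delta_n_mg,
    ef: float,
    convention: str = "n2o_n",
    factors: EmissionFactors | None = None,
):
    """CO2e (Mg) from avoided N2O emissions for a nitrogen reduction.

    ``delta_n_mg`` is the reduction in applied nitrogen (Mg N); ``ef`` is the
    total emission factor (fraction of applied N emitted).  Two accounting
    conventions are supported because IPCC Tier 1 emission factors are
    expressed as N2O-N per unit N:

    - ``n2o_n``: EF yields N2O-N, converted to N2O by 44/28 before applying
      the global warming potential -> delta_n x ef x 44/28 x GWP.
    - ``n2o_direct``: EF yields N2O mass directly -> delta_n x ef x GWP.
    """
    factors = factors or EmissionFactors()
    delta_n_mg = _require_nonnegative(delta_n_mg, "delta_n_mg")
    ef = float(_require_finite(ef, "ef"))
    if not 0.0 <= ef <= 1.0:
        raise InvalidQuantityError(f"ef must be in [0, 1], got {ef!r}")
    if convention == "n2o_n":
        return delta_n_mg * ef * factors.n2o_n_to_n2o * factors.gwp_n2o
    if convention == "n2o_direct":
        return delta_n_mg * ef * factors.gwp_n2o
    raise ConfigurationError(
        f"unknown N2O convention {convention!r}; expected 'n2o_n' or 'n2o_direct'"
    )
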