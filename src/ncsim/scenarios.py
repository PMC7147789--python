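"""Scenario schedules: per-year activity levels with ramps and constraints.

Implementation scenarios are expressed as percent change from each
activity's baseline rate, reached through ramps rather than step changes.
A :class:`ScenarioSchedule` is a list of (year, level) anchors; the level in
any year is obtained by linear interpolation from (start_year, 0) through
the anchors, holding the last anchor's level afterwards.  Levels are signed
fractions of the baseline: -0.5 halves the rate, +2.0 triples it.

Timber harvest deferment carries two statewide constraints: annual
deferment on private industrial land may not exceed 25% of its baseline
volume, and total remaining harvest may not fall below 40% of the overall
baseline.  :func:`enforce_harvest_constraints` clamps proposed deferment
fractions to honor both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import BundleValidationError, ConfigurationError, InvalidQuantityError
from .land_management import OWNERSHIPS

__all__ = [
    "START_YEAR",
    "END_YEAR",
    "ScenarioSchedule",
    "Scenario",
    "level_at",
    "activity_rate",
    "enforce_harvest_constraints",
]

START_YEAR = 2020
END_YEAR = 2050


@dataclass(frozen=True)
class ScenarioSchedule:
    """Time path of one activity's implementation level.

    ``anchors`` is a sorted list of (year, level) pairs; ``interpolation``
    is 'linear' (default) or 'step' (level jumps to the anchor value at the
    anchor year).
    """

    activity_id: str
    anchors: tuple  # ((year, level), ...)
    interpolation: str = "linear"
    start_year: int = START_YEAR
    end_year: int = END_YEAR

    def __post_init__(self) -> None:
        object.__setattr__(self, "anchors", tuple((int(y), float(l)) for y, l in self.anchors))
        if self.interpolation not in ("linear", "step"):
            raise ConfigurationError(
                f"unknown interpolation {self.interpolation!r}; expected 'linear' or 'step'"
            )
        years = [y for y, _ in self.anchors]
        if years != sorted(years):
            raise ConfigurationError(f"anchors must be sorted by year: {self.anchors!r}")
        for y, level in self.anchors:
            if not (self.start_year <= y <= self.end_year):
                raise ConfigurationError(
                    f"anchor year {y} outside horizon [{self.start_year}, {self.end_year}]"
                )
            if not np.isfinite(level):
                raise ConfigurationError(f"anchor level must be finite, got {level!r}")

    def to_dict(self) -> dict:
        out = {"anchors": [[y, l] for y, l in self.anchors]}
        if self.interpolation != "linear":
            out["interpolation"] = self.interpolation
        return out

    @classmethod
    def from_dict(cls, activity_id: str, data: dict) -> "ScenarioSchedule":
        return cls(
            activity_id=activity_id,
            anchors=tuple((y, l) for y, l in data["anchors"]),
            interpolation=data.get("interpolation", "linear"),
        )

    def levels(self, years) -> np.ndarray:
        """Vector of levels for an array of calendar years."""
        return np.array([level_at(self, int(y)) for y in np.asarray(years)])


def level_at(schedule: ScenarioSchedule, year: int) -> float:
    """Implementation level (fraction of baseline change) in ``year``.

    Linear interpolation starts from (start_year, 0); after the last anchor
    the level is held constant.
    """
    if not (schedule.start_year <= year <= schedule.end_year):
        raise InvalidQuantityError(
            f"year {year} outside schedule horizon "
            f"[{schedule.start_year}, {schedule.end_year}]"
        )
    if not schedule.anchors:
        return 0.0
    if schedule.interpolation == "step":
        level = 0.0
        for y, l in schedule.anchors:
            if year >= y:
                level = l
        return level
    points = [(schedule.start_year, 0.0)]
    # a level anchored at start_year overrides the implicit zero start
    for y, l in schedule.anchors:
        if y == schedule.start_year:
            points = []
        points.append((y, l))
    xs = np.array([p[0] for p in points], dtype=float)
    ys = np.array([p[1] for p in points], dtype=float)
    return float(np.interp(year, xs, ys))


def activity_rate(baseline: float, level: float) -> float:
    """Scenario activity rate: baseline x (1 + level), floored at zero."""
    if not np.isfinite(baseline) or baseline < 0.0:
        raise InvalidQuantityError(f"baseline must be finite and >= 0, got {baseline!r}")
    return max(baseline * (1.0 + level), 0.0)


def enforce_harvest_constraints(
    proposed_deferment: Mapping[str, float],
    ownership_shares: Mapping[str, float],
    industrial_cap: float = 0.25,
    overall_floor: float = 0.40,
) -> dict:
    """Clamp per-ownership harvest deferment fractions to the constraints.

    The private-industrial fraction is clamped to ``industrial_cap``.  If
    the harvest remaining after all deferments would fall below
    ``overall_floor`` of the overall baseline, deferments on the other
    ownerships are scaled down proportionally until the floor holds exactly.
    Never raises for feasible shares; clamps instead.
    """
    deferment = {}
    for ownership, fraction in proposed_deferment.items():
        if ownership not in OWNERSHIPS:
            raise ConfigurationError(f"unknown ownership {ownership!r}")
        if not np.isfinite(fraction) or not 0.0 <= fraction <= 1.0:
            raise InvalidQuantityError(
                f"deferment fraction for {ownership!r} must be in [0, 1], got {fraction!r}"
            )
        deferment[ownership] = float(fraction)
    if "private_industrial" in deferment:
        deferment["private_industrial"] = min(
            deferment["private_industrial"], industrial_cap
        )
    deferred_volume = sum(
        ownership_shares.get(o, 0.0) * d for o, d in deferment.items()
    )
    remaining = 1.0 - deferred_volume
    if remaining < overall_floor - 1e-12:
        industrial = deferment.get("private_industrial", 0.0) * ownership_shares.get(
            "private_industrial", 0.0
        )
        other = deferred_volume - industrial
        # scale non-industrial deferments so the floor holds exactly
        target_other = max((1.0 - overall_floor) - industrial, 0.0)
        scale = target_other / other if other > 0.0 else 0.0
        for ownership in deferment:
            if ownership != "private_industrial":
                deferment[ownership] *= scale
    return deferment


@dataclass(frozen=True)
class Scenario:
    """A named implementation scenario.

    ``schedules`` maps rate-type activity ids to their schedules;
    ``deferment`` maps forest ownerships to schedules whose (positive)
    levels are harvest deferment fractions of that ownership's baseline.
    """

    name: str
    schedules: Mapping[str, ScenarioSchedule]
    deferment: Mapping[str, ScenarioSchedule] = field(default_factory=dict)
    description: str = ""

    def validate_against(self, activity_ids, ownerships=OWNERSHIPS) -> None:
        """Check that every modeled activity has a schedule."""
        missing = sorted(set(activity_ids) - set(self.schedules))
        if missing:
            raise BundleValidationError(
                f"scenario {self.name!r} is missing schedules for activities: {missing}"
            )
        if self.deferment:
            missing_own = sorted(set(ownerships) - set(self.deferment))
            if missing_own:
                raise BundleValidationError(
                    f"scenario {self.name!r} is missing deferment schedules for "
                    f"ownerships: {missing_own}"
                )

    def deferment_levels(self, years) -> dict:
        """Per-ownership deferment fraction arrays over ``years`` (unconstrained)."""
        return {o: s.levels(years) for o, s in self.deferment.items()}
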