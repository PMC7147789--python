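"""Seeded sampling of per-unit rates and Monte Carlo summary statistics.

Every uncertain per-unit rate in a parameter bundle is described by a
:class:`DistributionSpec` (normal, uniform, or degenerate point mass).
Draws always go through a caller-supplied ``numpy.random.Generator`` so a
single master seed makes whole simulations bit-reproducible.

Summaries follow the convention of reporting the median with an empirical
90% confidence interval (5th and 95th percentiles).  Percentiles use linear
interpolation between order statistics (numpy's default); this matters at
n = 1000 where the interval endpoints fall between order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidQuantityError

__all__ = ["DistributionSpec", "SummaryStat", "draw", "summarize"]

_FAMILIES = ("normal", "uniform", "point")


@dataclass(frozen=True)
class DistributionSpec:
    """A sampled per-unit rate.

    Parameters
    ----------
    family:
        'normal' (p1=mean, p2=sd), 'uniform' (p1=lower, p2=upper) or
        'point' (p1=value, p2 ignored).
    truncate_at_zero:
        If true, draws are clipped at zero.  Off by default: clipping a
        normal biases its median relative to the quoted mean, and the
        quoted means are what the per-unit rates are calibrated to.
    """

    family: str
    p1: float
    p2: float = 0.0
    units: str = ""
    truncate_at_zero: bool = False

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise InvalidQuantityError(
                f"unknown distribution family {self.family!r}; expected one of {_FAMILIES}"
            )
        if not (np.isfinite(self.p1) and np.isfinite(self.p2)):
            raise InvalidQuantityError(
                f"distribution parameters must be finite, got p1={self.p1!r} p2={self.p2!r}"
            )
        if self.family == "normal" and self.p2 < 0.0:
            raise InvalidQuantityError(f"normal sd must be >= 0, got {self.p2!r}")
        if self.family == "uniform" and self.p1 > self.p2:
            raise InvalidQuantityError(
                f"uniform lower bound {self.p1!r} exceeds upper bound {self.p2!r}"
            )

    @property
    def mean(self) -> float:
        """Analytic expectation of the distribution (ignoring truncation)."""
        if self.family == "uniform":
            return 0.5 * (self.p1 + self.p2)
        return self.p1

    def to_dict(self) -> dict:
        out = {"family": self.family, "p1": self.p1, "p2": self.p2, "units": self.units}
        if self.truncate_at_zero:
            out["truncate_at_zero"] = True
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "DistributionSpec":
        return cls(
            family=data["family"],
            p1=float(data["p1"]),
            p2=float(data.get("p2", 0.0)),
            units=str(data.get("units", "")),
            truncate_at_zero=bool(data.get("truncate_at_zero", False)),
        )


@dataclass(frozen=True)
class SummaryStat:
    """Median with empirical 90% confidence interval (5th/95th percentile)."""

    median: float
    ci_lo: float
    ci_hi: float
    n: int

    def __post_init__(self) -> None:
        if not (self.ci_lo <= self.median <= self.ci_hi):
            raise InvalidQuantityError(
                f"require ci_lo <= median <= ci_hi, got "
                f"({self.ci_lo!r}, {self.median!r}, {self.ci_hi!r})"
            )


def draw(spec: DistributionSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` independent samples from ``spec`` using ``rng``.

    Identical (seeded) generator state and spec give an identical sequence.
    """
    if not isinstance(spec, DistributionSpec):
        raise InvalidQuantityError(f"expected a DistributionSpec, got {type(spec).__name__}")
    if n < 1:
        raise InvalidQuantityError(f"n must be >= 1, got {n!r}")
    if spec.family == "normal":
        out = rng.normal(spec.p1, spec.p2, size=n)
    elif spec.family == "uniform":
        if spec.p1 == spec.p2:  # degenerate; rng.uniform would still work
            out = np.full(n, spec.p1)
        else:
            out = rng.uniform(spec.p1, spec.p2, size=n)
    else:  # point
        out = np.full(n, spec.p1)
    if spec.truncate_at_zero:
        out = np.clip(out, 0.0, None)
    return out


def summarize(draws) -> SummaryStat:
    """Summarize Monte Carlo draws as median and 90% CI.

    Percentiles are computed with linear interpolation between order
    statistics.  Raises on empty or non-finite input.
    """
    arr = np.asarray(draws, dtype=float).ravel()
    if arr.size == 0:
        raise InvalidQuantityError("cannot summarize an empty sequence of draws")
    if not np.all(np.isfinite(arr)):
        raise InvalidQuantityError("draws must be finite")
    lo, med, hi = np.percentile(arr, [5.0, 50.0, 95.0], method="linear")
    return SummaryStat(median=float(med), ci_lo=float(lo), ci_hi=float(hi), n=arr.size)
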