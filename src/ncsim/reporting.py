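"""Contextualize simulated reductions against statutory emission targets.

Oregon's statutory goals set statewide emissions at 33.9 MMT CO2e by 2035
and 14 MMT CO2e by 2050 against 2017 reference emissions of 64 MMT CO2e, so
the required reductions are 30.1 and 50 MMT CO2e.  This module computes the
fraction of those needed reductions that simulated NCS activity provides,
and the per-activity shares of the cumulative reduction.
"""

from __future__ import annotations

import pandas as pd

from .bundle import StateTargets
from .errors import InvalidQuantityError
from .simulator import SimulationResult

__all__ = [
    "StateTargets",
    "needed_reduction",
    "fraction_of_needed",
    "activity_shares",
    "report_frame",
    "plot_annual_totals",
]

MG_PER_MMT = 1e6


def needed_reduction(targets: StateTargets, year: int) -> float:
    """Reduction (MMT CO2e) required to move from the reference emissions
    to the statutory target for ``year`` (2035 or 2050)."""
    if year == 2035:
        return targets.reference_emissions_2017 - targets.target_2035
    if year == 2050:
        return targets.reference_emissions_2017 - targets.target_2050
    raise InvalidQuantityError(f"no statutory target defined for year {year}")


def fraction_of_needed(ncs_annual_mmt: float, needed_mmt: float) -> float:
    """Percent of the needed reduction provided by NCS (unrounded)."""
    if needed_mmt <= 0:
        raise InvalidQuantityError(f"needed reduction must be > 0, got {needed_mmt!r}")
    return 100.0 * ncs_annual_mmt / needed_mmt


def activity_shares(result: SimulationResult) -> pd.Series:
    """Percent of the final-year cumulative median contributed by each
    activity (shares over activity medians; sums to 100)."""
    shares = result.shares
    if shares is None or not shares.notna().all():
        raise InvalidQuantityError("result carries no valid activity shares (zero total?)")
    return shares


def report_frame(result: SimulationResult, targets: StateTargets) -> pd.DataFrame:
    """Tidy comparison of simulated annual reductions with the targets.

    Columns: scenario, year, ncs_median, ncs_ci_lo, ncs_ci_hi (MMT CO2e
    yr-1), needed (MMT), fraction_of_needed (percent); one row per target
    year.
    """
    rows = []
    for year in (2035, 2050):
        needed = needed_reduction(targets, year)
        annual = result.totals_annual.loc[result.totals_annual["year"] == year]
        if annual.empty:
            continue
        med = float(annual["median"].iloc[0]) / MG_PER_MMT
        rows.append(
            {
                "scenario": result.scenario_name,
                "year": year,
                "ncs_median": med,
                "ncs_ci_lo": float(annual["ci_lo"].iloc[0]) / MG_PER_MMT,
                "ncs_ci_hi": float(annual["ci_hi"].iloc[0]) / MG_PER_MMT,
                "needed": needed,
                "fraction_of_needed": fraction_of_needed(med, needed),
            }
        )
    return pd.DataFrame(rows)


def plot_annual_totals(results, path=None, bau_series=None):
    """Plot median annual reductions (MMT CO2e/yr) for one or more runs.

    ``bau_series`` is an optional user-supplied business-as-usual emission
    trajectory (mapping year -> MMT) drawn for context; none is embedded.
    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(results, SimulationResult):
        results = [results]
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for res in results:
        frame = res.totals_annual
        ax.plot(frame["year"], frame["median"] / MG_PER_MMT, label=res.scenario_name)
        ax.fill_between(
            frame["year"],
            frame["ci_lo"] / MG_PER_MMT,
            frame["ci_hi"] / MG_PER_MMT,
            alpha=0.2,
        )
    if bau_series:
        years = sorted(bau_series)
        ax.plot(years, [bau_series[y] for y in years], "k--", label="business as usual")
    ax.set_xlabel("year")
    ax.set_ylabel("annual GHG reduction (MMT CO2e / yr)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
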