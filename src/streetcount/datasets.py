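"""Bundled example datasets from a published multi-location street-count
monitoring programme.

``location_indicators``: one baseline indicator row per route for 30 routes
across seven locations (Bosnia, Serbia, Romania, Panama, Puerto Rico, Costa
Rica, Nepal) — dogs/km plus reproductive and welfare percentages.  Empty
cells are genuinely undefined indicators: one location assessed no skin
condition on a route with too few dogs, and the Kathmandu surveys scored
body condition only for emaciated dogs, leaving % BCS 1-or-2 undefined.

``density_monitoring``: repeat dogs/km survey-event averages over time for
the five locations with more than one survey event, in long format with
mid-month dates standing in for the survey months.
"""

from __future__ import annotations

import datetime as dt
from importlib import resources

import pandas as pd

__all__ = [
    "load_location_indicators",
    "load_density_monitoring",
    "load_route_series",
    "MUMBAI_SUMMARY",
]

#: Published summary of a 21-route replicated baseline survey of Mumbai
#: (January 2014): routes, SE of the mean replicate density difference,
#: mean density, mean replicate difference, and the lactating-female
#: composition counts used in the sample-size example.
MUMBAI_SUMMARY = {
    "n_routes": 21,
    "se_diff": 0.29,
    "mean_diff": 0.097,
    "baseline_mean": 10.54,
    "n_females": 3236,
    "p_lactating": 0.08,
    "p_lactating_slums": 0.11,
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("streetcount.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_location_indicators() -> pd.DataFrame:
    """Baseline indicator table: 30 routes in 7 locations (NaN = undefined)."""
    return _read("location_indicators.csv")


def load_density_monitoring() -> pd.DataFrame:
    """Long-format repeat-survey dogs/km series with parsed dates."""
    df = _read("density_monitoring.csv")
    df["survey_date"] = pd.to_datetime(df["survey_date"]).dt.date
    return df


def load_route_series(route: str) -> tuple[list[dt.date], list[float]]:
    """(dates, dogs/km) monitoring series for one named route."""
    df = load_density_monitoring()
    sub = df[df["route"] == route].sort_values("survey_date")
    if sub.empty:
        raise KeyError(f"no monitoring series for route {route!r}")
    return list(sub["survey_date"]), list(sub["dogs_per_km"])
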