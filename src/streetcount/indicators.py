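"""Per-route survey indicators: density, reproductive activity, welfare.

The monitoring index is dogs seen per km of street; alongside it the
protocol tracks the percentage of females visibly lactating (a proxy for
recent reproduction), the percentage of body-condition-scored dogs that are
emaciated (BCS 1) or emaciated/thin (BCS 1 or 2), and the percentage of
skin-assessed dogs with a visible skin condition.

Conventions
-----------
* The female denominator for % lactating is female + lactating_female +
  sterilised_female (sterilised females are identified females); set
  ``females_include_sterilised=False`` to restrict to intact females.
* Pups count towards density and the BCS/skin denominators but never
  towards the female denominator.
* A percentage whose denominator is zero is *undefined* and propagates as
  ``None`` (NaN in tabular output), never as 0 — e.g. abbreviated protocols
  that score only emaciated dogs leave % BCS 1-or-2 undefined.
* Within a survey event, density is the mean of per-replicate densities
  while composition pools raw counts across replicates (stabilising small
  counts).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .survey_io import DogClass, DogRecord, ReplicateSurvey, Route, RouteType, SkinCondition

__all__ = [
    "SurveyEvent",
    "IndicatorSet",
    "dogs_per_km",
    "event_density",
    "composition",
    "event_indicators",
    "extrapolate_total",
    "indicator_table",
]

_FEMALE_CLASSES = frozenset(
    {DogClass.FEMALE, DogClass.LACTATING_FEMALE, DogClass.STERILISED_FEMALE}
)
_INTACT_FEMALE_CLASSES = frozenset({DogClass.FEMALE, DogClass.LACTATING_FEMALE})


@dataclass
class SurveyEvent:
    """All replicates of one route at one monitoring time point.

    Replicate surveys run on (ideally consecutive) distinct days; at least
    two replicates are needed for the day-to-day variance estimate behind
    the power analysis.
    """

    route_id: str
    event_label: str
    replicates: list[ReplicateSurvey] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.replicates:
            raise ValueError(f"event {self.event_label!r} has no replicates")
        ids = {r.route_id for r in self.replicates}
        if ids != {self.route_id}:
            raise ValueError(
                f"event {self.event_label!r}: replicates reference routes {sorted(ids)}, "
                f"expected {self.route_id!r}"
            )
        dates = [r.survey_date for r in self.replicates]
        if len(set(dates)) != len(dates):
            raise ValueError(f"event {self.event_label!r} has replicates on duplicate dates")

    @property
    def records(self) -> list[DogRecord]:
        """All dog records pooled across replicates."""
        return [rec for rep in self.replicates for rec in rep.records]


@dataclass(frozen=True)
class IndicatorSet:
    """One row of the indicator table; ``None`` marks an undefined percentage."""

    dogs_per_km: Optional[float]
    pct_lactating: Optional[float]
    pct_bcs1: Optional[float]
    pct_bcs1or2: Optional[float]
    pct_skin: Optional[float]
    n_dogs: int = 0
    n_females: int = 0
    n_bcs_scored: int = 0
    n_skin_assessed: int = 0

    def __post_init__(self) -> None:
        for name in ("dogs_per_km", "pct_lactating", "pct_bcs1", "pct_bcs1or2", "pct_skin"):
            v = getattr(self, name)
            if v is None:
                continue
            if name == "dogs_per_km":
                if v < 0:
                    raise ValueError("dogs_per_km must be non-negative")
            elif not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} must lie in [0, 100], got {v!r}")
        if self.n_females > self.n_dogs:
            raise ValueError("n_females cannot exceed n_dogs")


def dogs_per_km(replicate: ReplicateSurvey, route: Route) -> float:
    """Observed dogs per kilometre of street for one replicate survey."""
    if replicate.route_id != route.route_id:
        raise ValueError(
            f"replicate is for route {replicate.route_id!r}, not {route.route_id!r}"
        )
    return len(replicate.records) / route.length_km


def event_density(event: SurveyEvent, route: Route) -> float:
    """Mean of per-replicate densities across an event's replicate surveys."""
    densities = [dogs_per_km(rep, route) for rep in event.replicates]
    return sum(densities) / len(densities)


def _pct(numer: int, denom: int) -> Optional[float]:
    return None if denom == 0 else 100.0 * numer / denom


def composition(
    records: Sequence[DogRecord],
    females_include_sterilised: bool = True,
    abbreviated_bcs: bool = False,
) -> IndicatorSet:
    """Composition and welfare percentages for a set of dog records.

    Percentages are taken over the records for which the relevant score was
    made: % lactating over identified females, % BCS over BCS-scored dogs,
    % skin over skin-assessed dogs.  Zero denominators yield undefined
    (``None``) percentages.

    ``abbreviated_bcs=True`` declares the high-workload protocol variant in
    which observers assess every dog but write down a score only for
    emaciated (BCS 1) dogs: every dog then counts in the % BCS 1
    denominator, while % BCS 1-or-2 is undefined because thin dogs were
    never distinguished.
    """
    female_classes = _FEMALE_CLASSES if females_include_sterilised else _INTACT_FEMALE_CLASSES
    n_dogs = len(records)
    n_females = sum(1 for r in records if r.dog_class in female_classes)
    n_lact = sum(1 for r in records if r.dog_class is DogClass.LACTATING_FEMALE)
    scored = [r.bcs for r in records if r.bcs is not None]
    n_bcs_scored = n_dogs if abbreviated_bcs else len(scored)
    n_skin_present = sum(1 for r in records if r.skin_condition is SkinCondition.PRESENT)
    n_skin_assessed = sum(
        1 for r in records if r.skin_condition is not SkinCondition.UNRECORDED
    )
    return IndicatorSet(
        dogs_per_km=None,
        pct_lactating=_pct(n_lact, n_females),
        pct_bcs1=_pct(sum(1 for b in scored if b == 1), n_bcs_scored),
        pct_bcs1or2=(
            None if abbreviated_bcs
            else _pct(sum(1 for b in scored if b in (1, 2)), len(scored))
        ),
        pct_skin=_pct(n_skin_present, n_skin_assessed),
        n_dogs=n_dogs,
        n_females=n_females,
        n_bcs_scored=n_bcs_scored,
        n_skin_assessed=n_skin_assessed,
    )


def event_indicators(
    event: SurveyEvent,
    route: Route,
    females_include_sterilised: bool = True,
    abbreviated_bcs: bool = False,
) -> IndicatorSet:
    """Full indicator row for one survey event.

    Density averages per-replicate densities; composition is computed on the
    records pooled across the event's replicates.
    """
    comp = composition(event.records, females_include_sterilised, abbreviated_bcs)
    return IndicatorSet(
        dogs_per_km=event_density(event, route),
        pct_lactating=comp.pct_lactating,
        pct_bcs1=comp.pct_bcs1,
        pct_bcs1or2=comp.pct_bcs1or2,
        pct_skin=comp.pct_skin,
        n_dogs=comp.n_dogs,
        n_females=comp.n_females,
        n_bcs_scored=comp.n_bcs_scored,
        n_skin_assessed=comp.n_skin_assessed,
    )


def extrapolate_total(
    mean_density: float,
    total_street_km: float,
    detectability: float = 1.0,
    route_type: RouteType | str = RouteType.REPRESENTATIVE,
) -> float:
    """Extrapolate mean density to a total roaming-dog count for an area.

    ``mean_density × total_street_km ÷ detectability``.  Valid only for
    representative routes: hotspot routes oversample high-density areas by
    construction, so extrapolating them inflates the total.
    """
    if RouteType(route_type) is RouteType.HOTSPOT:
        raise ValueError(
            "extrapolation to an area total requires representative routes; "
            "hotspot routes are deliberately non-representative"
        )
    if total_street_km <= 0:
        raise ValueError("total_street_km must be positive")
    if not (0.0 < detectability <= 1.0):
        raise ValueError("detectability must lie in (0, 1]")
    if mean_density < 0:
        raise ValueError("mean_density must be non-negative")
    return mean_density * total_street_km / detectability


_TABLE_COLUMNS = [
    "location", "route_type", "route_id", "event_label",
    "dogs_per_km", "pct_lactating", "pct_bcs1", "pct_bcs1or2", "pct_skin",
    "n_dogs", "n_females", "n_bcs_scored", "n_skin_assessed",
]


def indicator_table(
    events: Iterable[SurveyEvent],
    routes: Mapping[str, Route],
    females_include_sterilised: bool = True,
    abbreviated_bcs: bool = False,
) -> pd.DataFrame:
    """One indicator row per route per event, in the standard column order.

    Undefined percentages appear as NaN.  An empty event iterable yields an
    empty table with the standard columns.
    """
    rows = []
    for event in events:
        route = routes[event.route_id]
        ind = event_indicators(event, route, females_include_sterilised, abbreviated_bcs)
        rows.append({
            "location": route.location,
            "route_type": route.route_type.value,
            "route_id": route.route_id,
            "event_label": event.event_label,
            **{k: getattr(ind, k) for k in _TABLE_COLUMNS[4:]},
        })
    df = pd.DataFrame(rows, columns=_TABLE_COLUMNS)
    for col in _TABLE_COLUMNS[4:9]:  # None -> NaN, numeric dtype
        df[col] = pd.to_numeric(df[col])
    return df
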