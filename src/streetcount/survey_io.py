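"""Reading and writing street-survey routes and observation logs.

Routes are KML LineStrings (as exported by web mapping tools); per-replicate
observation logs are GPX 1.1 waypoint files in the event-recorder dialect
where each waypoint is one observed dog and the waypoint ``name`` is the
button label tapped by the observer.  Observations round-trip through a flat
CSV that substitutes for a field database.

All coordinates are WGS84 decimal degrees; no projection step is applied.
Route lengths are great-circle (haversine) sums on a sphere of radius
6371.0088 km — the sub-0.5 % error versus an ellipsoidal geodesic is far
below day-to-day count variation.
"""

from __future__ import annotations

import csv
import datetime as dt
import math
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from lxml import etree

__all__ = [
    "EARTH_RADIUS_KM",
    "ROUTE_LENGTH_WARNING_KM",
    "DogClass",
    "SkinCondition",
    "RouteType",
    "Route",
    "DogRecord",
    "ReplicateSurvey",
    "LabelMap",
    "RouteLengthWarning",
    "FormatError",
    "UnmappedLabelError",
    "route_length_km",
    "read_route_kml",
    "write_route_kml",
    "read_event_log_gpx",
    "write_event_log_gpx",
    "write_observations_csv",
    "read_observations_csv",
    "default_label_map",
]

#: Mean Earth radius (IUGG), kilometres.
EARTH_RADIUS_KM = 6371.0088

#: Protocol guideline: routes are usually at most 20 km (≈2 h by vehicle).
ROUTE_LENGTH_WARNING_KM = 20.0

_KML_NS = "http://www.opengis.net/kml/2.2"
_GPX_NS = "http://www.topografix.com/GPX/1/1"


class RouteLengthWarning(UserWarning):
    """A route exceeds the protocol's usual 20 km maximum (not an error)."""


class FormatError(ValueError):
    """A file does not contain what the protocol format requires."""


class UnmappedLabelError(KeyError):
    """A GPX waypoint label has no entry in the label map."""

    def __init__(self, labels: Sequence[str]):
        self.labels = sorted(set(labels))
        super().__init__(
            "waypoint label(s) not in label map: " + ", ".join(repr(l) for l in self.labels)
        )


class DogClass(str, Enum):
    """The seven gender/age classes scored during a street count."""

    MALE = "male"
    FEMALE = "female"
    LACTATING_FEMALE = "lactating_female"
    UNKNOWN_ADULT = "unknown_adult"
    PUP = "pup"  # under 4 months of age
    STERILISED_MALE = "sterilised_male"
    STERILISED_FEMALE = "sterilised_female"


class SkinCondition(str, Enum):
    """Visible skin condition assessment."""

    PRESENT = "present"
    ABSENT = "absent"
    UNRECORDED = "unrecorded"


class RouteType(str, Enum):
    """How the route was drawn.

    Representative routes are drawn blind to expected dog density and support
    extrapolation to area totals; hotspot routes deliberately bisect known
    high-density areas and are valid only for within-route trends.
    """

    REPRESENTATIVE = "representative"
    HOTSPOT = "hotspot"


def _validate_polyline(polyline: Sequence[tuple[float, float]]) -> None:
    if len(polyline) < 1:
        raise ValueError("polyline must contain at least one point")
    for i, (lat, lon) in enumerate(polyline):
        if not (-90.0 <= lat <= 90.0):
            raise ValueError(f"latitude out of range at point {i}: {lat!r}")
        if not (-180.0 <= lon <= 180.0):
            raise ValueError(f"longitude out of range at point {i}: {lon!r}")


def _haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


def route_length_km(polyline: Sequence[tuple[float, float]]) -> float:
    """Total great-circle length of a (lat, lon) polyline in kilometres.

    A single point has length 0.  Lengths beyond the protocol's usual 20 km
    maximum raise a :class:`RouteLengthWarning` but are returned unchanged.

    Raises
    ------
    ValueError
        If any coordinate is outside valid WGS84 ranges (the message names
        the offending point index).
    """
    _validate_polyline(polyline)
    total = 0.0
    for (lat1, lon1), (lat2, lon2) in zip(polyline, polyline[1:]):
        total += _haversine_km(lat1, lon1, lat2, lon2)
    if total > ROUTE_LENGTH_WARNING_KM:
        warnings.warn(
            f"route length {total:.2f} km exceeds the usual protocol maximum of "
            f"{ROUTE_LENGTH_WARNING_KM:.0f} km",
            RouteLengthWarning,
            stacklevel=2,
        )
    return total


@dataclass(frozen=True)
class Route:
    """A named survey polyline; the unit over which density is defined."""

    route_id: str
    location: str
    route_type: RouteType
    polyline: tuple[tuple[float, float], ...]
    length_km: float = field(init=False)

    def __post_init__(self) -> None:
        poly = tuple((float(a), float(b)) for a, b in self.polyline)
        if len(poly) < 2:
            raise ValueError("route polyline must have at least 2 points")
        object.__setattr__(self, "polyline", poly)
        object.__setattr__(self, "route_type", RouteType(self.route_type))
        object.__setattr__(self, "length_km", route_length_km(poly))
        if self.length_km <= 0:
            raise ValueError("route has zero length")


@dataclass(frozen=True)
class DogRecord:
    """One observed dog: class, welfare scores, and where/when it was logged.

    ``bcs`` is the 1–5 body condition score (1 = emaciated, 2 = thin) or
    ``None`` when not recorded — abbreviated protocols score only emaciated
    dogs.  ``skin_condition`` records presence/absence of a visible skin
    problem.
    """

    timestamp: dt.datetime
    point: tuple[float, float]
    dog_class: DogClass
    bcs: Optional[int] = None
    skin_condition: SkinCondition = SkinCondition.UNRECORDED

    def __post_init__(self) -> None:
        object.__setattr__(self, "dog_class", DogClass(self.dog_class))
        object.__setattr__(self, "skin_condition", SkinCondition(self.skin_condition))
        if self.bcs is not None and self.bcs not in (1, 2, 3, 4, 5):
            raise ValueError(f"bcs must be 1..5 or None, got {self.bcs!r}")
        lat, lon = self.point
        _validate_polyline([(lat, lon)])


@dataclass
class ReplicateSurvey:
    """One pass of one route on one day; the replicate unit of the protocol."""

    route_id: str
    survey_date: dt.date
    records: list[DogRecord] = field(default_factory=list)
    protocol_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.timestamp.date() != self.survey_date:
                raise ValueError(
                    f"record timestamp {rec.timestamp.isoformat()} falls outside "
                    f"survey date {self.survey_date.isoformat()} (concatenated log?)"
                )


# ---------------------------------------------------------------------------
# Label maps
# ---------------------------------------------------------------------------

_CLASS_LABELS: dict[str, DogClass] = {
    "Male": DogClass.MALE,
    "Female": DogClass.FEMALE,
    "Lactating female": DogClass.LACTATING_FEMALE,
    "Unknown adult": DogClass.UNKNOWN_ADULT,
    "Pup": DogClass.PUP,
    "Sterilised male": DogClass.STERILISED_MALE,
    "Sterilised female": DogClass.STERILISED_FEMALE,
}


@dataclass(frozen=True)
class LabelMap:
    """Maps GPX waypoint name strings to (dog_class, bcs, skin) triples.

    The default convention composes labels from a class button plus optional
    ``BCS1``..``BCS5`` and ``Skin`` suffixes, e.g. ``"Female BCS2 Skin"``.
    A missing BCS token means the score was not recorded; a missing ``Skin``
    token means no visible skin condition was seen.
    """

    mapping: Mapping[str, tuple[DogClass, Optional[int], SkinCondition]]

    def classify(self, label: str) -> tuple[DogClass, Optional[int], SkinCondition]:
        try:
            return self.mapping[label]
        except KeyError:
            raise UnmappedLabelError([label]) from None

    def label_for(
        self, dog_class: DogClass, bcs: Optional[int], skin: SkinCondition
    ) -> str:
        """Inverse lookup used when emitting GPX; raises if no label exists."""
        for label, triple in self.mapping.items():
            if triple == (dog_class, bcs, skin):
                return label
        raise KeyError(f"no label for {(dog_class, bcs, skin)!r}")


def default_label_map() -> LabelMap:
    """Label map for the default survey-app button layout (84 labels)."""
    mapping: dict[str, tuple[DogClass, Optional[int], SkinCondition]] = {}
    for label, cls in _CLASS_LABELS.items():
        for bcs in (None, 1, 2, 3, 4, 5):
            for skin in (SkinCondition.ABSENT, SkinCondition.PRESENT):
                name = label
                if bcs is not None:
                    name += f" BCS{bcs}"
                if skin is SkinCondition.PRESENT:
                    name += " Skin"
                mapping[name] = (cls, bcs, skin)
    return LabelMap(mapping)


# ---------------------------------------------------------------------------
# KML routes
# ---------------------------------------------------------------------------

def _parse_kml_coordinates(text: str) -> list[tuple[float, float]]:
    # KML order is lon,lat[,alt]; whitespace-separated tuples.
    points = []
    for chunk in text.split():
        parts = chunk.split(",")
        if len(parts) < 2:
            raise FormatError(f"malformed KML coordinate tuple: {chunk!r}")
        lon, lat = float(parts[0]), float(parts[1])
        points.append((lat, lon))
    return points


def read_route_kml(
    path: str | Path,
    route_id: str,
    location: str = "",
    route_type: RouteType | str = RouteType.REPRESENTATIVE,
) -> Route:
    """Read a route from a KML file.

    Only the first LineString is used (multi-segment routes must be
    pre-merged so route identity stays unambiguous); Placemark points and
    any further geometry are ignored.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"not well-formed XML: {path}: {exc}") from exc
    linestrings = tree.findall(f".//{{{_KML_NS}}}LineString")
    if not linestrings:  # tolerate namespace-less KML
        linestrings = [el for el in tree.iter() if etree.QName(el).localname == "LineString"]
    if not linestrings:
        raise FormatError(f"no LineString in KML file {path}")
    coords_el = next(
        (el for el in linestrings[0].iter() if etree.QName(el).localname == "coordinates"),
        None,
    )
    if coords_el is None or not (coords_el.text or "").strip():
        raise FormatError(f"LineString without coordinates in {path}")
    polyline = _parse_kml_coordinates(coords_el.text)
    return Route(route_id=route_id, location=location, route_type=route_type,
                 polyline=tuple(polyline))


def write_route_kml(route: Route, path: str | Path) -> None:
    """Write a route as a single-LineString KML document."""
    kml = etree.Element(f"{{{_KML_NS}}}kml", nsmap={None: _KML_NS})
    doc = etree.SubElement(kml, f"{{{_KML_NS}}}Document")
    pm = etree.SubElement(doc, f"{{{_KML_NS}}}Placemark")
    etree.SubElement(pm, f"{{{_KML_NS}}}name").text = route.route_id
    ls = etree.SubElement(pm, f"{{{_KML_NS}}}LineString")
    etree.SubElement(ls, f"{{{_KML_NS}}}coordinates").text = " ".join(
        f"{lon:.7f},{lat:.7f},0" for lat, lon in route.polyline
    )
    Path(path).write_bytes(etree.tostring(kml, xml_declaration=True, encoding="UTF-8",
                                          pretty_print=True))


# ---------------------------------------------------------------------------
# GPX event logs
# ---------------------------------------------------------------------------

def _local(el: etree._Element, name: str) -> Optional[etree._Element]:
    return next((c for c in el if etree.QName(c).localname == name), None)


def read_event_log_gpx(
    path: str | Path,
    label_map: LabelMap,
    survey_date: dt.date,
    route_id: str = "",
) -> ReplicateSurvey:
    """Read one replicate's GPX event log into a :class:`ReplicateSurvey`.

    Each ``wpt`` element becomes one :class:`DogRecord`, classified through
    ``label_map``.  Track points, if present, are retained in
    ``protocol_meta['track']`` for route-adherence and speed checks.

    Raises
    ------
    UnmappedLabelError
        Listing every waypoint label absent from the map.
    FormatError
        For waypoints without coordinates or malformed XML.
    """
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"not well-formed XML: {path}: {exc}") from exc
    root = tree.getroot()
    wpts = [el for el in root.iter() if etree.QName(el).localname == "wpt"]

    unmapped = []
    records: list[DogRecord] = []
    for wpt in wpts:
        lat_s, lon_s = wpt.get("lat"), wpt.get("lon")
        if lat_s is None or lon_s is None:
            raise FormatError(f"waypoint without coordinates in {path}")
        name_el = _local(wpt, "name")
        label = (name_el.text or "").strip() if name_el is not None else ""
        if label not in label_map.mapping:
            unmapped.append(label)
            continue
        dog_class, bcs, skin = label_map.classify(label)
        time_el = _local(wpt, "time")
        if time_el is not None and time_el.text:
            ts = dt.datetime.fromisoformat(time_el.text.replace("Z", "+00:00"))
            ts = ts.replace(tzinfo=None)
        else:
            ts = dt.datetime.combine(survey_date, dt.time(0, 0))
        records.append(DogRecord(timestamp=ts, point=(float(lat_s), float(lon_s)),
                                 dog_class=dog_class, bcs=bcs, skin_condition=skin))
    if unmapped:
        raise UnmappedLabelError(unmapped)

    track = [
        (float(tp.get("lat")), float(tp.get("lon")))
        for tp in root.iter()
        if etree.QName(tp).localname == "trkpt"
    ]
    meta = {"source": str(path)}
    if track:
        meta["track"] = track
    return ReplicateSurvey(route_id=route_id, survey_date=survey_date,
                           records=records, protocol_meta=meta)


def write_event_log_gpx(
    survey: ReplicateSurvey, path: str | Path, label_map: LabelMap
) -> None:
    """Write a replicate survey as a GPX 1.1 waypoint file."""
    gpx = etree.Element(f"{{{_GPX_NS}}}gpx", nsmap={None: _GPX_NS},
                        attrib={"version": "1.1", "creator": "streetcount"})
    for rec in survey.records:
        wpt = etree.SubElement(
            gpx, f"{{{_GPX_NS}}}wpt",
            attrib={"lat": f"{rec.point[0]:.7f}", "lon": f"{rec.point[1]:.7f}"},
        )
        etree.SubElement(wpt, f"{{{_GPX_NS}}}time").text = (
            rec.timestamp.isoformat(timespec="seconds") + "Z"
        )
        etree.SubElement(wpt, f"{{{_GPX_NS}}}name").text = label_map.label_for(
            rec.dog_class, rec.bcs, rec.skin_condition
        )
    Path(path).write_bytes(etree.tostring(gpx, xml_declaration=True, encoding="UTF-8",
                                          pretty_print=True))


# ---------------------------------------------------------------------------
# Observation CSV
# ---------------------------------------------------------------------------

_CSV_FIELDS = ["route_id", "survey_date", "timestamp", "dog_class", "bcs",
               "skin_condition", "lat", "lon"]


def write_observations_csv(surveys: Iterable[ReplicateSurvey], path: str | Path) -> int:
    """Write one CSV row per dog record; returns the number of rows written.

    Unrecorded BCS is an empty cell (never ``0``); unrecorded skin condition
    likewise.  The file round-trips through :func:`read_observations_csv`
    losslessly.
    """
    n = 0
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_CSV_FIELDS)
        writer.writeheader()
        for survey in surveys:
            for rec in survey.records:
                writer.writerow({
                    "route_id": survey.route_id,
                    "survey_date": survey.survey_date.isoformat(),
                    "timestamp": rec.timestamp.isoformat(timespec="seconds"),
                    "dog_class": rec.dog_class.value,
                    "bcs": "" if rec.bcs is None else rec.bcs,
                    "skin_condition": (
                        "" if rec.skin_condition is SkinCondition.UNRECORDED
                        else rec.skin_condition.value
                    ),
                    "lat": f"{rec.point[0]:.7f}",
                    "lon": f"{rec.point[1]:.7f}",
                })
                n += 1
    return n


def read_observations_csv(path: str | Path) -> list[ReplicateSurvey]:
    """Read an observation CSV back into replicate surveys.

    Rows are grouped by (route_id, survey_date); group order follows first
    appearance in the file, so a written file reads back in the same order.
    """
    groups: dict[tuple[str, dt.date], list[DogRecord]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["route_id"], dt.date.fromisoformat(row["survey_date"]))
            rec = DogRecord(
                timestamp=dt.datetime.fromisoformat(row["timestamp"]),
                point=(float(row["lat"]), float(row["lon"])),
                dog_class=DogClass(row["dog_class"]),
                bcs=int(row["bcs"]) if row["bcs"] else None,
                skin_condition=(
                    SkinCondition(row["skin_condition"]) if row["skin_condition"]
                    else SkinCondition.UNRECORDED
                ),
            )
            groups.setdefault(key, []).append(rec)
    return [
        ReplicateSurvey(route_id=rid, survey_date=date, records=recs)
        for (rid, date), recs in groups.items()
    ]
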