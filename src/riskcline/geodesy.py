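"""Great-circle distances along the out-of-Africa expansion route.

Distance from Africa is the standard proxy for the cumulative drift a
population has experienced under the serial-founder model of the human range
expansion.  Each population's distance is computed as a chain of haversine
great-circle legs from an African origin (Addis Ababa) through
region-specific waypoints, so that the path approximates overland migration:
European populations are routed through Cairo and Istanbul, East Asian ones
through Cairo and Phnom Penh, American ones through Cairo, Anadyr and Prince
Rupert (the Bering land bridge), rather than straight across oceans.

The route table is a plain ``{region: Route}`` mapping and is fully
user-overridable; :data:`DEFAULT_ROUTES` ships sensible defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoPoint",
    "Route",
    "PopulationPanel",
    "great_circle_km",
    "route_distance_km",
    "assign_distances",
    "DEFAULT_ROUTES",
    "ADDIS_ABABA",
]

#: Mean Earth radius in km used for all great-circle arithmetic.
EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GeoPoint:
    """A point on the sphere, in decimal degrees."""

    latitude: float
    longitude: float
    label: str = ""

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude!r} outside [-90, 90]")
        if not -180.0 <= self.longitude <= 180.0:
            raise ValueError(f"longitude {self.longitude!r} outside [-180, 180]")


def great_circle_km(a: GeoPoint, b: GeoPoint) -> float:
    """Haversine great-circle distance between two points, in km.

    Symmetric and non-negative; zero iff the points coincide.  Computed on a
    sphere of radius :data:`EARTH_RADIUS_KM`.
    """
    phi1, phi2 = math.radians(a.latitude), math.radians(b.latitude)
    dphi = phi2 - phi1
    dlam = math.radians(b.longitude - a.longitude)
    h = math.sin(dphi / 2.0) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2.0) ** 2
    # clip guards rounding for near-antipodal pairs
    return 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(h)))


@dataclass(frozen=True)
class Route:
    """An origin plus an ordered (possibly empty) chain of waypoints."""

    origin: GeoPoint
    waypoints: tuple[GeoPoint, ...] = ()


def route_distance_km(target: GeoPoint, route: Route) -> float:
    """Total distance origin -> w1 -> ... -> wk -> target, in km.

    With no waypoints this is the direct origin-to-target great-circle
    distance.  Waypoints can only lengthen the path (triangle inequality).
    """
    legs = (route.origin, *route.waypoints, target)
    return sum(great_circle_km(p, q) for p, q in zip(legs[:-1], legs[1:]))


# -- default waypoint cities ------------------------------------------------

ADDIS_ABABA = GeoPoint(9.03, 38.74, "Addis Ababa")
CAIRO = GeoPoint(30.05, 31.25, "Cairo")
ISTANBUL = GeoPoint(41.01, 28.98, "Istanbul")
ANADYR = GeoPoint(64.73, 177.51, "Anadyr")
PHNOM_PENH = GeoPoint(11.55, 104.92, "Phnom Penh")
PRINCE_RUPERT = GeoPoint(54.32, -130.32, "Prince Rupert")

#: Region -> route defaults for worldwide population panels.  Overridable;
#: regions not listed here must be supplied by the caller's route table.
DEFAULT_ROUTES: dict[str, Route] = {
    "AFRICA": Route(ADDIS_ABABA),
    "MIDDLE_EAST": Route(ADDIS_ABABA, (CAIRO,)),
    "EUROPE": Route(ADDIS_ABABA, (CAIRO, ISTANBUL)),
    "CENTRAL_SOUTH_ASIA": Route(ADDIS_ABABA, (CAIRO, ISTANBUL)),
    "EAST_ASIA": Route(ADDIS_ABABA, (CAIRO, PHNOM_PENH)),
    "OCEANIA": Route(ADDIS_ABABA, (CAIRO, PHNOM_PENH)),
    "AMERICA": Route(ADDIS_ABABA, (CAIRO, ANADYR, PRINCE_RUPERT)),
}


@dataclass
class PopulationPanel:
    """Ordered set of sampled populations with geography.

    ``table`` is indexed by population name; recognised columns are
    ``region``, ``latitude``, ``longitude`` and ``distance_km``.  Synthetic
    panels carry ``distance_km`` directly; real panels carry coordinates and
    a region, and get distances from :func:`assign_distances`.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("duplicate population names in panel")

    @property
    def populations(self) -> list[str]:
        return list(self.table.index)

    @property
    def distances_km(self) -> pd.Series:
        if "distance_km" not in self.table.columns:
            raise ValueError("panel has no distances; run assign_distances first")
        return self.table["distance_km"]


def assign_distances(
    panel: PopulationPanel,
    route_table: Mapping[str, Route] | None = None,
) -> pd.Series:
    """Per-population distance from the route origin, in km.

    Each population's ``region`` selects a route from ``route_table``
    (default :data:`DEFAULT_ROUTES`); the distance is the waypoint-routed
    great-circle distance from the route's origin to the population's
    coordinates.  The result is also stored on the panel as ``distance_km``.
    """
    routes = DEFAULT_ROUTES if route_table is None else route_table
    for col in ("region", "latitude", "longitude"):
        if col not in panel.table.columns:
            raise ValueError(f"panel lacks required column {col!r}")
    out = {}
    for pop, row in panel.table.iterrows():
        region = row["region"]
        if region not in routes:
            raise KeyError(f"no route defined for region {region!r} (population {pop!r})")
        target = GeoPoint(float(row["latitude"]), float(row["longitude"]), str(pop))
        out[pop] = route_distance_km(target, routes[region])
    dist = pd.Series(out, name="distance_km").reindex(panel.table.index)
    panel.table["distance_km"] = dist
    return dist
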