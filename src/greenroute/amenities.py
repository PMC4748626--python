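"""Buffer search around a location for food, recreation and other amenities,
plus accident counts, with popup-style record formatting.

Buffers are straight-line (Euclidean) closed disks: a point exactly on the
boundary is included. The radius can be given directly in meters or derived
from a travel speed and time budget.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .geodata import AMENITY_CATEGORIES, AccidentRecord, Amenity

__all__ = [
    "BufferQuery",
    "buffer_radius",
    "find_amenities",
    "accident_count_in_buffer",
    "amenity_record",
]


def buffer_radius(speed_kmh: float, time_min: float) -> float:
    """Search radius in meters reachable at ``speed_kmh`` in ``time_min``."""
    return speed_kmh * (time_min / 60.0) * 1000.0


@dataclass
class BufferQuery:
    """A disk query: center plus a radius (direct or speed x time) and an
    optional category filter (empty = all categories)."""

    center: tuple[float, float]
    radius_m: float | None = None
    speed_kmh: float | None = None
    time_min: float | None = None
    categories: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.radius_m is None:
            if self.speed_kmh is None or self.time_min is None:
                raise ValueError("give radius_m or both speed_kmh and time_min")
            self.radius_m = buffer_radius(self.speed_kmh, self.time_min)
        if self.radius_m <= 0:
            raise ValueError(f"buffer radius must be > 0, got {self.radius_m}")
        self.categories = frozenset(self.categories)
        unknown = self.categories - set(AMENITY_CATEGORIES)
        if unknown:
            raise ValueError(f"unknown amenity categories: {sorted(unknown)}")


def _dist(p: Sequence[float], q: Sequence[float]) -> float:
    return math.hypot(p[0] - q[0], p[1] - q[1])


def find_amenities(amenities: Iterable[Amenity], query: BufferQuery) -> list[Amenity]:
    """Amenities of the requested categories within the closed disk,
    sorted by distance ascending (ties by id)."""
    hits = []
    for am in amenities:
        if query.categories and am.category not in query.categories:
            continue
        d = _dist(am.location, query.center)
        if d <= query.radius_m:
            hits.append((d, am.id, am))
    hits.sort(key=lambda t: (t[0], t[1]))
    return [am for _, _, am in hits]


def accident_count_in_buffer(
    accidents: Iterable[AccidentRecord],
    center: Sequence[float],
    radius_m: float,
) -> int:
    """Number of pedestrian/bicyclist-involved accidents within the disk."""
    if radius_m <= 0:
        raise ValueError("radius must be > 0")
    return sum(1 for a in accidents if _dist(a.location, center) <= radius_m)


def amenity_record(amenity: Amenity) -> dict:
    """Popup-style record for an amenity.

    All records carry the street address and phone contact; farmers' markets
    add opening hours and a website link when available; recreation entries
    add the program types offered and the city they belong to.
    """
    rec = {
        "id": amenity.id,
        "category": amenity.category,
        "name": amenity.name,
        "street_address": amenity.street_address,
        "phone": amenity.phone,
    }
    if amenity.category == "farmers_market":
        if amenity.opening_hours is not None:
            rec["opening_hours"] = amenity.opening_hours
        if amenity.website is not None:
            rec["website"] = amenity.website
    if amenity.category in ("recreation_general", "recreation_detailed"):
        rec["program_types"] = list(amenity.program_types or ())
        if amenity.city is not None:
            rec["city"] = amenity.city
        if amenity.met_value is not None:
            rec["met_value"] = amenity.met_value
    return rec
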