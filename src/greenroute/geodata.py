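"""Domain types and geometry for environmentally annotated road networks.

All coordinates are planar projected meters; lengths, buffers and snapping
distances are Euclidean. Geographic (lat/lon) data must be projected before
it enters the engine.

The road network is a *link set*: the primary objects are road segments
(links) carrying environmental attributes (slope, traffic pollution, NDVI
greenness, active-travel accident counts), with a node index recording which
segments meet at each intersection. Two segments are physically adjacent iff
they share an endpoint node.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from shapely.geometry import LineString, Point

__all__ = [
    "ROAD_CLASSES",
    "TRAVEL_MODES",
    "AMENITY_CATEGORIES",
    "GeodataError",
    "ValidationError",
    "RoadSegment",
    "RoadNetwork",
    "Raster",
    "Amenity",
    "AccidentRecord",
    "compute_gradient",
    "gradient_to_degrees",
    "nearest_segment",
    "load_network",
    "save_network",
    "load_amenities",
    "save_amenities",
    "load_accidents",
    "save_accidents",
    "load_raster",
    "save_raster",
    "save_route",
]

ROAD_CLASSES = ("bike_designated", "bike_alternative", "connecting", "local", "highway")
TRAVEL_MODES = ("drive", "bike", "walk")
ONE_WAY_VALUES = ("none", "a_to_b", "b_to_a")
AMENITY_CATEGORIES = (
    "fruit_veg",
    "farmers_market",
    "grocery",
    "restaurant",
    "park",
    "recreation_general",
    "recreation_detailed",
    "school",
    "healthcare",
)

# Node coordinates are keyed at millimeter precision so that floating-point
# noise in endpoint coordinates cannot split an intersection into two nodes.
_NODE_DECIMALS = 3


class GeodataError(Exception):
    """Base error for network / raster / amenity data problems."""


class ValidationError(GeodataError):
    """Input data violates a domain invariant."""


def node_key(point: Sequence[float]) -> tuple[float, float]:
    """Canonical hashable key for an intersection coordinate."""
    return (round(float(point[0]), _NODE_DECIMALS), round(float(point[1]), _NODE_DECIMALS))


def compute_gradient(altitude_a: float, altitude_b: float, length: float) -> float:
    """Slope gradient of a segment: altitude change over horizontal distance.

    The gradient is the unsigned ratio ``|altitude_b - altitude_a| / length``;
    a ratio of 1 corresponds to a 45 degree slope. Directional (signed) rise
    is recomputed from the altitudes during routing.

    Raises
    ------
    ValueError
        If ``length`` is not strictly positive.
    """
    if length <= 0:
        raise ValueError(f"segment length must be > 0, got {length}")
    return abs(altitude_b - altitude_a) / length


def gradient_to_degrees(ratio: float) -> float:
    """Convert a slope gradient ratio to an angle in degrees (arctangent)."""
    if ratio < 0:
        raise ValueError(f"gradient ratio must be >= 0, got {ratio}")
    return math.degrees(math.atan(ratio))


@dataclass(frozen=True)
class RoadSegment:
    """A directed-capable road link with environmental attributes.

    ``polyline`` runs from endpoint ``a`` to endpoint ``b``. ``length`` is the
    polyline length in meters (at least the straight-line a-b distance).
    ``gradient`` is the unsigned slope ratio; ``mean_pollution`` is in
    concentration units (e.g. ppb NO2), ``mean_greenness`` is NDVI in [-1, 1].
    """

    id: str
    polyline: tuple[tuple[float, float], ...]
    road_class: str
    one_way: str = "none"
    altitude_a: float = 0.0
    altitude_b: float = 0.0
    mean_pollution: float = 0.0
    mean_greenness: float = 0.0
    accident_count: int = 0
    modes_allowed: frozenset[str] = frozenset(TRAVEL_MODES)
    name: str | None = None

    def __post_init__(self) -> None:
        poly = tuple((float(x), float(y)) for x, y in self.polyline)
        object.__setattr__(self, "polyline", poly)
        object.__setattr__(self, "modes_allowed", frozenset(self.modes_allowed))
        if len(poly) < 2:
            raise ValidationError(f"segment {self.id}: polyline needs >= 2 points")
        if self.road_class not in ROAD_CLASSES:
            raise ValidationError(
                f"segment {self.id}: unknown road_class {self.road_class!r}"
            )
        if self.one_way not in ONE_WAY_VALUES:
            raise ValidationError(f"segment {self.id}: bad one_way {self.one_way!r}")
        if not self.modes_allowed <= set(TRAVEL_MODES):
            raise ValidationError(
                f"segment {self.id}: unknown modes {set(self.modes_allowed) - set(TRAVEL_MODES)}"
            )
        if self.accident_count < 0 or int(self.accident_count) != self.accident_count:
            raise ValidationError(
                f"segment {self.id}: accident_count must be a non-negative integer"
            )
        if not -1.0 <= self.mean_greenness <= 1.0:
            raise ValidationError(
                f"segment {self.id}: mean_greenness {self.mean_greenness} outside [-1, 1]"
            )
        if self.length <= 0:
            raise ValidationError(f"segment {self.id}: zero-length geometry")

    @property
    def a(self) -> tuple[float, float]:
        return self.polyline[0]

    @property
    def b(self) -> tuple[float, float]:
        return self.polyline[-1]

    @property
    def line(self) -> LineString:
        return LineString(self.polyline)

    @property
    def length(self) -> float:
        return self.line.length

    @property
    def gradient(self) -> float:
        return compute_gradient(self.altitude_a, self.altitude_b, self.length)

    def altitude_at(self, end: tuple[float, float]) -> float:
        """Altitude at whichever endpoint ``end`` refers to."""
        if node_key(end) == node_key(self.a):
            return self.altitude_a
        if node_key(end) == node_key(self.b):
            return self.altitude_b
        raise ValueError(f"{end} is not an endpoint of segment {self.id}")

    def allows(self, mode: str, direction: str) -> bool:
        """True when ``mode`` may traverse this segment in ``direction``."""
        if mode not in self.modes_allowed:
            return False
        if self.one_way == "none":
            return True
        return self.one_way == direction


class RoadNetwork:
    """A collection of :class:`RoadSegment` with an endpoint incidence index.

    ``node_index`` maps each intersection coordinate (rounded to mm) to the
    ids of the segments incident there; it is rebuilt on construction and is
    the only topology structure the router needs.
    """

    def __init__(self, segments: Iterable[RoadSegment], crs_note: str = "") -> None:
        self.segments: dict[str, RoadSegment] = {}
        for seg in segments:
            if seg.id in self.segments:
                raise ValidationError(f"duplicate segment id {seg.id!r}")
            self.segments[seg.id] = seg
        self.crs_note = crs_note
        self.node_index: dict[tuple[float, float], list[str]] = {}
        for seg in self.segments.values():
            for end in (seg.a, seg.b):
                self.node_index.setdefault(node_key(end), []).append(seg.id)
        for ids in self.node_index.values():
            ids.sort()

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments.values())

    def __contains__(self, seg_id: str) -> bool:
        return seg_id in self.segments

    def __getitem__(self, seg_id: str) -> RoadSegment:
        return self.segments[seg_id]

    @property
    def nodes(self) -> list[tuple[float, float]]:
        return list(self.node_index)

    def incident(self, node: Sequence[float]) -> list[str]:
        """Segment ids meeting at a node (empty if the node is unknown)."""
        return list(self.node_index.get(node_key(node), ()))

    def adjacent(self, seg_id: str) -> set[str]:
        """Ids of segments physically adjacent (sharing an endpoint)."""
        seg = self.segments[seg_id]
        out: set[str] = set()
        for end in (seg.a, seg.b):
            out.update(self.node_index[node_key(end)])
        out.discard(seg_id)
        return out

    def bounds(self) -> tuple[float, float, float, float]:
        if not self.segments:
            raise GeodataError("empty network has no bounds")
        xs = [x for s in self for x, _ in s.polyline]
        ys = [y for s in self for _, y in s.polyline]
        return min(xs), min(ys), max(xs), max(ys)

    def replace_segments(self, segments: Iterable[RoadSegment]) -> "RoadNetwork":
        return RoadNetwork(segments, crs_note=self.crs_note)


def nearest_segment(
    network: RoadNetwork, point: Sequence[float]
) -> tuple[str, float, float]:
    """Snap a point to the network.

    Returns ``(segment_id, offset_m, distance_m)`` where ``offset_m`` is the
    distance along the segment polyline (from endpoint ``a``) of the closest
    point. Ties on distance are broken by the lowest segment id.
    """
    if len(network) == 0:
        raise GeodataError("cannot snap to an empty network")
    p = Point(float(point[0]), float(point[1]))
    best: tuple[float, str] | None = None
    for seg_id in sorted(network.segments):
        d = network[seg_id].line.distance(p)
        if best is None or d < best[0] - 1e-12:
            best = (d, seg_id)
    dist, seg_id = best  # type: ignore[misc]
    offset = network[seg_id].line.project(p)
    return seg_id, float(offset), float(dist)


# ---------------------------------------------------------------------------
# Rasters (regular grid surfaces: reflectance, NDVI, pollution, greenness)
# ---------------------------------------------------------------------------


@dataclass
class Raster:
    """A regular grid surface in the ESRI ASCII grid layout.

    ``values`` has shape (n_rows, n_cols) with row 0 the *top* row, matching
    the on-disk order; (origin_x, origin_y) is the lower-left corner.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    values: np.ndarray
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("raster values must be a 2-D grid")
        if self.cell_size <= 0:
            raise ValidationError("cell_size must be > 0")
        body = self.values[self.values != self.nodata]
        if body.size and not np.all(np.isfinite(body)):
            raise ValidationError("raster contains non-finite, non-nodata cells")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y) of the covered rectangle."""
        return (
            self.origin_x,
            self.origin_y,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y + self.n_rows * self.cell_size,
        )

    def same_geometry(self, other: "Raster") -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.origin_x, other.origin_x)
            and math.isclose(self.origin_y, other.origin_y)
            and math.isclose(self.cell_size, other.cell_size)
        )

    def cell_of(self, x: float, y: float) -> tuple[int, int] | None:
        """(array_row, col) of the cell containing (x, y), or None if outside."""
        col = int(math.floor((x - self.origin_x) / self.cell_size))
        row_up = int(math.floor((y - self.origin_y) / self.cell_size))
        if not (0 <= col < self.n_cols and 0 <= row_up < self.n_rows):
            return None
        return self.n_rows - 1 - row_up, col

    def value_at(self, x: float, y: float) -> float | None:
        """Cell value at a point; None when outside the grid or nodata."""
        cell = self.cell_of(x, y)
        if cell is None:
            return None
        v = float(self.values[cell])
        return None if v == self.nodata else v

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Raster):
            return NotImplemented
        return self.same_geometry(other) and bool(
            np.array_equal(self.values, other.values)
        ) and self.nodata == other.nodata


# ---------------------------------------------------------------------------
# Amenities and accident records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Amenity:
    """A categorized point of interest with popup-style metadata."""

    id: str
    category: str
    location: tuple[float, float]
    name: str = ""
    street_address: str = ""
    phone: str = ""
    opening_hours: str | None = None
    website: str | None = None
    program_types: tuple[str, ...] | None = None
    city: str | None = None
    met_value: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "location", (float(self.location[0]), float(self.location[1]))
        )
        if self.program_types is not None:
            object.__setattr__(self, "program_types", tuple(self.program_types))
        if self.category not in AMENITY_CATEGORIES:
            raise ValidationError(f"amenity {self.id}: unknown category {self.category!r}")
        # Detailed recreation entries come from an audit that only kept
        # offerings above moderate-walking exertion (MET > 3.0).
        if (
            self.category == "recreation_detailed"
            and self.met_value is not None
            and self.met_value <= 3.0
        ):
            raise ValidationError(
                f"amenity {self.id}: detailed recreation requires MET > 3.0"
            )


@dataclass(frozen=True)
class AccidentRecord:
    """A traffic collision involving at least a pedestrian or a bicyclist."""

    id: str
    location: tuple[float, float]
    year: int
    involves: frozenset[str]

    #: default analysis window analog (inclusive)
    YEAR_WINDOW = (2005, 2007)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "location", (float(self.location[0]), float(self.location[1]))
        )
        object.__setattr__(self, "involves", frozenset(self.involves))
        if not self.involves:
            raise ValidationError(f"accident {self.id}: involves must be non-empty")
        if not self.involves <= {"pedestrian", "bicyclist"}:
            raise ValidationError(f"accident {self.id}: bad involves {self.involves}")
        lo, hi = self.YEAR_WINDOW
        if not lo <= self.year <= hi:
            raise ValidationError(
                f"accident {self.id}: year {self.year} outside window {lo}-{hi}"
            )


# ---------------------------------------------------------------------------
# GeoJSON / ASCII-grid / CSV readers and writers
# ---------------------------------------------------------------------------

_SEGMENT_DEFAULTS: Mapping[str, object] = {
    "one_way": "none",
    "altitude_a": 0.0,
    "altitude_b": 0.0,
    "mean_pollution": 0.0,
    "mean_greenness": 0.0,
    "accident_count": 0,
}


def _read_feature_collection(path: str | Path) -> list[dict]:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise GeodataError(f"{path}: malformed GeoJSON ({exc})") from exc
    if doc.get("type") != "FeatureCollection" or "features" not in doc:
        raise GeodataError(f"{path}: not a GeoJSON FeatureCollection")
    return doc["features"]


def _round_floats(obj, ndigits=6):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _write_feature_collection(features: list[dict], path: str | Path, **meta) -> None:
    doc = {"type": "FeatureCollection", "features": features, **meta}
    with open(path, "w") as fh:
        json.dump(_round_floats(doc), fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_network(path: str | Path) -> RoadNetwork:
    """Read a road network from a GeoJSON FeatureCollection of LineStrings.

    Mandatory per-feature properties: ``id`` and ``road_class``; all other
    segment attributes default permissively (flat, clean, two-way, all
    modes) so partial datasets load.
    """
    features = _read_feature_collection(path)
    segments = []
    for i, feat in enumerate(features):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "LineString":
            raise ValidationError(f"{path}: feature {i} is not a LineString")
        props = feat.get("properties") or {}
        if "road_class" not in props:
            raise ValidationError(f"{path}: feature {i} lacks mandatory 'road_class'")
        kwargs = dict(_SEGMENT_DEFAULTS)
        for key in kwargs:
            if key in props:
                kwargs[key] = props[key]
        modes = props.get("modes_allowed")
        segments.append(
            RoadSegment(
                id=str(props.get("id", i)),
                polyline=tuple(map(tuple, geom["coordinates"])),
                road_class=props["road_class"],
                modes_allowed=frozenset(modes) if modes else frozenset(TRAVEL_MODES),
                name=props.get("name"),
                **kwargs,  # type: ignore[arg-type]
            )
        )
    return RoadNetwork(segments, crs_note=_crs_note(path, features))


def _crs_note(path, features) -> str:
    try:
        with open(path) as fh:
            return json.load(fh).get("crs_note", "")
    except Exception:
        return ""


def save_network(network: RoadNetwork, path: str | Path) -> None:
    features = []
    for seg_id in sorted(network.segments):
        seg = network[seg_id]
        props = {
            "id": seg.id,
            "road_class": seg.road_class,
            "one_way": seg.one_way,
            "altitude_a": seg.altitude_a,
            "altitude_b": seg.altitude_b,
            "mean_pollution": seg.mean_pollution,
            "mean_greenness": seg.mean_greenness,
            "accident_count": int(seg.accident_count),
            "modes_allowed": sorted(seg.modes_allowed),
        }
        if seg.name is not None:
            props["name"] = seg.name
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [list(p) for p in seg.polyline],
                },
                "properties": props,
            }
        )
    _write_feature_collection(features, path, crs_note=network.crs_note)


def load_amenities(path: str | Path) -> list[Amenity]:
    features = _read_feature_collection(path)
    out = []
    for i, feat in enumerate(features):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValidationError(f"{path}: feature {i} is not a Point")
        p = feat.get("properties") or {}
        if "category" not in p:
            raise ValidationError(f"{path}: feature {i} lacks mandatory 'category'")
        out.append(
            Amenity(
                id=str(p.get("id", i)),
                category=p["category"],
                location=tuple(geom["coordinates"]),
                name=p.get("name", ""),
                street_address=p.get("street_address", ""),
                phone=p.get("phone", ""),
                opening_hours=p.get("opening_hours"),
                website=p.get("website"),
                program_types=tuple(p["program_types"]) if p.get("program_types") else None,
                city=p.get("city"),
                met_value=p.get("met_value"),
            )
        )
    return out


def save_amenities(amenities: Iterable[Amenity], path: str | Path) -> None:
    features = []
    for am in sorted(amenities, key=lambda a: a.id):
        props: dict = {"id": am.id, "category": am.category, "name": am.name,
                       "street_address": am.street_address, "phone": am.phone}
        for key in ("opening_hours", "website", "city", "met_value"):
            val = getattr(am, key)
            if val is not None:
                props[key] = val
        if am.program_types is not None:
            props["program_types"] = list(am.program_types)
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": list(am.location)},
                "properties": props,
            }
        )
    _write_feature_collection(features, path)


def load_accidents(path: str | Path) -> list[AccidentRecord]:
    """Read accident records from GeoJSON points or CSV.

    CSV columns: ``id,x,y,year,involves`` with ``involves`` a semicolon-joined
    subset of pedestrian/bicyclist.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        out = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                try:
                    out.append(
                        AccidentRecord(
                            id=row["id"],
                            location=(float(row["x"]), float(row["y"])),
                            year=int(row["year"]),
                            involves=frozenset(
                                s for s in row["involves"].split(";") if s
                            ),
                        )
                    )
                except (KeyError, ValueError) as exc:
                    raise GeodataError(f"{path}: bad accident row {row!r}: {exc}") from exc
        return out
    features = _read_feature_collection(path)
    out = []
    for i, feat in enumerate(features):
        geom = feat.get("geometry") or {}
        p = feat.get("properties") or {}
        out.append(
            AccidentRecord(
                id=str(p.get("id", i)),
                location=tuple(geom["coordinates"]),
                year=int(p["year"]),
                involves=frozenset(p["involves"]),
            )
        )
    return out


def save_accidents(accidents: Iterable[AccidentRecord], path: str | Path) -> None:
    path = Path(path)
    records = sorted(accidents, key=lambda a: a.id)
    if path.suffix.lower() == ".csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "x", "y", "year", "involves"])
            for a in records:
                writer.writerow(
                    [a.id, repr(a.location[0]), repr(a.location[1]), a.year,
                     ";".join(sorted(a.involves))]
                )
        return
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": list(a.location)},
            "properties": {"id": a.id, "year": a.year, "involves": sorted(a.involves)},
        }
        for a in records
    ]
    _write_feature_collection(features, path)


def load_raster(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid (ncols/nrows/xllcorner/yllcorner/cellsize header)."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise GeodataError(f"{path}: missing ASCII grid header field {key!r}")
    values = np.array([v for row in rows for v in row], dtype=float)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if values.size != n_rows * n_cols:
        raise GeodataError(
            f"{path}: grid body has {values.size} cells, header says {n_rows}x{n_cols}"
        )
    return Raster(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        cell_size=header["cellsize"],
        values=values.reshape(n_rows, n_cols),
        nodata=header.get("nodata_value", -9999.0),
    )


def save_raster(raster: Raster, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {raster.origin_x!r}\n")
        fh.write(f"yllcorner {raster.origin_y!r}\n")
        fh.write(f"cellsize {raster.cell_size!r}\n")
        fh.write(f"NODATA_value {raster.nodata!r}\n")
        for row in raster.values:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def save_route(route, network: RoadNetwork, path: str | Path) -> None:
    """Write a route as GeoJSON LineString features, one per traversed link."""
    features = []
    for i, leg in enumerate(route.legs(network)):
        seg = network[leg.segment_id]
        coords = leg.geometry(network)
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "LineString",
                             "coordinates": [list(p) for p in coords]},
                "properties": {
                    "order": i,
                    "id": seg.id,
                    "direction": leg.direction,
                    "road_class": seg.road_class,
                    "length_m": leg.length(network),
                    "cost_share": leg.cost,
                    "gradient": seg.gradient,
                },
            }
        )
    _write_feature_collection(
        features, path, total_impedance=route.total_impedance, feasible=route.feasible
    )
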