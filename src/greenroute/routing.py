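"""Preference-weighted link-based optimal route search.

The search state is a *directed link* (road segment + travel direction), not
an intersection node: two links are adjacent when they share an endpoint and
the second is travelable from it. Starting from the link the origin snaps
to, adjacent travelable links inside a rectangular box (origin/destination
extent plus a half-mile buffer) are marked and priced; the marked link with
the least cumulative impedance is settled and expanded next, until the
destination link is reached or the frontier inside the box is exhausted
("no direct route"). With strictly positive link costs this is
uniform-cost (Dijkstra) search over the line digraph of the network.

Impedance model
---------------
Each traversal of a link costs

    cost = eps * length * m_class + env_term

where ``m_class = 10 / class_weight`` maps the user's 1-10 road-class
rating (10 = most preferred) to a length multiplier, and ``env_term``
implements the selected environmental preference:

==================  =====================================================
preference          env_term (eps)
==================  =====================================================
none                0                                   (eps = 1)
avoid_elevation     directional rise in m, max(0, dz)   (eps = 1e-6)
low_pollution       length * mean_pollution             (eps = 1e-6)
vegetated           length * (1 - NDVI) / 2             (eps = 1e-6)
avoid_accidents     accident_count                      (eps = 1e-6)
==================  =====================================================

Route length carries full weight only under ``none``; for the environmental
preferences the tiny ``eps`` term breaks ties and keeps every cost strictly
positive without materially entering the objective (elevation gain and
accident counts are judged on their own, not per unit distance, while
pollution and greenness exposure are inherently length-weighted).
Partial first/last links are costed proportionally to the traversed
fraction.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Mapping

from shapely.geometry import box as shapely_box
from shapely.ops import substring

from .geodata import (
    GeodataError,
    RoadNetwork,
    RoadSegment,
    node_key,
    nearest_segment,
)

__all__ = [
    "HALF_MILE_M",
    "EPSILON",
    "PreferenceProfile",
    "BoundingBox",
    "Route",
    "RouteLeg",
    "make_bounding_box",
    "subset_network",
    "filter_by_slope",
    "link_cost",
    "find_route",
    "oracle_route",
]

#: half a mile in meters — the paper-scale pruning buffer around trip endpoints
HALF_MILE_M = 804.672

#: tie-breaking weight on length under environmental preferences
EPSILON = 1e-6

ENV_PREFS = ("none", "avoid_elevation", "low_pollution", "vegetated", "avoid_accidents")
BIKE_STYLES = ("most_friendly", "balanced")

_DEFAULT_WEIGHTS = {
    "bike": {
        "bike_designated": 10,
        "bike_alternative": 8,
        "connecting": 5,
        "local": 6,
        "highway": 1,
    },
    "walk": {"connecting": 5, "local": 8, "highway": 1},
}
# car routing exposes no class preferences: highways favored, rest neutral
_DRIVE_WEIGHTS = {"highway": 10}
_FALLBACK_WEIGHT = 5

_DEFAULT_SPEED_KMH = {"drive": 40.0, "bike": 15.0, "walk": 5.0}


@dataclass
class PreferenceProfile:
    """User routing preferences: mode, road-class ratings, environment.

    ``class_weights`` rates road classes 1-10 (10 = most preferred to travel
    on); bicycling rates all five classes, walking rates connecting/local/
    highway. Classes absent from the map get a neutral weight of 5.
    ``max_gradient`` is a slope-ratio ceiling (segments steeper than it are
    excluded); ``body_weight_lb`` feeds the walking calorie model.
    """

    mode: str = "bike"
    bike_style: str = "balanced"
    class_weights: Mapping[str, int] = field(default_factory=dict)
    env_pref: str = "none"
    speed_kmh: float | None = None
    max_gradient: float | None = None
    body_weight_lb: float = 150.0

    def __post_init__(self) -> None:
        if self.mode not in ("drive", "bike", "walk"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.bike_style not in BIKE_STYLES:
            raise ValueError(f"unknown bike_style {self.bike_style!r}")
        if self.env_pref not in ENV_PREFS:
            raise ValueError(f"unknown env_pref {self.env_pref!r}")
        merged = dict(
            _DRIVE_WEIGHTS if self.mode == "drive" else _DEFAULT_WEIGHTS[self.mode]
        )
        if self.mode != "drive":
            merged.update({k: int(v) for k, v in self.class_weights.items()})
        for cls, w in merged.items():
            if not 1 <= w <= 10:
                raise ValueError(f"class weight for {cls} must be in 1..10, got {w}")
        self.class_weights = merged
        if self.speed_kmh is None:
            self.speed_kmh = _DEFAULT_SPEED_KMH[self.mode]
        if self.speed_kmh <= 0:
            raise ValueError("speed must be > 0")
        if self.max_gradient is not None and self.max_gradient < 0:
            raise ValueError("max_gradient must be >= 0 when set")

    def class_multiplier(self, road_class: str) -> float:
        w = self.class_weights.get(road_class, _FALLBACK_WEIGHT)
        m = 10.0 / w
        if self.mode == "bike" and self.bike_style == "most_friendly":
            m = m * m
        return m


@dataclass(frozen=True)
class BoundingBox:
    min_x: float
    min_y: float
    max_x: float
    max_y: float

    def __post_init__(self) -> None:
        if self.min_x > self.max_x or self.min_y > self.max_y:
            raise ValueError("bounding box min exceeds max")

    def contains(self, point) -> bool:
        return (
            self.min_x <= point[0] <= self.max_x
            and self.min_y <= point[1] <= self.max_y
        )


def make_bounding_box(start, end, buffer: float = HALF_MILE_M) -> BoundingBox:
    """Axis-aligned rectangle covering both trip endpoints plus a buffer."""
    if buffer < 0:
        raise ValueError("buffer must be >= 0")
    return BoundingBox(
        min_x=min(start[0], end[0]) - buffer,
        min_y=min(start[1], end[1]) - buffer,
        max_x=max(start[0], end[0]) + buffer,
        max_y=max(start[1], end[1]) + buffer,
    )


def subset_network(network: RoadNetwork, bbox: BoundingBox) -> RoadNetwork:
    """Restrict to segments whose polyline intersects the box; rebuild topology."""
    rect = shapely_box(bbox.min_x, bbox.min_y, bbox.max_x, bbox.max_y)
    return network.replace_segments(
        seg for seg in network if seg.line.intersects(rect)
    )


def filter_by_slope(network: RoadNetwork, max_gradient: float | None) -> RoadNetwork:
    """Drop segments steeper than the slope-ratio ceiling (None = keep all)."""
    if max_gradient is None:
        return network
    return network.replace_segments(
        seg for seg in network if seg.gradient <= max_gradient
    )


def link_cost(segment: RoadSegment, direction: str, profile: PreferenceProfile) -> float:
    """Impedance of one full traversal of a link in a direction.

    Callers must pre-filter for admissibility (mode, one-way, max slope);
    pricing an inadmissible traversal raises.
    """
    if not segment.allows(profile.mode, direction):
        raise ValueError(
            f"segment {segment.id} not travelable {direction} by {profile.mode}"
        )
    eps = 1.0 if profile.env_pref == "none" else EPSILON
    cost = eps * segment.length * profile.class_multiplier(segment.road_class)
    if profile.env_pref == "avoid_elevation":
        dz = (
            segment.altitude_b - segment.altitude_a
            if direction == "a_to_b"
            else segment.altitude_a - segment.altitude_b
        )
        cost += max(0.0, dz)
    elif profile.env_pref == "low_pollution":
        cost += segment.length * segment.mean_pollution
    elif profile.env_pref == "vegetated":
        cost += segment.length * (1.0 - segment.mean_greenness) / 2.0
    elif profile.env_pref == "avoid_accidents":
        cost += segment.accident_count
    return cost


# ---------------------------------------------------------------------------
# Routes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RouteLeg:
    """One traversed (possibly partial) link of a route.

    ``frac_start``/``frac_end`` are fractions of the link measured along the
    direction of travel (0 = entry endpoint, 1 = far endpoint).
    """

    segment_id: str
    direction: str
    frac_start: float
    frac_end: float
    cost: float

    def length(self, network: RoadNetwork) -> float:
        return network[self.segment_id].length * abs(self.frac_end - self.frac_start)

    def rise(self, network: RoadNetwork) -> float:
        """Signed altitude change over the traversed portion (meters)."""
        seg = network[self.segment_id]
        dz = seg.altitude_b - seg.altitude_a
        if self.direction == "b_to_a":
            dz = -dz
        return dz * (self.frac_end - self.frac_start)

    def geometry(self, network: RoadNetwork) -> list[tuple[float, float]]:
        seg = network[self.segment_id]
        length = seg.length
        if self.direction == "a_to_b":
            s, e = self.frac_start * length, self.frac_end * length
        else:
            s, e = (1 - self.frac_start) * length, (1 - self.frac_end) * length
        part = substring(seg.line, s, e)
        return [(p[0], p[1]) for p in part.coords]


@dataclass(frozen=True)
class Route:
    """An ordered directed link sequence with per-leg traversal fractions."""

    legs_spec: tuple[tuple[str, str, float, float, float], ...]
    total_impedance: float
    feasible: bool
    reason: str | None = None

    @property
    def links(self) -> tuple[tuple[str, str], ...]:
        return tuple((s, d) for s, d, *_ in self.legs_spec)

    def legs(self, network: RoadNetwork) -> list[RouteLeg]:
        return [
            RouteLeg(seg_id, direction, fs, fe, cost)
            for seg_id, direction, fs, fe, cost in self.legs_spec
        ]

    def length_m(self, network: RoadNetwork) -> float:
        return sum(leg.length(network) for leg in self.legs(network))

    @staticmethod
    def infeasible(reason: str) -> "Route":
        return Route(legs_spec=(), total_impedance=math.inf, feasible=False,
                     reason=reason)


# ---------------------------------------------------------------------------
# Search machinery
# ---------------------------------------------------------------------------

_DIR_FROM_NODE = {"a": "a_to_b", "b": "b_to_a"}


def _entry_directions(seg: RoadSegment, node) -> list[str]:
    """Travel directions that enter ``seg`` at ``node`` (loops yield both)."""
    key = node_key(node)
    dirs = []
    if key == node_key(seg.a):
        dirs.append("a_to_b")
    if key == node_key(seg.b):
        dirs.append("b_to_a")
    return dirs


def _travel_frac(seg: RoadSegment, offset_m: float, direction: str) -> float:
    """Travel-direction fraction of a point at polyline offset (from a)."""
    f = offset_m / seg.length
    return f if direction == "a_to_b" else 1.0 - f


def _far_node(seg: RoadSegment, direction: str):
    return seg.b if direction == "a_to_b" else seg.a


@dataclass
class _SearchProblem:
    """Snapped, slope-filtered, box-restricted instance shared by both
    the production search and the exhaustive oracle."""

    network: RoadNetwork
    profile: PreferenceProfile
    start_seg: str
    start_off: float
    end_seg: str
    end_off: float

    def initial_states(self) -> list[tuple[str, str, float, float]]:
        """(seg, direction, frac_start, partial_cost) options leaving the origin."""
        seg = self.network[self.start_seg]
        out = []
        for direction in ("a_to_b", "b_to_a"):
            if not seg.allows(self.profile.mode, direction):
                continue
            fs = _travel_frac(seg, self.start_off, direction)
            cost = link_cost(seg, direction, self.profile) * (1.0 - fs)
            out.append((self.start_seg, direction, fs, cost))
        return out

    def end_entries(self, node) -> list[tuple[str, float, float]]:
        """(direction, frac_end, partial_cost) ways to reach the destination
        point by entering the destination link at ``node``."""
        seg = self.network[self.end_seg]
        out = []
        for direction in _entry_directions(seg, node):
            if not seg.allows(self.profile.mode, direction):
                continue
            fe = _travel_frac(seg, self.end_off, direction)
            cost = link_cost(seg, direction, self.profile) * fe
            out.append((direction, fe, cost))
        return out

    def direct_legs(self) -> tuple[tuple, float] | None:
        """Single-link traversal when origin and destination share a link."""
        if self.start_seg != self.end_seg:
            return None
        seg = self.network[self.start_seg]
        if self.end_off >= self.start_off:
            direction, lo, hi = "a_to_b", self.start_off, self.end_off
        else:
            direction, lo, hi = "b_to_a", self.end_off, self.start_off
        if not seg.allows(self.profile.mode, direction) and hi > lo:
            return None
        frac = (hi - lo) / seg.length
        if frac == 0:
            direction = "a_to_b" if seg.allows(self.profile.mode, "a_to_b") else "b_to_a"
            if not seg.allows(self.profile.mode, direction):
                return None
        cost = link_cost(seg, direction, self.profile) * frac
        fs = _travel_frac(seg, self.start_off, direction)
        fe = _travel_frac(seg, self.end_off, direction)
        leg = (self.start_seg, direction, fs, fe, cost)
        return leg, cost

    def successors(self, seg_id: str, direction: str):
        """Adjacent travelable link states reachable past the far node."""
        seg = self.network[seg_id]
        node = _far_node(seg, direction)
        for nb_id in self.network.incident(node):
            nb = self.network[nb_id]
            for nb_dir in _entry_directions(nb, node):
                if nb_id == seg_id and nb_dir == direction:
                    continue  # no re-traversing the same state
                if nb.allows(self.profile.mode, nb_dir):
                    yield nb_id, nb_dir, link_cost(nb, nb_dir, self.profile)


def _prepare(
    network: RoadNetwork,
    start,
    end,
    profile: PreferenceProfile,
    buffer_m: float,
    use_box: bool,
) -> _SearchProblem | Route:
    if len(network) == 0:
        raise GeodataError("cannot route on an empty network")
    start_seg, start_off, _ = nearest_segment(network, start)
    end_seg, end_off, _ = nearest_segment(network, end)
    working = filter_by_slope(network, profile.max_gradient)
    if use_box:
        working = subset_network(working, make_bounding_box(start, end, buffer_m))
    for which, seg_id in (("start", start_seg), ("end", end_seg)):
        if seg_id not in working:
            return Route.infeasible(
                f"{which} snaps to segment {seg_id!r} excluded by the slope"
                " filter or the bounding box"
            )
        if profile.mode not in working[seg_id].modes_allowed:
            return Route.infeasible(
                f"{which} segment {seg_id!r} not travelable by {profile.mode}"
            )
    return _SearchProblem(working, profile, start_seg, start_off, end_seg, end_off)


def find_route(
    network: RoadNetwork,
    start,
    end,
    profile: PreferenceProfile,
    buffer_m: float = HALF_MILE_M,
    use_box: bool = True,
) -> Route:
    """Least-impedance route between two points.

    Endpoints snap to their nearest links; the search is restricted to links
    intersecting the buffered bounding box and to links within any slope
    ceiling. Returns an infeasible Route (with a reason) when origin and
    destination cannot be joined inside the box. Ties on impedance are
    broken toward fewer links, then lower link ids.
    """
    prob = _prepare(network, start, end, profile, buffer_m, use_box)
    if isinstance(prob, Route):
        return prob

    # Priority entries: (cost, hops, tiebreak-id, state). The destination is
    # a virtual state entered by partially traversing the destination link.
    heap: list = []
    best_seen: dict = {}
    pred: dict = {}
    counter = 0

    direct = prob.direct_legs()
    if direct is not None:
        leg, cost = direct
        heapq.heappush(heap, (cost, 1, "", counter, "END", ("direct", leg)))
        counter += 1

    for seg_id, direction, fs, cost in prob.initial_states():
        state = (seg_id, direction)
        heapq.heappush(heap, (cost, 1, seg_id, counter, state, ("start", fs)))
        counter += 1

    settled: set = set()
    while heap:
        cost, hops, _, _, state, via = heapq.heappop(heap)
        if state in settled:
            continue
        settled.add(state)
        pred[state] = via
        if state == "END":
            return _reconstruct(prob, pred, cost)
        seg_id, direction = state
        node = _far_node(prob.network[seg_id], direction)
        for e_dir, fe, e_cost in prob.end_entries(node):
            if "END" not in settled:
                heapq.heappush(
                    heap,
                    (cost + e_cost, hops + 1, prob.end_seg, counter, "END",
                     ("goal", state, e_dir, fe)),
                )
                counter += 1
        for nb_id, nb_dir, nb_cost in prob.successors(seg_id, direction):
            nxt = (nb_id, nb_dir)
            if nxt in settled:
                continue
            total = cost + nb_cost
            if nxt not in best_seen or total < best_seen[nxt]:
                best_seen[nxt] = total
                heapq.heappush(
                    heap, (total, hops + 1, nb_id, counter, nxt, ("step", state))
                )
                counter += 1
    return Route.infeasible("no direct route: frontier exhausted inside the box")


def _reconstruct(prob: _SearchProblem, pred: dict, total: float) -> Route:
    via = pred["END"]
    if via[0] == "direct":
        return Route(legs_spec=(via[1],), total_impedance=total, feasible=True)
    _, last_state, e_dir, fe = via
    end_seg = prob.network[prob.end_seg]
    legs = [(prob.end_seg, e_dir, 0.0, fe, link_cost(end_seg, e_dir, prob.profile) * fe)]
    state = last_state
    while True:
        via = pred[state]
        seg_id, direction = state
        seg = prob.network[seg_id]
        full = link_cost(seg, direction, prob.profile)
        if via[0] == "start":
            fs = via[1]
            legs.append((seg_id, direction, fs, 1.0, full * (1.0 - fs)))
            break
        legs.append((seg_id, direction, 0.0, 1.0, full))
        state = via[1]
    legs.reverse()
    return Route(legs_spec=tuple(legs), total_impedance=total, feasible=True)


# ---------------------------------------------------------------------------
# Exhaustive oracle (tests only)
# ---------------------------------------------------------------------------


def oracle_route(
    network: RoadNetwork,
    start,
    end,
    profile: PreferenceProfile,
    buffer_m: float = HALF_MILE_M,
    use_box: bool = True,
    max_link_states: int = 60,
) -> Route:
    """Minimal-impedance route by exhaustive enumeration of simple directed
    link paths (with cost-bound pruning; exact because all costs are > 0).

    Intended as an independent correctness oracle on small networks; refuses
    graphs with more than ``max_link_states`` directed link states.
    """
    prob = _prepare(network, start, end, profile, buffer_m, use_box)
    if isinstance(prob, Route):
        return prob
    if 2 * len(prob.network) > max_link_states:
        raise GeodataError(
            f"oracle refuses {2 * len(prob.network)} link states (cap {max_link_states})"
        )

    best = {"cost": math.inf, "legs": None}

    direct = prob.direct_legs()
    if direct is not None:
        leg, cost = direct
        best["cost"], best["legs"] = cost, [leg]

    def visit(state, cum, path_legs, visited):
        seg_id, direction = state
        node = _far_node(prob.network[seg_id], direction)
        for e_dir, fe, e_cost in prob.end_entries(node):
            total = cum + e_cost
            if total < best["cost"]:
                best["cost"] = total
                best["legs"] = path_legs + [
                    (prob.end_seg, e_dir, 0.0, fe, e_cost)
                ]
        for nb_id, nb_dir, nb_cost in prob.successors(seg_id, direction):
            nxt = (nb_id, nb_dir)
            if nxt in visited:
                continue
            total = cum + nb_cost
            if total >= best["cost"]:
                continue
            visit(
                nxt,
                total,
                path_legs + [(nb_id, nb_dir, 0.0, 1.0, nb_cost)],
                visited | {nxt},
            )

    for seg_id, direction, fs, cost in prob.initial_states():
        if cost < best["cost"]:
            state = (seg_id, direction)
            visit(state, cost, [(seg_id, direction, fs, 1.0, cost)], {state})

    if best["legs"] is None:
        return Route.infeasible("no direct route: frontier exhausted inside the box")
    return Route(
        legs_spec=tuple(best["legs"]), total_impedance=best["cost"], feasible=True
    )
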