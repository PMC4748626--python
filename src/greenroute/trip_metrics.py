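"""Derived trip outputs: time, length, elevation gain, CO2, calories,
exposure summaries, slope color coding and turn-by-turn directions.

CO2 accounting assumes a typical passenger car emits 5 tons of CO2 over an
annual travel distance of 20,000 km, i.e. 0.25 kg per km travelled; a car
trip *emits* length x 0.25 kg while a bicycling or walking trip *saves* the
same amount. Cycling energy expenditure uses 35 Cal per mile (21.75 Cal per
km, the metric equivalent); walking uses bodyweight in pounds x 0.853 x
distance in kilometers, with a 150 lb default body weight.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

from .geodata import RoadNetwork
from .routing import PreferenceProfile, Route

__all__ = [
    "MetricConstants",
    "TripSummary",
    "co2_for_trip",
    "co2_label",
    "calories_bike",
    "calories_walk",
    "trip_time",
    "elevation_gain",
    "exposure_summary",
    "directions",
    "slope_color_classes",
    "summarize_trip",
    "DEFAULT_SLOPE_BINS",
]


@dataclass(frozen=True)
class MetricConstants:
    co2_kg_per_km: float = 0.25
    bike_cal_per_km: float = 21.75
    bike_cal_per_mile: float = 35.0
    walk_cal_coeff: float = 0.853  # Cal per lb per km
    default_body_weight_lb: float = 150.0
    km_per_mile: float = 1.609344


CONSTANTS = MetricConstants()

#: slope-ratio bin edges for route color coding: 0-2%, 2-5%, 5-10%, >10%
DEFAULT_SLOPE_BINS = (0.02, 0.05, 0.10)


def co2_for_trip(length_km: float, mode: str) -> float | None:
    """CO2 in kg for a trip: emitted when driving, saved when bike/walk.

    Transit emissions are not estimated (returns None).
    """
    if length_km < 0:
        raise ValueError("trip length must be >= 0")
    if mode == "transit":
        return None
    return length_km * CONSTANTS.co2_kg_per_km


def co2_label(mode: str) -> str | None:
    if mode == "drive":
        return "emitted"
    if mode in ("bike", "walk"):
        return "saved"
    return None


def calories_bike(length_km: float) -> float:
    """Cycling energy expenditure: 21.75 Cal per km (35 Cal per mile)."""
    if length_km < 0:
        raise ValueError("trip length must be >= 0")
    return length_km * CONSTANTS.bike_cal_per_km


def calories_walk(
    length_km: float, body_weight_lb: float = CONSTANTS.default_body_weight_lb
) -> float:
    """Walking energy expenditure: bodyweight (lb) x 0.853 x distance (km)."""
    if length_km < 0:
        raise ValueError("trip length must be >= 0")
    return body_weight_lb * CONSTANTS.walk_cal_coeff * length_km


def trip_time(length_km: float, speed_kmh: float) -> float:
    """Travel time in minutes at a constant speed."""
    if speed_kmh <= 0:
        raise ValueError("speed must be > 0")
    return 60.0 * length_km / speed_kmh


def elevation_gain(route: Route, network: RoadNetwork) -> float:
    """Total elevation increased over the trip: sum of positive rises (m).

    Descents do not offset climbs; an out-and-back over one hill gains a
    full ascent.
    """
    return sum(max(0.0, leg.rise(network)) for leg in route.legs(network))


def exposure_summary(
    route: Route, network: RoadNetwork
) -> tuple[float, float, float]:
    """(total inhalation proxy, mean pollution, mean greenness) of a route.

    The inhalation proxy is sum_i length_i x mean pollution_i over traversed
    links (partial links contribute their traversed length); the means are
    length-weighted.
    """
    total_len = total_pol = weighted_pol = weighted_grn = 0.0
    for leg in route.legs(network):
        seg = network[leg.segment_id]
        length = leg.length(network)
        total_len += length
        total_pol += length * seg.mean_pollution
        weighted_pol += length * seg.mean_pollution
        weighted_grn += length * seg.mean_greenness
    if total_len == 0:
        return 0.0, 0.0, 0.0
    return total_pol, weighted_pol / total_len, weighted_grn / total_len


def directions(route: Route, network: RoadNetwork) -> list[tuple[str, float]]:
    """Roadway-by-roadway directions: (road name or id, traversed length m)."""
    out = []
    for leg in route.legs(network):
        seg = network[leg.segment_id]
        out.append((seg.name or seg.id, leg.length(network)))
    return out


def slope_color_classes(
    route: Route, network: RoadNetwork, bins: tuple[float, ...] = DEFAULT_SLOPE_BINS
) -> list[int]:
    """Per-traversed-link slope class (1 = flattest bin) for color coding."""
    classes = []
    for leg in route.legs(network):
        g = network[leg.segment_id].gradient
        cls = 1
        for edge in bins:
            if g > edge:
                cls += 1
        classes.append(cls)
    return classes


@dataclass
class TripSummary:
    """The trip planner output block for one computed route."""

    mode: str
    length_km: float
    time_min: float
    elevation_gain_m: float
    co2_kg: float | None
    co2_label: str | None
    calories: float | None
    mean_pollution: float
    total_inhalation_proxy: float
    mean_greenness: float
    accident_total: int
    directions: list[tuple[str, float]]
    slope_classes: list[int]
    total_impedance: float

    def to_json(self, path: str | Path | None = None) -> str:
        doc = asdict(self)
        doc["directions"] = [list(d) for d in doc["directions"]]
        text = json.dumps(doc, sort_keys=True, indent=1)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def format_block(self) -> str:
        lines = [
            f"mode:            {self.mode}",
            f"route length:    {self.length_km:.3f} km",
            f"trip time:       {self.time_min:.1f} min",
            f"elevation gain:  {self.elevation_gain_m:.1f} m",
        ]
        if self.co2_kg is not None:
            lines.append(f"CO2 {self.co2_label}:     {self.co2_kg:.3f} kg")
        if self.calories is not None:
            lines.append(f"calories:        {self.calories:.1f} Cal")
        lines += [
            f"mean pollution:  {self.mean_pollution:.2f}",
            f"inhalation:      {self.total_inhalation_proxy:.1f} (m x conc)",
            f"mean greenness:  {self.mean_greenness:.3f} (NDVI)",
            f"accidents:       {self.accident_total}",
            "directions:",
        ]
        for name, length in self.directions:
            lines.append(f"  {name}  {length:.0f} m")
        return "\n".join(lines)


def summarize_trip(
    route: Route, network: RoadNetwork, profile: PreferenceProfile
) -> TripSummary:
    """Assemble the full output block for a feasible route."""
    if not route.feasible:
        raise ValueError(f"cannot summarize infeasible route: {route.reason}")
    length_km = route.length_m(network) / 1000.0
    total_inh, mean_pol, mean_grn = exposure_summary(route, network)
    accident_total = sum(
        network[leg.segment_id].accident_count for leg in route.legs(network)
    )
    if profile.mode == "bike":
        calories = calories_bike(length_km)
    elif profile.mode == "walk":
        calories = calories_walk(length_km, profile.body_weight_lb)
    else:
        calories = None
    return TripSummary(
        mode=profile.mode,
        length_km=length_km,
        time_min=trip_time(length_km, profile.speed_kmh),
        elevation_gain_m=elevation_gain(route, network),
        co2_kg=co2_for_trip(length_km, profile.mode),
        co2_label=co2_label(profile.mode),
        calories=calories,
        mean_pollution=mean_pol,
        total_inhalation_proxy=total_inh,
        mean_greenness=mean_grn,
        accident_total=accident_total,
        directions=directions(route, network),
        slope_classes=slope_color_classes(route, network),
        total_impedance=route.total_impedance,
    )
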