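"""Seedable generators for synthetic urban worlds.

Emulates the structure of the data the engine consumes — a gridded road
network with five road classes and terrain-derived slopes, a traffic
pollution surface elevated near highways, red/near-infrared reflectance
surfaces with a high-greenness park patch, category-labelled amenity points
with popup metadata, and pedestrian/bicyclist accident records snapped to
segments — so every module is testable without any external download.
Everything is fully deterministic under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.geometry import Point

from .geodata import (
    ROAD_CLASSES,
    AccidentRecord,
    Amenity,
    Raster,
    RoadNetwork,
    RoadSegment,
)
from .surfaces import sample_segment_mean

__all__ = [
    "SyntheticConfig",
    "make_grid_network",
    "make_pollution_surface",
    "make_greenness_surface",
    "park_extent",
    "scatter_amenities",
    "scatter_accidents",
    "make_world",
]

_DEFAULT_CLASS_MIX = {
    "bike_designated": 0.10,
    "bike_alternative": 0.15,
    "connecting": 0.25,
    "local": 0.45,
    "highway": 0.05,
}

_DEFAULT_AMENITY_COUNTS = {
    "fruit_veg": 6,
    "farmers_market": 2,
    "grocery": 8,
    "restaurant": 10,
    "park": 4,
    "recreation_general": 5,
    "recreation_detailed": 3,
    "school": 4,
    "healthcare": 3,
}

_STREETS = ("Main", "Oak", "Cedar", "Palm", "Willow", "Magnolia", "Sunset", "Vine")
_CITIES = ("Northside", "Riverton", "Eastgate", "Lakeview")
_PROGRAMS = ("swimming", "basketball", "soccer", "aerobics", "tennis", "dance")


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic world.

    A ``rows x cols`` lattice of intersections spaced ``spacing_m`` apart
    (100 m, a typical urban block); road classes drawn from ``class_mix``
    except on ``highway_rows``, whose horizontal segments are highways.
    Pollution decays exponentially away from highways with length scale
    ``pollution_decay_m``; accidents are Poisson per segment with mean
    ``accident_rate`` on highways and a quarter of it elsewhere.
    """

    seed: int = 0
    rows: int = 10
    cols: int = 10
    spacing_m: float = 100.0
    class_mix: dict = field(default_factory=lambda: dict(_DEFAULT_CLASS_MIX))
    highway_rows: tuple[int, ...] | None = None  # None -> middle row
    terrain: str = "random_smooth"  # flat | ridge | random_smooth
    terrain_amplitude_m: float = 30.0
    one_way_fraction: float = 0.1
    pollution_baseline: float = 10.0
    pollution_peak: float = 40.0
    pollution_decay_m: float = 200.0
    raster_cell_m: float = 30.0
    amenity_counts: dict = field(default_factory=lambda: dict(_DEFAULT_AMENITY_COUNTS))
    accident_rate: float = 1.5

    def __post_init__(self) -> None:
        total = sum(self.class_mix.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"class_mix must sum to 1, got {total}")
        if self.highway_rows is None:
            self.highway_rows = (self.rows // 2,)
        if self.terrain not in ("flat", "ridge", "random_smooth"):
            raise ValueError(f"unknown terrain {self.terrain!r}")
        if any(c < 0 for c in self.amenity_counts.values()) or self.accident_rate < 0:
            raise ValueError("counts and rates must be >= 0")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        return (0.0, 0.0, (self.cols - 1) * self.spacing_m, (self.rows - 1) * self.spacing_m)


def _terrain_fn(config: SyntheticConfig):
    x0, y0, x1, y1 = config.extent
    width = max(x1 - x0, 1.0)
    height = max(y1 - y0, 1.0)
    amp = config.terrain_amplitude_m
    if config.terrain == "flat":
        return lambda x, y: 0.0
    if config.terrain == "ridge":
        # a single north-south ridge along the middle column
        cx = (x0 + x1) / 2.0
        return lambda x, y: amp * math.exp(-(((x - cx) / (width / 4.0)) ** 2))
    rng = np.random.default_rng(config.seed + 101)
    n_waves = 4
    fx = rng.uniform(0.5, 1.5, n_waves) / width
    fy = rng.uniform(0.5, 1.5, n_waves) / height
    phase = rng.uniform(0, 2 * math.pi, n_waves)
    coef = rng.uniform(0.5, 1.0, n_waves)

    def alt(x, y):
        s = sum(
            c * math.sin(2 * math.pi * (fx[k] * x + fy[k] * y) + phase[k])
            for k, c in enumerate(coef)
        )
        return amp * (s / (2.0 * n_waves) + 0.5)

    return alt


def make_grid_network(config: SyntheticConfig) -> RoadNetwork:
    """A rows x cols lattice road network (2*r*c - r - c segments)."""
    rng = np.random.default_rng(config.seed)
    alt = _terrain_fn(config)
    classes = sorted(config.class_mix)
    probs = [config.class_mix[c] for c in classes]
    segments = []

    def add(i0, j0, i1, j1, horizontal_row):
        a = (j0 * config.spacing_m, i0 * config.spacing_m)
        b = (j1 * config.spacing_m, i1 * config.spacing_m)
        if horizontal_row is not None and horizontal_row in config.highway_rows:
            cls = "highway"
        else:
            cls = classes[rng.choice(len(classes), p=probs)]
        one_way = "none"
        if rng.random() < config.one_way_fraction:
            one_way = "a_to_b" if rng.random() < 0.5 else "b_to_a"
        modes = frozenset({"bike", "walk"}) if cls == "bike_designated" else frozenset(
            {"drive", "bike", "walk"}
        )
        segments.append(
            RoadSegment(
                id=f"s{len(segments):04d}",
                polyline=(a, b),
                road_class=cls,
                one_way=one_way,
                altitude_a=alt(*a),
                altitude_b=alt(*b),
                modes_allowed=modes,
                name=f"{_STREETS[len(segments) % len(_STREETS)]} "
                f"{'Ave' if horizontal_row is None else 'St'} {len(segments)}",
            )
        )

    for i in range(config.rows):
        for j in range(config.cols - 1):
            add(i, j, i, j + 1, horizontal_row=i)
    for i in range(config.rows - 1):
        for j in range(config.cols):
            add(i, j, i + 1, j, horizontal_row=None)
    return RoadNetwork(segments, crs_note="synthetic planar meters")


def _raster_frame(config: SyntheticConfig) -> tuple[float, float, int, int]:
    x0, y0, x1, y1 = config.extent
    cell = config.raster_cell_m
    margin = cell  # one cell of slack so edge segments sample inside
    n_cols = int(math.ceil((x1 - x0 + 2 * margin) / cell))
    n_rows = int(math.ceil((y1 - y0 + 2 * margin) / cell))
    return x0 - margin, y0 - margin, n_rows, n_cols


def make_pollution_surface(network: RoadNetwork, config: SyntheticConfig) -> Raster:
    """Traffic pollution: baseline plus an exponential plume off highways.

    value(cell) = baseline + (peak - baseline) * exp(-d / decay) with d the
    distance from the cell center to the nearest highway segment.
    """
    ox, oy, n_rows, n_cols = _raster_frame(config)
    cell = config.raster_cell_m
    highways = [seg.line for seg in network if seg.road_class == "highway"]
    values = np.full((n_rows, n_cols), config.pollution_baseline, dtype=float)
    if highways:
        for r in range(n_rows):
            y = oy + (n_rows - 1 - r + 0.5) * cell
            for c in range(n_cols):
                p = Point(ox + (c + 0.5) * cell, y)
                d = min(line.distance(p) for line in highways)
                values[r, c] = config.pollution_baseline + (
                    config.pollution_peak - config.pollution_baseline
                ) * math.exp(-d / config.pollution_decay_m)
    return Raster(ox, oy, cell, values)


def park_extent(config: SyntheticConfig) -> tuple[float, float, float, float]:
    """The rectangle of the designated high-greenness park patch."""
    x0, y0, x1, y1 = config.extent
    w, h = x1 - x0, y1 - y0
    return (x0 + 0.1 * w, y0 + 0.6 * h, x0 + 0.35 * w, y0 + 0.9 * h)


def _smooth_field(rng, n_rows, n_cols, lo, hi):
    yy, xx = np.mgrid[0:n_rows, 0:n_cols]
    out = np.zeros((n_rows, n_cols))
    for _ in range(3):
        fx = rng.uniform(0.5, 2.0) / max(n_cols, 1)
        fy = rng.uniform(0.5, 2.0) / max(n_rows, 1)
        ph = rng.uniform(0, 2 * math.pi)
        out += np.sin(2 * math.pi * (fx * xx + fy * yy) + ph)
    out = (out - out.min()) / max(out.max() - out.min(), 1e-12)
    return lo + out * (hi - lo)


def make_greenness_surface(config: SyntheticConfig) -> tuple[Raster, Raster]:
    """(NIR, RED) reflectance rasters in [0, 1] with a green park patch.

    Inside the park patch NIR is high and RED low, so its NDVI exceeds the
    surroundings (live vegetation is bright in near-infrared, dark in red).
    """
    ox, oy, n_rows, n_cols = _raster_frame(config)
    cell = config.raster_cell_m
    rng = np.random.default_rng(config.seed + 202)
    nir = _smooth_field(rng, n_rows, n_cols, 0.25, 0.45)
    red = _smooth_field(rng, n_rows, n_cols, 0.20, 0.40)
    px0, py0, px1, py1 = park_extent(config)
    for r in range(n_rows):
        y = oy + (n_rows - 1 - r + 0.5) * cell
        for c in range(n_cols):
            x = ox + (c + 0.5) * cell
            if px0 <= x <= px1 and py0 <= y <= py1:
                nir[r, c] = 0.75
                red[r, c] = 0.08
    return Raster(ox, oy, cell, nir), Raster(ox, oy, cell, red)


def scatter_amenities(
    config: SyntheticConfig, extent: tuple[float, float, float, float] | None = None
) -> list[Amenity]:
    """Uniform amenity points per category with plausible popup metadata."""
    x0, y0, x1, y1 = extent if extent is not None else config.extent
    rng = np.random.default_rng(config.seed + 303)
    out: list[Amenity] = []
    for category in sorted(config.amenity_counts):
        for i in range(config.amenity_counts[category]):
            loc = (rng.uniform(x0, x1), rng.uniform(y0, y1))
            street = _STREETS[int(rng.integers(len(_STREETS)))]
            city = _CITIES[int(rng.integers(len(_CITIES)))]
            kwargs: dict = {}
            if category == "farmers_market":
                kwargs["opening_hours"] = "Sat 8:00-13:00"
                kwargs["website"] = f"https://market-{i}.example.org"
            if category in ("recreation_general", "recreation_detailed"):
                n_prog = int(rng.integers(1, 4))
                progs = rng.choice(len(_PROGRAMS), size=n_prog, replace=False)
                kwargs["program_types"] = tuple(_PROGRAMS[k] for k in sorted(progs))
                kwargs["city"] = city
            if category == "recreation_detailed":
                kwargs["met_value"] = round(float(rng.uniform(3.1, 8.0)), 1)
            out.append(
                Amenity(
                    id=f"{category}-{i:03d}",
                    category=category,
                    location=loc,
                    name=f"{city} {category.replace('_', ' ')} {i}",
                    street_address=f"{int(rng.integers(100, 9900))} {street} St",
                    phone=f"(555) 01{int(rng.integers(0, 10))}-"
                    f"{int(rng.integers(0, 10000)):04d}",
                    **kwargs,
                )
            )
    return out


def scatter_accidents(
    network: RoadNetwork, config: SyntheticConfig
) -> tuple[RoadNetwork, list[AccidentRecord]]:
    """Poisson accidents per segment (rate boosted on highways), snapped to
    segment midpoints; returns the network with accident_count updated so
    that sum(accident_count) == number of records."""
    rng = np.random.default_rng(config.seed + 404)
    records: list[AccidentRecord] = []
    new_segments = []
    for seg_id in sorted(network.segments):
        seg = network[seg_id]
        rate = config.accident_rate if seg.road_class == "highway" else config.accident_rate / 4.0
        count = int(rng.poisson(rate)) if rate > 0 else 0
        mid = seg.line.interpolate(0.5, normalized=True)
        for k in range(count):
            involves = [
                frozenset({"pedestrian"}),
                frozenset({"bicyclist"}),
                frozenset({"pedestrian", "bicyclist"}),
            ][int(rng.integers(3))]
            records.append(
                AccidentRecord(
                    id=f"acc-{seg.id}-{k}",
                    location=(mid.x, mid.y),
                    year=int(rng.integers(2005, 2008)),
                    involves=involves,
                )
            )
        new_segments.append(replace(seg, accident_count=count))
    return network.replace_segments(new_segments), records


def make_world(config: SyntheticConfig):
    """Generate a complete consistent world.

    Returns a dict with keys ``network`` (pollution/greenness sampled onto
    segments, accident counts attached), ``nir``, ``red``, ``pollution``
    (rasters), ``amenities`` and ``accidents``.
    """
    from .surfaces import ndvi  # local import to avoid cycle at module load

    network = make_grid_network(config)
    pollution = make_pollution_surface(network, config)
    nir, red = make_greenness_surface(config)
    green = ndvi(nir, red)
    annotated = []
    for seg_id in sorted(network.segments):
        seg = network[seg_id]
        pol = sample_segment_mean(pollution, seg)
        grn = sample_segment_mean(green, seg)
        annotated.append(
            replace(
                seg,
                mean_pollution=pol if pol is not None else 0.0,
                mean_greenness=grn if grn is not None else 0.0,
            )
        )
    network = network.replace_segments(annotated)
    network, accidents = scatter_accidents(network, config)
    amenities = scatter_amenities(config)
    return {
        "network": network,
        "nir": nir,
        "red": red,
        "pollution": pollution,
        "greenness": green,
        "amenities": amenities,
        "accidents": accidents,
    }
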