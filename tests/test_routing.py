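import itertools
import math

import pytest

from greenroute.geodata import RoadNetwork, RoadSegment
from greenroute.routing import (
    EPSILON,
    HALF_MILE_M,
    BoundingBox,
    PreferenceProfile,
    filter_by_slope,
    find_route,
    link_cost,
    make_bounding_box,
    oracle_route,
    subset_network,
)

from conftest import random_small_network


def _seg(sid, p0, p1, **kw):
    kw.setdefault("road_class", "local")
    return RoadSegment(id=sid, polyline=(p0, p1), **kw)


def _impedances_match(a, b):
    assert a.feasible == b.feasible
    if a.feasible:
        assert a.total_impedance == pytest.approx(b.total_impedance, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------- bounding box

def test_bounding_box_half_mile_default():
    bb = make_bounding_box((0, 0), (1000, 1000))
    assert (bb.min_x, bb.min_y, bb.max_x, bb.max_y) == pytest.approx(
        (-804.672, -804.672, 1804.672, 1804.672)
    )


def test_bounding_box_degenerate():
    bb = make_bounding_box((5, 5), (5, 5), buffer=0)
    assert (bb.min_x, bb.min_y, bb.max_x, bb.max_y) == (5, 5, 5, 5)


def test_bounding_box_contains_endpoints():
    import numpy as np

    rng = np.random.default_rng(0)
    for _ in range(20):
        s, e = rng.uniform(-1e4, 1e4, 2), rng.uniform(-1e4, 1e4, 2)
        bb = make_bounding_box(s, e, buffer=float(rng.uniform(0, 1e3)))
        assert bb.contains(s) and bb.contains(e)


def test_subset_network_extremes(square_loop):
    full = subset_network(square_loop, BoundingBox(-10, -10, 110, 110))
    assert set(full.segments) == set(square_loop.segments)
    empty = subset_network(square_loop, BoundingBox(1e6, 1e6, 2e6, 2e6))
    assert len(empty) == 0


def test_subset_network_matches_scan():
    import numpy as np
    from shapely.geometry import box as shapely_box

    net, _, _ = random_small_network(17)
    rng = np.random.default_rng(5)
    for _ in range(10):
        xs = np.sort(rng.uniform(-100, 600, 2))
        ys = np.sort(rng.uniform(-100, 400, 2))
        bb = BoundingBox(xs[0], ys[0], xs[1], ys[1])
        got = set(subset_network(net, bb).segments)
        rect = shapely_box(xs[0], ys[0], xs[1], ys[1])
        assert got == {s.id for s in net if s.line.intersects(rect)}


# ---------------------------------------------------------------- link costs

def test_pollution_cost_is_length_times_concentration():
    seg = _seg("p", (0, 0), (1000, 0), mean_pollution=10.0)
    cost = link_cost(seg, "a_to_b", PreferenceProfile(env_pref="low_pollution"))
    # eps * length * class multiplier adds only a tie-breaking sliver
    assert cost == pytest.approx(10000.0, abs=0.01)


def test_elevation_cost_counts_only_rises():
    seg = _seg("h", (0, 0), (100, 0), altitude_a=20.0, altitude_b=5.0)
    profile = PreferenceProfile(env_pref="avoid_elevation")
    downhill = link_cost(seg, "a_to_b", profile)
    uphill = link_cost(seg, "b_to_a", profile)
    assert downhill == pytest.approx(0.0, abs=0.01)
    assert uphill == pytest.approx(15.0, abs=0.01)


def test_accident_cost_is_count():
    seg = _seg("a", (0, 0), (500, 0), accident_count=3)
    cost = link_cost(seg, "a_to_b", PreferenceProfile(env_pref="avoid_accidents"))
    assert cost == pytest.approx(3.0, abs=0.01)


def test_plain_cost_is_length_times_class_multiplier():
    seg = _seg("n", (0, 0), (250, 0), road_class="local")
    profile = PreferenceProfile(mode="bike", class_weights={"local": 5})
    assert link_cost(seg, "a_to_b", profile) == pytest.approx(500.0)


def test_most_friendly_sharpens_class_priority():
    seg = _seg("b", (0, 0), (100, 0), road_class="highway")
    base = PreferenceProfile(mode="bike", class_weights={"highway": 2})
    sharp = PreferenceProfile(
        mode="bike", bike_style="most_friendly", class_weights={"highway": 2}
    )
    assert link_cost(seg, "a_to_b", sharp) == pytest.approx(
        link_cost(seg, "a_to_b", base) * 5.0
    )


def test_inadmissible_traversal_raises():
    seg = _seg("o", (0, 0), (100, 0), one_way="a_to_b")
    with pytest.raises(ValueError):
        link_cost(seg, "b_to_a", PreferenceProfile())
    bike_only = _seg("m", (0, 0), (100, 0), modes_allowed=frozenset({"bike"}))
    with pytest.raises(ValueError):
        link_cost(bike_only, "a_to_b", PreferenceProfile(mode="drive"))


def test_all_costs_nonnegative_on_random_networks():
    for seed in range(10):
        net, _, _ = random_small_network(seed)
        profile = PreferenceProfile(env_pref="vegetated")
        for seg in net:
            for direction in ("a_to_b", "b_to_a"):
                if seg.allows("bike", direction):
                    assert link_cost(seg, direction, profile) >= 0


# ---------------------------------------------------------------- find_route

def test_same_segment_route(square_loop):
    profile = PreferenceProfile(mode="walk")
    route = find_route(square_loop, (20, 0), (80, 0), profile)
    assert route.feasible
    assert route.links == (("sq0", "a_to_b"),)
    net_len = route.length_m(square_loop)
    assert net_len == pytest.approx(60.0)


def test_uniform_grid_is_manhattan_shortest():
    segs = []
    n = 4
    for i in range(n):
        for j in range(n - 1):
            segs.append(_seg(f"h{i}{j}", (j * 100, i * 100), ((j + 1) * 100, i * 100)))
    for i in range(n - 1):
        for j in range(n):
            segs.append(_seg(f"v{i}{j}", (j * 100, i * 100), (j * 100, (i + 1) * 100)))
    net = RoadNetwork(segs)
    profile = PreferenceProfile(mode="walk", env_pref="none")
    route = find_route(net, (0, 0), (300, 300), profile)
    assert route.feasible
    # Manhattan distance 600 m at the walk local-road multiplier 10/8
    assert route.length_m(net) == pytest.approx(600.0)
    oracle = oracle_route(net, (0, 0), (300, 300), profile)
    _impedances_match(route, oracle)


def test_avoid_accidents_picks_accident_free_parallel():
    # two equal-length two-link paths from (0,0) to (200,0); the north one
    # carries 3 accidents on its first link
    segs = [
        _seg("s_a", (0, 0), (100, -50), accident_count=0),
        _seg("s_b", (100, -50), (200, 0), accident_count=0),
        _seg("n_a", (0, 0), (100, 50), accident_count=3),
        _seg("n_b", (100, 50), (200, 0), accident_count=0),
        _seg("in", (-100, 0), (0, 0)),
        _seg("out", (200, 0), (300, 0)),
    ]
    net = RoadNetwork(segs)
    profile = PreferenceProfile(env_pref="avoid_accidents")
    route = find_route(net, (-50, 0), (250, 0), profile)
    used = {sid for sid, _ in route.links}
    assert "n_a" not in used and "s_a" in used


def test_disconnected_components_infeasible():
    net = RoadNetwork([
        _seg("w", (0, 0), (100, 0)),
        _seg("e", (10000, 0), (10100, 0)),
    ])
    route = find_route(net, (50, 0), (10050, 0), PreferenceProfile(), use_box=False)
    assert not route.feasible
    assert "no direct route" in route.reason


def test_route_respects_one_way():
    # the only direct link is one-way against us; the detour must be used
    segs = [
        _seg("direct", (0, 0), (200, 0), one_way="b_to_a"),
        _seg("up", (0, 0), (0, 100)),
        _seg("across", (0, 100), (200, 100)),
        _seg("down", (200, 100), (200, 0)),
    ]
    net = RoadNetwork(segs)
    route = find_route(net, (0, 0), (200, 0), PreferenceProfile(mode="walk"))
    assert route.feasible
    assert ("direct", "a_to_b") not in route.links
    # with the flag flipped the direct link is used
    flipped = RoadNetwork([
        seg if seg.id != "direct" else _seg("direct", (0, 0), (200, 0), one_way="a_to_b")
        for seg in segs
    ])
    route2 = find_route(flipped, (0, 0), (200, 0), PreferenceProfile(mode="walk"))
    assert ("direct", "a_to_b") in route2.links


def test_cumulative_impedance_nondecreasing():
    net, start, end = random_small_network(23)
    profile = PreferenceProfile(mode="bike", env_pref="low_pollution")
    route = find_route(net, start, end, profile)
    if route.feasible:
        assert all(leg.cost >= 0 for leg in route.legs(net))
        assert sum(leg.cost for leg in route.legs(net)) == pytest.approx(
            route.total_impedance, rel=1e-9
        )


def test_weight_scale_invariance():
    """Doubling every class weight rescales impedance but not the path."""
    net, start, end = random_small_network(31)
    base = PreferenceProfile(
        mode="bike",
        class_weights={c: 2 for c in ("bike_designated", "bike_alternative",
                                      "connecting", "local", "highway")},
    )
    doubled = PreferenceProfile(
        mode="bike",
        class_weights={c: 4 for c in ("bike_designated", "bike_alternative",
                                      "connecting", "local", "highway")},
    )
    r1 = find_route(net, start, end, base)
    r2 = find_route(net, start, end, doubled)
    assert r1.feasible == r2.feasible
    if r1.feasible:
        assert r1.links == r2.links
        assert r1.total_impedance == pytest.approx(2 * r2.total_impedance)


def test_box_pruning_sound_when_route_fits():
    net, start, end = random_small_network(41)
    profile = PreferenceProfile(mode="walk")
    boxed = find_route(net, start, end, profile, use_box=True)
    unboxed = find_route(net, start, end, profile, use_box=False)
    # the half-mile box covers these small worlds entirely
    _impedances_match(boxed, unboxed)


def test_box_monotone_in_buffer():
    net, start, end = random_small_network(43)
    profile = PreferenceProfile(mode="bike")
    small = find_route(net, start, end, profile, buffer_m=200.0)
    large = find_route(net, start, end, profile, buffer_m=HALF_MILE_M)
    if small.feasible:
        assert large.feasible
        assert large.total_impedance <= small.total_impedance + 1e-9


# ---------------------------------------------------------------- slope filter

def test_slope_filter_identity_and_empty():
    net, _, _ = random_small_network(3)
    assert set(filter_by_slope(net, None).segments) == set(net.segments)
    steep = RoadNetwork([
        _seg("s1", (0, 0), (100, 0), altitude_a=0, altitude_b=30),
        _seg("s2", (100, 0), (200, 0), altitude_a=30, altitude_b=0),
    ])
    assert len(filter_by_slope(steep, 0.05)) == 0


def test_slope_filter_matches_manual_scan():
    net, _, _ = random_small_network(13)
    out = filter_by_slope(net, 0.1)
    assert set(out.segments) == {s.id for s in net if s.gradient <= 0.1}


def test_snap_to_slope_excluded_segment_is_infeasible():
    steep = _seg("st", (0, 0), (100, 0), altitude_a=0, altitude_b=50)
    flat = _seg("fl", (100, 0), (200, 0))
    net = RoadNetwork([steep, flat])
    profile = PreferenceProfile(mode="walk", max_gradient=0.1)
    route = find_route(net, (10, 0), (150, 0), profile)
    assert not route.feasible
    assert "slope" in route.reason


# ---------------------------------------------------------------- oracle

def test_oracle_single_edge():
    net = RoadNetwork([_seg("only", (0, 0), (100, 0))])
    route = oracle_route(net, (10, 0), (90, 0), PreferenceProfile(mode="walk"))
    assert route.feasible and route.links == (("only", "a_to_b"),)


def test_oracle_refuses_large_networks():
    from greenroute.geodata import GeodataError
    from greenroute.synthetic import SyntheticConfig, make_grid_network

    net = make_grid_network(SyntheticConfig(seed=0, rows=6, cols=6))
    with pytest.raises(GeodataError, match="refuses"):
        oracle_route(net, (0, 0), (500, 500), PreferenceProfile())


@pytest.mark.parametrize("seed", range(12))
def test_search_matches_oracle_small_sample(seed):
    """Dijkstra impedance equals exhaustive enumeration on random worlds."""
    net, start, end = random_small_network(seed)
    for mode, pref in itertools.product(
        ("walk", "bike"), ("none", "low_pollution", "avoid_accidents")
    ):
        profile = PreferenceProfile(mode=mode, env_pref=pref)
        _impedances_match(
            find_route(net, start, end, profile),
            oracle_route(net, start, end, profile),
        )
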