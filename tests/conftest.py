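import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from greenroute.geodata import ROAD_CLASSES, RoadNetwork, RoadSegment

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def square_loop_segments(side=100.0):
    """Four segments forming a closed square loop."""
    corners = [(0, 0), (side, 0), (side, side), (0, side)]
    return [
        RoadSegment(
            id=f"sq{i}",
            polyline=(corners[i], corners[(i + 1) % 4]),
            road_class="local",
        )
        for i in range(4)
    ]


@pytest.fixture
def square_loop():
    return RoadNetwork(square_loop_segments())


def random_small_network(seed):
    """A random pruned lattice with <= 12 nodes and fully random attributes.

    Attributes (classes, one-way flags, altitudes, pollution, greenness,
    accident counts, allowed modes) are drawn independently so the router
    is exercised across all impedance terms.
    """
    rng = np.random.default_rng(seed)
    rows, cols = [(3, 3), (3, 4), (2, 5), (2, 6)][int(rng.integers(4))]
    spacing = 100.0
    edges = []
    for i in range(rows):
        for j in range(cols - 1):
            edges.append(((j, i), (j + 1, i)))
    for i in range(rows - 1):
        for j in range(cols):
            edges.append(((j, i), (j, i + 1)))
    segments = []
    for k, (a, b) in enumerate(edges):
        if rng.random() < 0.2:
            continue  # prune
        one_way = "none"
        if rng.random() < 0.2:
            one_way = "a_to_b" if rng.random() < 0.5 else "b_to_a"
        modes = {"drive", "bike", "walk"}
        if rng.random() < 0.1:
            modes.discard("drive")
        segments.append(
            RoadSegment(
                id=f"e{k:02d}",
                polyline=(
                    (a[0] * spacing, a[1] * spacing),
                    (b[0] * spacing, b[1] * spacing),
                ),
                road_class=ROAD_CLASSES[int(rng.integers(len(ROAD_CLASSES)))],
                one_way=one_way,
                altitude_a=float(rng.uniform(0, 30)),
                altitude_b=float(rng.uniform(0, 30)),
                mean_pollution=float(rng.uniform(0, 50)),
                mean_greenness=float(rng.uniform(-0.2, 0.9)),
                accident_count=int(rng.poisson(1.0)),
                modes_allowed=frozenset(modes),
            )
        )
    if not segments:  # keep at least one link so snapping works
        segments = square_loop_segments()[:1]
    net = RoadNetwork(segments)
    extent_x, extent_y = (cols - 1) * spacing, (rows - 1) * spacing
    start = (float(rng.uniform(0, extent_x)), float(rng.uniform(0, extent_y)))
    end = (float(rng.uniform(0, extent_x)), float(rng.uniform(0, extent_y)))
    return net, start, end
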