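# greenroute

A trip-planning engine for active transportation and environmental health.
It answers the question public-health GIS tools pose to their users: *given
my mode of travel and what I care about — hills, traffic pollution, green
surroundings, accident history — which route should I take, and what does
the trip do for my health and my CO2 footprint?* It also locates healthy
food stores, parks, recreational programs and other amenities within a
buffer of any location, and computes vegetation greenness (NDVI) surfaces
from reflectance data.

The intended users are spatial-epidemiology and active-travel researchers
who need a scriptable, reproducible planner over their own road networks,
and who want every routing decision to be an explicit, inspectable cost
model rather than a black box.

## The model

**Link-based least-impedance routing.** The network is a set of directed
road *links* (segments), each carrying: road class (bicycling designated,
bicycling alternative, connecting, local, highway), one-way flag, endpoint
altitudes, mean traffic pollution concentration, mean NDVI greenness and a
pedestrian/bicyclist accident count. The search state is a directed link,
not an intersection: two links are adjacent when they share an endpoint
node. Starting from the link the origin snaps to, adjacent travelable links
are marked and priced, and the marked link with least cumulative impedance
is expanded next — uniform-cost search on the line digraph — until the
destination link is reached, or the frontier inside the search box is
exhausted (no direct route). The search is restricted to the rectangle
covering origin and destination plus a half-mile buffer, which prunes
city-scale networks to the neighborhood that matters.

**Impedance.** Traversing link *i* costs

    cost_i = eps * L_i * (10 / w_class) + env_i

where `L_i` is link length, `w_class` in 1..10 is the user's rating of the
link's road class (10 = most preferred), and `env_i` depends on the chosen
environmental preference:

| preference        | env_i                         | eps   |
|-------------------|-------------------------------|-------|
| none              | 0                             | 1     |
| avoid elevation   | max(0, rise in m)             | 1e-6  |
| low pollution     | L_i x mean pollution_i        | 1e-6  |
| vegetated         | L_i x (1 - NDVI_i) / 2        | 1e-6  |
| avoid accidents   | accident count_i              | 1e-6  |

Elevation gain and accident counts are judged on their own (no distance
term beyond the eps tie-breaker); pollution and greenness exposure are
inherently length-weighted — total pollution is the inhalation proxy
`sum_i L_i x mean pollution_i`. A maximum slope-gradient ceiling (gradient
= altitude change / horizontal distance; ratio 1 = 45°) excludes links
outright.

**Trip metrics.** A car emits 0.25 kg CO2 per km (5 t per 20,000 km/year);
cycling or walking the same distance *saves* it. Cycling burns 21.75 Cal/km
(35 Cal/mile); walking burns `bodyweight_lb x 0.853 x km` (150 lb default).
Summaries add trip time, total elevation gain (sum of positive rises),
length-weighted pollution and greenness exposure, accident totals,
color-coded slope classes and roadway-by-roadway directions.

**Surfaces.** NDVI = (NIR − RED)/(NIR + RED) cellwise from reflectance
rasters in [0, 1]; legends recode surfaces low-to-high into quantile
classes; display surfaces are dissected into 80 rectangular tiles so a
viewer loads only the tiles intersecting its viewport.

## Worked example

Generate a seeded synthetic city (10x10 grid, one highway row with a
pollution plume, smooth terrain, a green park patch, amenities, accidents)
and plan a low-pollution bicycle trip across it:

```sh
greenroute simulate --seed 7 --rows 10 --cols 10 --out-dir demo
greenroute route --network demo/network.geojson \
    --start 20,30 --end 880,870 --mode bike --pref low-pollution \
    --speed 15 --out demo/route.geojson --summary demo/summary.json
```

prints

```
mode:            bike
route length:    1.800 km
trip time:       7.2 min
elevation gain:  27.6 m
CO2 saved:     0.450 kg
calories:        39.1 Cal
mean pollution:  24.44
inhalation:      43993.6 (m x conc)
mean greenness:  0.213 (NDVI)
accidents:       9
directions:
  Cedar Ave 90  70 m
  Oak St 9  100 m
  ...
  Palm Ave 179  30 m
```

The 1.8 km route takes 7.2 minutes at 15 km/h, saves 0.450 kg of CO2 over
driving (1.8 x 0.25), burns 39.1 Cal (1.8 x 21.75), and climbs 27.6 m in
total. Its inhalation proxy (sum of traversed length x segment pollution)
is what the `low-pollution` preference minimized — rerunning with
`--pref none` yields a route whose proxy is at least as high. Amenity
search works the same way:

```sh
greenroute amenities --points demo/amenities.geojson \
    --center 450,450 --speed 5 --minutes 10 --categories grocery,fruit_veg \
    --out demo/found.geojson
```

finds grocery and fruit & vegetable stores within the 833 m a walker covers
in 10 minutes at 5 km/h.

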