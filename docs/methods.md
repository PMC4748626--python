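# Methods

## Scope and assumptions

greenroute plans least-impedance trips for driving, bicycling and walking
over road networks annotated with slope, traffic pollution, NDVI greenness
and active-travel accident counts, and summarizes each trip's health and
environmental outcomes. All geometry is planar: coordinates are projected
meters, lengths and buffer distances are Euclidean, and any lat/lon data
must be projected upstream. Public-transit itineraries, turn penalties,
time-dependent traffic and address geocoding are out of scope; pollution
surfaces are consumed as rasters, not fitted.

## Link-based search

The router works on the line digraph of the network: a state is a
(segment, direction) pair, and states are adjacent when the second segment
is travelable (mode allowed, one-way respected) from the endpoint node at
which the first terminates. Origin and destination snap to their nearest
segments by perpendicular distance (ties to the lowest segment id); partial
first/last segments are costed proportionally to the traversed fraction.
The search runs best-first with a settled set — Dijkstra on link states,
with virtual origin/destination states for the partial ends — and is exact
because every link cost is strictly positive. Ties on impedance break
toward fewer links, then lower segment ids, so results are deterministic.

Before searching, the network is restricted to segments intersecting the
axis-aligned rectangle that covers both endpoints expanded by a half-mile
(804.672 m) buffer on all sides. This pruning is a heuristic: a route
optimal in the full network that strays more than half a mile beyond the
endpoint rectangle can be missed, in which case a boxed search returns a
costlier route or none. The buffer is a tunable multiplier in the CLI
(`--expand`); enlarging it can only improve the found impedance, never
worsen it (box monotonicity, tested).

An exhaustive oracle (`oracle_route`) enumerates simple directed link paths
with cost-bound pruning — exact for positive costs — and refuses networks
with more than 60 link states. It exists for verification: the production
search is required to match it everywhere it runs.

## Impedance composition

cost(link) = eps · length · m_class + env_term, with m_class = 10 /
class_weight. The weight scale is 1–10 with 10 meaning *most preferred to
travel on*; a weight-10 class costs its bare length, a weight-1 class costs
ten times that. The "most bicycle friendly" style squares m_class,
sharpening the priority of designated bicycle roadways while preserving the
user's class ordering; "balanced" uses m_class as is. Driving exposes no
class preferences: highways are fixed at weight 10, everything else at 5.
Classes missing from a profile's weight map (e.g. the two bicycle classes
under walking, whose scale covers only connecting/local/highway) fall back
to the neutral midpoint 5.

The environmental terms are: directional rise max(0, dz) in meters
(elevation gain counts only climbs, so descending a hill never offsets
climbing it); length × mean pollution (an inhalation proxy — exposure is
time/length-weighted); length × (1 − NDVI)/2 (mapping NDVI in [−1, 1] to a
nonnegative "lack of green" density so that greener routes cost less);
and the raw accident count. Elevation and accident objectives carry no
distance term of their own; eps = 1e-6 on the length term keeps every cost
strictly positive (forbidding zero-cost cycles and making the search exact)
and breaks ties toward shorter routes without materially entering the
objective. Under `none`, eps = 1 and the cost is pure class-weighted
length.

Slope gradient is stored unsigned (|altitude difference| / length; ratio
1 = 45°) because the slope ceiling reads as a magnitude limit; the signed
rise used by the elevation objective is recomputed from endpoint altitudes
per travel direction.

## Trip metrics

CO2: 0.25 kg/km — the emission factor of a typical passenger car assumed
to emit 5 t over 20,000 km/year — reported as "emitted" for driving and
"saved" for bicycling/walking; transit is not estimated. Calories: cycling
21.75 Cal/km (the metric equivalent of 35 Cal/mile; the two constants agree
to within 0.01 Cal via 1.609344 km/mile); walking bodyweight_lb × 0.853 ×
km with a 150 lb default. Mean pollution and greenness of a trip are
length-weighted over traversed links (consistent with the inhalation
proxy), so they are invariant under segment subdivision and bounded by the
per-link extrema. Slope color classes bin per-link gradients at 2%, 5% and
10% — conventional cycling-map legend edges, overridable per call.

## Surfaces

NDVI = (NIR − RED)/(NIR + RED) with reflectance in [0, 1]; cells with zero
denominator or nodata inputs become nodata, everything else lies in
[−1, 1]. Legend recoding uses equal-count (quantile) breaks, 5 classes by
default, with right-inclusive bins so a constant surface is entirely class
1. Display tiling defaults to 8 × 10 = 80 rectangles (a portrait-shaped
split of the canonical 80-tile dissection); when dimensions do not divide
evenly, rows/columns are split as evenly as possible and the tiles still
partition the raster exactly. Raster-to-segment sampling walks the polyline
at a 10 m step (sub-cell for typical 30 m grids), skipping nodata.

## Synthetic worlds

The generator emulates the *structure* of an urban GIS stack so every
module is testable offline: a rows × cols lattice (100 m blocks) with road
classes drawn from a mix (local-dominated, one highway row by default),
10% one-way links, terrain that is flat, a single ridge, or a smooth
low-frequency harmonic field (amplitude 30 m — city-scale relief);
pollution = baseline 10 + 30 × exp(−d/200 m) off highways (a plume-like
decay); reflectance fields in [0, 1] with a park patch (NIR 0.75, RED 0.08)
that is reliably greener than its surroundings; amenities uniform per
category with popup metadata (farmers' markets carry hours and a website,
recreation entries carry program types and city, detailed recreation draws
MET values above 3.0); accidents Poisson per segment (mean 1.5 on highways,
a quarter of that elsewhere, years 2005–2007, each involving a pedestrian
and/or bicyclist), placed at segment midpoints so record counts and segment
attributes stay conserved. Everything is deterministic under a fixed seed.

What the generator does *not* emulate: real city morphology (curved
streets, irregular blocks, bridges), correlated land use, Landsat scene
artifacts, geocoding noise, or realistic traffic volumes. Passing tests
demonstrate algorithmic correctness on structurally faithful inputs, not
calibration to any real region.

## Numerical and design choices

- Node identity rounds endpoint coordinates to millimeters, so
  floating-point noise cannot split an intersection.
- Impedance comparisons in tests use a 1e-9 relative tolerance; the
  search itself compares exact floats (safe: both search and oracle sum
  the same per-link costs).
- Snapping ties, equal-impedance routes and GeoJSON key order are all
  resolved deterministically; CLI outputs are byte-stable (sorted keys,
  floats at 6 decimals).
- Degenerate inputs: empty networks raise; an all-nodata raster cannot be
  classified; a segment outside its raster samples to nodata and loads as
  attribute 0; origins snapping to slope-excluded or box-excluded segments
  yield an infeasible route with a reason rather than an error.
- Problem sizes in the test suite — pruned lattices of at most 12 nodes for
  the 200-network oracle sweep, 10 × 10 worlds for end-to-end behavior —
  are chosen so the exhaustive oracle stays exact and the whole suite runs
  in well under a minute per file.

## Known limitations

- The half-mile box is not admissible pruning (see above); city-scale
  optimality outside the box is not guaranteed, matching the intended
  neighborhood-trip use.
- The eps tie-breaker means environmental objectives are minimized only to
  first order: two routes whose env terms differ by less than eps × length
  × multiplier can rank by length instead.
- Exposure means use segment-mean attributes; within-segment pollution
  structure finer than the sampling step is averaged away.
- Walking and cycling calorie models are distance(-and-weight) linear;
  they ignore slope, speed and MET-specific intensity.
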