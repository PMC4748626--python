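"""Raster surface operations: NDVI, legend classification, display tiling
and raster-to-segment attribute sampling.

Vegetation greenness is the normalized difference vegetation index,

    NDVI = (NIR - RED) / (NIR + RED)

computed cellwise from red and near-infrared reflectance grids (reflectance
in [0, 1], NDVI in [-1, 1]; live vegetation is dark in red, bright in NIR,
so greener cells score higher). Pollution and greenness surfaces are recoded
low-to-high into legend classes, and display surfaces are dissected into
rectangular tiles so a viewer only loads the tiles intersecting its viewport.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geodata import GeodataError, Raster, RoadSegment

__all__ = [
    "SurfaceClassMap",
    "ndvi",
    "classify_surface",
    "tile_surface",
    "select_tiles",
    "sample_segment_mean",
    "DEFAULT_TILE_GRID",
]

#: default display tiling: 8 columns x 10 rows = 80 rectangular tiles
DEFAULT_TILE_GRID = (8, 10)


@dataclass
class SurfaceClassMap:
    """Integer legend classes (1 = lowest) with their value breaks."""

    raster: Raster
    n_classes: int
    breaks: tuple[float, ...]


def ndvi(nir: Raster, red: Raster) -> Raster:
    """Compute NDVI from near-infrared and red reflectance rasters.

    Cells where either input is nodata, or where NIR + RED = 0, become
    nodata. All valid outputs lie in [-1, 1].
    """
    if not nir.same_geometry(red):
        raise GeodataError("NIR and RED rasters have different grid geometry")
    n, r = nir.values, red.values
    invalid = (n == nir.nodata) | (r == red.nodata)
    denom = n + r
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom != 0, (n - r) / np.where(denom == 0, 1, denom), np.nan)
    out = np.where(invalid | (denom == 0), -9999.0, out)
    return Raster(nir.origin_x, nir.origin_y, nir.cell_size, out, nodata=-9999.0)


def classify_surface(raster: Raster, n_classes: int = 5) -> SurfaceClassMap:
    """Recode a surface low-to-high into quantile (equal-count) classes.

    Class 1 holds the lowest values; nodata cells keep the nodata sentinel.
    """
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    valid = raster.values != raster.nodata
    body = raster.values[valid]
    if body.size == 0:
        raise GeodataError("cannot classify an all-nodata raster")
    qs = np.quantile(body, [i / n_classes for i in range(1, n_classes)])
    # right-inclusive bins: values equal to a break stay in the lower class,
    # so a constant raster is entirely class 1
    classes = np.digitize(raster.values, qs, right=True) + 1.0
    classes = np.where(valid, classes, raster.nodata)
    labeled = Raster(
        raster.origin_x, raster.origin_y, raster.cell_size, classes, raster.nodata
    )
    return SurfaceClassMap(raster=labeled, n_classes=n_classes, breaks=tuple(qs))


def tile_surface(
    raster: Raster, n_x: int = DEFAULT_TILE_GRID[0], n_y: int = DEFAULT_TILE_GRID[1]
) -> list[Raster]:
    """Dissect a raster into an n_x-by-n_y grid of rectangular tiles.

    Tiles partition the raster exactly (every cell in exactly one tile) and
    carry correct origins. Returned row-major from the top-left tile.
    """
    if n_x < 1 or n_y < 1:
        raise ValueError("tile grid dimensions must be >= 1")
    if raster.n_cols < n_x or raster.n_rows < n_y:
        raise GeodataError(
            f"raster {raster.n_rows}x{raster.n_cols} smaller than tile grid {n_y}x{n_x}"
        )
    row_chunks = np.array_split(np.arange(raster.n_rows), n_y)
    col_chunks = np.array_split(np.arange(raster.n_cols), n_x)
    tiles = []
    for rows in row_chunks:
        for cols in col_chunks:
            block = raster.values[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
            # array row 0 is the top: the tile's lower-left corner sits below
            # its last array row
            rows_below = raster.n_rows - (rows[-1] + 1)
            tiles.append(
                Raster(
                    origin_x=raster.origin_x + cols[0] * raster.cell_size,
                    origin_y=raster.origin_y + rows_below * raster.cell_size,
                    cell_size=raster.cell_size,
                    values=block.copy(),
                    nodata=raster.nodata,
                )
            )
    return tiles


def select_tiles(
    tiles: list[Raster], view_box: tuple[float, float, float, float]
) -> list[Raster]:
    """Tiles whose extent intersects the (min_x, min_y, max_x, max_y) view box."""
    bx0, by0, bx1, by1 = view_box
    out = []
    for tile in tiles:
        tx0, ty0, tx1, ty1 = tile.extent
        if tx0 <= bx1 and bx0 <= tx1 and ty0 <= by1 and by0 <= ty1:
            out.append(tile)
    return out


def sample_segment_mean(
    raster: Raster, segment: RoadSegment, step: float = 10.0
) -> float | None:
    """Mean raster value along a segment polyline, sampled every ``step`` m.

    Endpoints are always included. Nodata / out-of-grid samples are skipped;
    returns None when no sample hits a valid cell (segment outside raster or
    an all-nodata strip).
    """
    if step <= 0:
        raise ValueError("sampling step must be > 0")
    line = segment.line
    n = max(1, int(np.ceil(line.length / step)))
    values = []
    for i in range(n + 1):
        p = line.interpolate(line.length * i / n)
        v = raster.value_at(p.x, p.y)
        if v is not None:
            values.append(v)
    return float(np.mean(values)) if values else None
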