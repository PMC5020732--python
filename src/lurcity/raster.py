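"""Planar raster primitives for GIS-style feature engineering.

Everything the buffer/distance/density variable catalogue needs: vector
rasterization, circular focal sums, Euclidean distance transforms with a
log-distance variant, quartic kernel density, and Horn slope.  All
geometry is planar, in metres, with the grid origin at the top-left
corner and rows increasing southward.  Cell centres sit at
``origin + (index + 0.5) * cell_size`` and cell extents are half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .vector import VectorLayer

__all__ = [
    "GridSpec",
    "RasterGrid",
    "rasterize",
    "focal_sum",
    "euclidean_distance",
    "log_distance",
    "kernel_density",
    "slope_from_dem",
    "nodata_to_zero",
]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster: shape, top-left outer corner, cell size (m)."""

    nrows: int
    ncols: int
    origin: tuple[float, float]
    cell_size: float

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-centre coordinates, shape (nrows, ncols)."""
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = y0 - (np.arange(self.nrows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing (x, y); raises if outside."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({x}, {y}) outside grid extent")
        return row, col

    def contains(self, x: float, y: float) -> bool:
        x0, y0 = self.origin
        return (x0 <= x < x0 + self.ncols * self.cell_size
                and y0 - self.nrows * self.cell_size < y <= y0)


@dataclass
class RasterGrid:
    """A 2-D value grid plus its georeferencing and a nodata mask.

    ``nodata`` is a boolean array, True where the cell carries no value.
    Values under the mask are ignored by all operations.
    """

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 5.0
    nodata: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.nodata is None:
            self.nodata = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata = np.asarray(self.nodata, dtype=bool)
            if self.nodata.shape != self.values.shape:
                raise ValueError("nodata mask shape mismatch")
        if not np.all(np.isfinite(self.values[~self.nodata])):
            raise ValueError("raster values must be finite where not nodata")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.values.shape[0], self.values.shape[1],
                        self.origin, self.cell_size)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "RasterGrid":
        return RasterGrid(self.values.copy(), self.origin, self.cell_size,
                          self.nodata.copy())

    def like(self, values: np.ndarray,
             nodata: np.ndarray | None = None) -> "RasterGrid":
        """New raster on this grid with the given values."""
        return RasterGrid(values, self.origin, self.cell_size, nodata)

    def sample(self, points) -> np.ndarray:
        """Values at the cells containing each (x, y) point; no interpolation."""
        out = np.empty(len(points))
        for i, (x, y) in enumerate(points):
            r, c = self.grid.index_of(x, y)
            out[i] = self.values[r, c]
        return out

    # --- ESRI ASCII grid IO (text) -------------------------------------
    NODATA_VALUE = -9999.0

    def write_ascii(self, path) -> None:
        x0, y0 = self.origin
        nrows, ncols = self.shape
        vals = np.where(self.nodata, self.NODATA_VALUE, self.values)
        header = (f"ncols {ncols}\nnrows {nrows}\n"
                  f"xllcorner {x0}\nyllcorner {y0 - nrows * self.cell_size}\n"
                  f"cellsize {self.cell_size}\nNODATA_value {self.NODATA_VALUE}\n")
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, vals, fmt="%.8g")

    @classmethod
    def read_ascii(cls, path) -> "RasterGrid":
        meta: dict[str, float] = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                meta[key.lower()] = float(val)
            vals = np.loadtxt(fh)
        vals = np.atleast_2d(vals)
        cs = meta["cellsize"]
        origin = (meta["xllcorner"], meta["yllcorner"] + meta["nrows"] * cs)
        nd = vals == meta.get("nodata_value", cls.NODATA_VALUE)
        vals = np.where(nd, 0.0, vals)
        return cls(vals, origin, cs, nd)


# ---------------------------------------------------------------------------
# rasterization


def _burn_segment(lengths: np.ndarray, grid: GridSpec,
                  p0: tuple[float, float], p1: tuple[float, float]) -> None:
    """Accumulate per-cell overlap length of one segment (grid traversal)."""
    (x0, y0), (x1, y1) = p0, p1
    seg_len = float(np.hypot(x1 - x0, y1 - y0))
    if seg_len == 0.0:
        return
    gx, gy = grid.origin
    cs = grid.cell_size
    ts = [0.0, 1.0]
    # parameter values where the segment crosses grid lines
    if x1 != x0:
        k0 = int(np.ceil((min(x0, x1) - gx) / cs))
        k1 = int(np.floor((max(x0, x1) - gx) / cs))
        for k in range(k0, k1 + 1):
            ts.append(((gx + k * cs) - x0) / (x1 - x0))
    if y1 != y0:
        k0 = int(np.ceil((gy - max(y0, y1)) / cs))
        k1 = int(np.floor((gy - min(y0, y1)) / cs))
        for k in range(k0, k1 + 1):
            ts.append((y0 - (gy - k * cs)) / (y0 - y1))
    ts = np.unique(np.clip(ts, 0.0, 1.0))
    mids = (ts[:-1] + ts[1:]) / 2.0
    dls = (ts[1:] - ts[:-1]) * seg_len
    for t, dl in zip(mids, dls):
        if dl <= 1e-12:
            continue
        mx, my = x0 + t * (x1 - x0), y0 + t * (y1 - y0)
        col = int(np.floor((mx - gx) / cs))
        row = int(np.floor((gy - my) / cs))
        if 0 <= row < grid.nrows and 0 <= col < grid.ncols:
            lengths[row, col] += dl


def rasterize(layer: VectorLayer, template: GridSpec | RasterGrid,
              mode: str = "presence") -> RasterGrid:
    """Burn a vector layer onto a grid.

    Modes: ``presence`` (1 where covered), ``length_weight`` (metres of
    line per cell), ``area_weight`` (m^2 of polygon per cell).  Lines mark
    a cell only when a positive length falls inside it; polygons use the
    cell-centre-in-polygon rule; points mark their containing cell.
    An empty layer yields an all-zero raster with a warning.
    """
    import shapely

    grid = template.grid if isinstance(template, RasterGrid) else template
    out = np.zeros(grid.shape)
    if len(layer) == 0:
        warnings.warn("rasterizing an empty layer: all-zero raster")
        return RasterGrid(out, grid.origin, grid.cell_size)

    X, Y = None, None
    for geom, _attrs in layer:
        gtype = geom.geom_type
        if gtype in ("Point", "MultiPoint"):
            pts = geom.geoms if gtype == "MultiPoint" else [geom]
            for p in pts:
                if grid.contains(p.x, p.y):
                    r, c = grid.index_of(p.x, p.y)
                    out[r, c] = out[r, c] + 1.0 if mode != "presence" else 1.0
        elif gtype in ("LineString", "MultiLineString"):
            lines = geom.geoms if gtype == "MultiLineString" else [geom]
            acc = np.zeros(grid.shape)
            for line in lines:
                coords = list(line.coords)
                for p0, p1 in zip(coords[:-1], coords[1:]):
                    _burn_segment(acc, grid, p0, p1)
            if mode == "length_weight":
                out += acc
            else:
                out[acc > 1e-9] = 1.0
        elif gtype in ("Polygon", "MultiPolygon"):
            if X is None:
                X, Y = grid.cell_centers()
            inside = shapely.contains_xy(geom, X.ravel(), Y.ravel())
            inside = inside.reshape(grid.shape)
            if mode == "area_weight":
                out[inside] += grid.cell_size ** 2
            else:
                out[inside] = 1.0
        else:  # pragma: no cover - guarded by VectorLayer validation
            raise ValueError(f"unsupported geometry type {gtype}")
    return RasterGrid(out, grid.origin, grid.cell_size)


# ---------------------------------------------------------------------------
# focal statistics


def _disc_kernel(radius: float, cell_size: float) -> np.ndarray:
    n = int(np.floor(radius / cell_size + 1e-9))
    off = np.arange(-n, n + 1)
    dj, di = np.meshgrid(off, off)
    d2 = (di * cell_size) ** 2 + (dj * cell_size) ** 2
    return (d2 <= radius ** 2 + 1e-6).astype(float)


def focal_sum(raster: RasterGrid, radius: float) -> RasterGrid:
    """Sum of values over the circular neighbourhood of each cell.

    The neighbourhood contains every cell whose centre lies within the
    Euclidean ``radius`` (m) of the target cell's centre.  Edge cells sum
    over the in-grid part only.
    """
    if radius < raster.cell_size:
        raise ValueError("radius must be at least one cell_size")
    kernel = _disc_kernel(radius, raster.cell_size)
    vals = np.where(raster.nodata, 0.0, raster.values)
    if vals.size * kernel.size <= 1e6:
        out = ndimage.convolve(vals, kernel, mode="constant", cval=0.0)
    else:
        out = signal.fftconvolve(vals, kernel, mode="same")
        out[np.abs(out) < 1e-9] = 0.0
    return raster.like(out)


# ---------------------------------------------------------------------------
# distances


def euclidean_distance(features: RasterGrid) -> RasterGrid:
    """Distance (m) from each cell centre to the nearest feature-cell centre.

    Feature cells are the nonzero, non-nodata cells of ``features``.
    """
    mask = (features.values != 0) & ~features.nodata
    if not mask.any():
        raise ValueError("distance undefined: no feature cells")
    dist = ndimage.distance_transform_edt(
        ~mask, sampling=features.cell_size)
    return features.like(dist)


def log_distance(dist: RasterGrid) -> RasterGrid:
    """Natural log of (distance + one cell size).

    The offset keeps feature cells (distance 0) at ln(cell_size) rather
    than -inf; pollutant decay with distance is close to exponential, so
    the log scale linearizes distance effects.
    """
    vals = np.where(dist.nodata, 0.0, dist.values)
    if (vals < 0).any():
        raise ValueError("distances must be non-negative")
    return dist.like(np.log(vals + dist.cell_size), dist.nodata.copy())


# ---------------------------------------------------------------------------
# kernel density


def kernel_density(points: VectorLayer, radius: float,
                   template: GridSpec | RasterGrid,
                   weight_attr: str = "weight") -> RasterGrid:
    """Quartic-kernel density surface in units per km^2.

    Each weighted point spreads its mass over a disc of the given radius
    with the quartic (biweight) kernel K(d) = 3/(pi r^2) (1 - (d/r)^2)^2,
    which integrates to the point's weight.  Points are accumulated on
    the grid and convolved, so the field is exactly linear in weights.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    grid = template.grid if isinstance(template, RasterGrid) else template
    cs = grid.cell_size
    acc = np.zeros(grid.shape)
    for geom, attrs in points:
        w = float(attrs.get(weight_attr, 0.0))
        if w < 0:
            raise ValueError("kernel density weights must be >= 0")
        if w == 0 or not grid.contains(geom.x, geom.y):
            continue
        r, c = grid.index_of(geom.x, geom.y)
        acc[r, c] += w
    n = int(np.ceil(radius / cs))
    off = np.arange(-n, n + 1)
    dj, di = np.meshgrid(off, off)
    d = np.hypot(di * cs, dj * cs)
    kern = np.where(d < radius,
                    3.0 / (np.pi * radius ** 2) * (1 - (d / radius) ** 2) ** 2,
                    0.0)
    if acc.size * kern.size <= 1e6:
        dens = ndimage.convolve(acc, kern, mode="constant", cval=0.0)
    else:
        dens = signal.fftconvolve(acc, kern, mode="same")
        dens[dens < 0] = 0.0
    return RasterGrid(dens * 1e6, grid.origin, cs)  # per m^2 -> per km^2


# ---------------------------------------------------------------------------
# terrain


def slope_from_dem(dem: RasterGrid) -> RasterGrid:
    """Slope in degrees from the Horn 3x3 finite-difference gradient.

    Edges are handled by replicating border cells, so a constant or
    planar DEM keeps its exact slope up to the boundary.
    """
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise ValueError("DEM must be at least 3x3")
    z = np.pad(np.where(dem.nodata, 0.0, dem.values), 1, mode="edge")
    cs = dem.cell_size
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8 * cs)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8 * cs)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    return dem.like(slope)


def nodata_to_zero(raster: RasterGrid) -> RasterGrid:
    """Replace nodata cells by 0 and clear the mask; other values unchanged."""
    vals = np.where(raster.nodata, 0.0, raster.values)
    return RasterGrid(vals, raster.origin, raster.cell_size)
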