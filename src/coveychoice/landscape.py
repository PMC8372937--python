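"""Landscape covariates from vegetation-height rasters.

Vegetation height grids (e.g. LiDAR canopy-height models at 3.6 m
resolution) are classified into open / shrub / tree cover, and three
point-buffered metrics are computed around telemetry locations:

* percent cover of a class within a radius (default 50 m),
* woody (shrub + tree) edge density in m/ha within the radius,
* Euclidean distance to the nearest cell of a class (e.g. trees).

Coordinates are planar metric (a projected CRS is assumed upstream);
geographic coordinates are not supported.  Buffer membership uses the
cell-center-in-disc rule and distances are measured to cell centers,
which keeps every metric checkable against exhaustive enumeration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "OPEN",
    "SHRUB",
    "TREE",
    "CLASS_NAMES",
    "Point",
    "HeightRaster",
    "CoverRaster",
    "classify_heights",
    "percent_class_within",
    "edge_density_within",
    "distance_to_class",
    "read_ascii_grid",
    "write_ascii_grid",
    "landscape_covariate_table",
]

OPEN, SHRUB, TREE = 0, 1, 2
CLASS_NAMES = {"open": OPEN, "shrub": SHRUB, "tree": TREE}
_CLASS_LABELS = {v: k for k, v in CLASS_NAMES.items()}

#: default height windows (m): shrub = [0.7, 3.5), tree = [3.5, 40].
DEFAULT_SHRUB_RANGE = (0.7, 3.5)
DEFAULT_TREE_RANGE = (3.5, 40.0)


@dataclass(frozen=True)
class Point:
    """A planar location in projected metric coordinates."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"non-finite point coordinates ({self.x}, {self.y})")


class _Grid:
    """Shared geometry for rectangular rasters.

    ``values[0, 0]`` is the north-west cell (row 0 at the top, the ASCII-grid
    convention); ``(xll, yll)`` is the lower-left corner of the grid.
    """

    def __init__(self, values: np.ndarray, xll: float = 0.0, yll: float = 0.0,
                 resolution: float = 3.6):
        values = np.asarray(values)
        if values.ndim != 2 or values.size == 0:
            raise ValueError("raster values must form a non-empty 2-D grid")
        if not resolution > 0:
            raise ValueError(f"resolution must be positive, got {resolution}")
        self.values = values
        self.xll = float(xll)
        self.yll = float(yll)
        self.resolution = float(resolution)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (cx, cy) arrays of cell-center coordinates, shape = grid."""
        nrows, ncols = self.shape
        res = self.resolution
        xs = self.xll + (np.arange(ncols) + 0.5) * res
        ys = self.yll + (nrows - 1 - np.arange(nrows) + 0.5) * res
        return np.meshgrid(xs, ys)

    def cell_containing(self, p: Point) -> tuple[int, int] | None:
        """(row, col) of the cell containing p, or None if off-raster."""
        nrows, ncols = self.shape
        col = int(np.floor((p.x - self.xll) / self.resolution))
        row_from_bottom = int(np.floor((p.y - self.yll) / self.resolution))
        row = nrows - 1 - row_from_bottom
        if 0 <= row < nrows and 0 <= col < ncols:
            return row, col
        return None


class HeightRaster(_Grid):
    """Gridded vegetation height (m, >= 0)."""

    def __init__(self, heights, xll: float = 0.0, yll: float = 0.0,
                 resolution: float = 3.6):
        heights = np.asarray(heights, dtype=float)
        super().__init__(heights, xll, yll, resolution)
        bad = ~np.isfinite(heights)
        if bad.any():
            idx = tuple(int(i) for i in np.argwhere(bad)[0])
            raise ValueError(f"non-finite height at cell {idx}")
        if (heights < 0).any():
            idx = tuple(int(i) for i in np.argwhere(heights < 0)[0])
            raise ValueError(f"negative height at cell {idx}")


class CoverRaster(_Grid):
    """Categorical cover grid on the same geometry as its HeightRaster.

    Cell values are integer class codes (OPEN / SHRUB / TREE by default);
    additional caller-supplied class layers (e.g. native grass, managed
    ground) can be passed to the metric functions as boolean masks.
    """

    def __init__(self, classes, xll: float = 0.0, yll: float = 0.0,
                 resolution: float = 3.6):
        classes = np.asarray(classes, dtype=np.int16)
        super().__init__(classes, xll, yll, resolution)

    def class_mask(self, cls) -> np.ndarray:
        """Boolean mask for a class given as code, name, or mask."""
        if isinstance(cls, np.ndarray) and cls.dtype == bool:
            if cls.shape != self.shape:
                raise ValueError("class mask shape does not match raster")
            return cls
        if isinstance(cls, str):
            cls = CLASS_NAMES[cls.lower()]
        return self.values == int(cls)


def classify_heights(raster: HeightRaster,
                     shrub_range: tuple[float, float] = DEFAULT_SHRUB_RANGE,
                     tree_range: tuple[float, float] = DEFAULT_TREE_RANGE,
                     ) -> CoverRaster:
    """Threshold a height raster into open / shrub / tree cover.

    Shrub is the half-open window [lo, hi) and tree the closed window
    [lo, hi], so a cell at the shared 3.5 m boundary is a tree and no cell
    belongs to both classes.  Heights outside both windows (including tall
    outliers above the tree ceiling) are open.
    """
    s_lo, s_hi = map(float, shrub_range)
    t_lo, t_hi = map(float, tree_range)
    if not (s_lo < s_hi and t_lo < t_hi):
        raise ValueError("degenerate class height window")
    # half-open shrub / closed tree; only the shared boundary may touch
    if s_hi > t_lo and t_hi > s_lo:
        if not np.isclose(s_hi, t_lo):
            raise ValueError("shrub and tree height windows overlap")
    h = raster.values
    classes = np.full(h.shape, OPEN, dtype=np.int16)
    classes[(h >= s_lo) & (h < s_hi)] = SHRUB
    classes[(h >= t_lo) & (h <= t_hi)] = TREE
    return CoverRaster(classes, raster.xll, raster.yll, raster.resolution)


def _disc_mask(cover: _Grid, p: Point, radius: float) -> np.ndarray:
    if not radius > 0:
        raise ValueError(f"radius must be positive, got {radius}")
    cx, cy = cover.cell_centers()
    return (cx - p.x) ** 2 + (cy - p.y) ** 2 <= radius ** 2


def _check_buffer_coverage(cover: _Grid, p: Point, radius: float,
                           inside: np.ndarray) -> None:
    if not inside.any():
        raise ValueError(
            f"buffer of radius {radius} around ({p.x}, {p.y}) lies entirely "
            "off the raster")
    nrows, ncols = cover.shape
    res = cover.resolution
    x_max = cover.xll + ncols * res
    y_max = cover.yll + nrows * res
    if (p.x - radius < cover.xll or p.x + radius > x_max
            or p.y - radius < cover.yll or p.y + radius > y_max):
        warnings.warn(
            "buffer extends beyond the raster; metric computed over "
            "in-raster cells only", stacklevel=3)


def percent_class_within(cover: CoverRaster, p: Point, radius: float,
                         cls) -> float:
    """Fraction of buffer cells (center-in-disc) matching a class, in [0, 1]."""
    inside = _disc_mask(cover, p, radius)
    _check_buffer_coverage(cover, p, radius, inside)
    mask = cover.class_mask(cls)
    return float(mask[inside].sum() / inside.sum())


def _woody_edges(cover: CoverRaster, woody_classes=("shrub", "tree")):
    """Midpoints and unit length of every internal woody/non-woody boundary.

    Returns (mx, my) arrays of shared-edge midpoints; each edge has length
    one cell side.  Only interior cell pairs are considered: the raster
    border itself is not an edge (the class outside the raster is unknown).
    """
    woody = np.zeros(cover.shape, dtype=bool)
    for cls in woody_classes:
        woody |= cover.class_mask(cls)
    cx, cy = cover.cell_centers()
    res = cover.resolution
    mids_x, mids_y = [], []
    # vertical neighbours (share a horizontal edge)
    diff = woody[:-1, :] != woody[1:, :]
    mids_x.append(cx[:-1, :][diff])
    mids_y.append((cy[:-1, :][diff] + cy[1:, :][diff]) / 2.0)
    # horizontal neighbours (share a vertical edge)
    diff = woody[:, :-1] != woody[:, 1:]
    mids_x.append((cx[:, :-1][diff] + cx[:, 1:][diff]) / 2.0)
    mids_y.append(cy[:, :-1][diff])
    return np.concatenate(mids_x), np.concatenate(mids_y), res


def edge_density_within(cover: CoverRaster, p: Point, radius: float,
                        woody_classes=("shrub", "tree")) -> float:
    """Woody edge density (m/ha) inside a disc of ``radius`` around ``p``.

    Sums the length of shrub/tree vs. other boundaries whose shared-edge
    midpoint falls inside the disc and divides by the full disc area in
    hectares.
    """
    inside = _disc_mask(cover, p, radius)
    _check_buffer_coverage(cover, p, radius, inside)
    mx, my, res = _woody_edges(cover, woody_classes)
    in_disc = (mx - p.x) ** 2 + (my - p.y) ** 2 <= radius ** 2
    total_length_m = float(in_disc.sum()) * res
    area_ha = np.pi * radius ** 2 / 1e4
    return total_length_m / area_ha


def distance_to_class(cover: CoverRaster, p: Point, cls) -> float:
    """Euclidean distance (m) from ``p`` to the nearest cell of ``cls``.

    Zero when ``p`` lies inside a cell of the class; otherwise the distance
    to the nearest matching cell center.  Raises if the raster contains no
    cell of the class (the caller must widen the extent rather than accept
    a silent sentinel).
    """
    mask = cover.class_mask(cls)
    if not mask.any():
        raise ValueError("raster contains no cell of the requested class")
    home = cover.cell_containing(p)
    if home is not None and mask[home]:
        return 0.0
    cx, cy = cover.cell_centers()
    d2 = (cx[mask] - p.x) ** 2 + (cy[mask] - p.y) ** 2
    return float(np.sqrt(d2.min()))


# --- text raster I/O (ESRI ASCII grid) -------------------------------------

def read_ascii_grid(path, kind: str = "height"):
    """Read an ESRI ASCII grid into a HeightRaster or CoverRaster."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner",
                       "cellsize", "nodata_value"}:
                header[key] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    values = np.array(rows)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid data does not match declared dimensions")
    args = (values, header.get("xllcorner", 0.0), header.get("yllcorner", 0.0),
            header.get("cellsize", 3.6))
    return HeightRaster(*args) if kind == "height" else CoverRaster(*args)


def write_ascii_grid(raster: _Grid, path) -> None:
    """Write a raster as an ESRI ASCII grid."""
    nrows, ncols = raster.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\nnrows {nrows}\n")
        fh.write(f"xllcorner {raster.xll}\nyllcorner {raster.yll}\n")
        fh.write(f"cellsize {raster.resolution}\n")
        is_int = np.issubdtype(raster.values.dtype, np.integer)
        fmt = "%d" if is_int else "%.4f"
        np.savetxt(fh, raster.values, fmt=fmt)


def landscape_covariate_table(cover: CoverRaster, points, radius: float = 50.0):
    """Per-point NG-style percent covers, woody edge density, and tree distance.

    ``points`` is an iterable of (id, Point).  Returns a pandas DataFrame with
    columns id, pct_open, pct_shrub, pct_tree, WE, TD.
    """
    import pandas as pd

    records = []
    for pid, p in points:
        records.append({
            "id": pid,
            "pct_open": percent_class_within(cover, p, radius, OPEN),
            "pct_shrub": percent_class_within(cover, p, radius, SHRUB),
            "pct_tree": percent_class_within(cover, p, radius, TREE),
            "WE": edge_density_within(cover, p, radius),
            "TD": distance_to_class(cover, p, TREE),
        })
    return pd.DataFrame.from_records(records)
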