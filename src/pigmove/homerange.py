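"""Home-range and availability geometry.

Second-order (home-range placement) availability is the minimum convex
polygon around all locations, buffered outward to admit long-distance
movements; use at that order is the 95% fixed-kernel home range of each
individual.  Kernel home ranges use a bivariate normal kernel with one
scalar bandwidth per the classical reference rule

    h_ref = sqrt((var(x) + var(y)) / 2) * n**(-1/6)

and the 95% isopleth is the smallest set of grid cells holding 95% of the
estimated utilisation distribution.  Availability and use are sampled on a
systematic 90-m lattice (every third 30-m pixel), pixel-aligned for
reproducibility.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np
import shapely
from scipy import ndimage
from shapely.geometry import MultiPoint, Polygon

from .landscape import Raster

__all__ = [
    "mcp",
    "buffer_region",
    "href_bandwidth",
    "kde_surface",
    "isopleth",
    "grid_sample",
    "Isopleth",
    "DegenerateGeometryError",
]


class DegenerateGeometryError(ValueError):
    """Too few or collinear points: no polygon exists."""


def mcp(points: np.ndarray) -> Polygon:
    """Minimum convex polygon (convex hull) of an (n, 2) point array."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(points) < 3:
        raise DegenerateGeometryError(
            f"MCP needs at least 3 points, got {len(points)}"
        )
    hull = MultiPoint(points).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0:
        raise DegenerateGeometryError("points are collinear; MCP is degenerate")
    return hull


def buffer_region(poly: Polygon, distance: float, quad_segs: int = 32) -> Polygon:
    """Minkowski dilation of a polygon by ``distance`` metres (round corners)."""
    if distance < 0:
        raise ValueError("buffer distance must be non-negative")
    if distance == 0:
        return poly
    return poly.buffer(distance, quad_segs=quad_segs)


def href_bandwidth(points: np.ndarray) -> float:
    """Reference (normal-rule) bandwidth for the bivariate fixed kernel.

    h = sqrt(0.5 * (var(x) + var(y))) * n^(-1/6), with sample variances.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    if n < 5:
        raise ValueError(f"href needs at least 5 points, got {n}")
    vx = points[:, 0].var(ddof=1)
    vy = points[:, 1].var(ddof=1)
    if vx + vy == 0:
        raise ValueError("zero variance on both axes; bandwidth undefined")
    return float(np.sqrt(0.5 * (vx + vy)) * n ** (-1.0 / 6.0))


def kde_surface(
    points: np.ndarray,
    h: Optional[float] = None,
    cell: float = 30.0,
    pad_factor: float = 3.5,
) -> Raster:
    """Fixed-kernel density surface on a regular grid.

    Bivariate isotropic normal kernel with SD ``h`` per axis (``h`` defaults
    to the reference bandwidth); the grid extends ``pad_factor * h`` beyond
    the point bounding box and is snapped to multiples of ``cell``.  Cell
    values are densities (per m^2); their sum times the cell area is 1.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 1:
        raise ValueError("kde_surface needs at least one point")
    if h is None:
        h = href_bandwidth(points)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    pad = pad_factor * h + cell
    xmin = np.floor((points[:, 0].min() - pad) / cell) * cell
    ymin = np.floor((points[:, 1].min() - pad) / cell) * cell
    xmax = np.ceil((points[:, 0].max() + pad) / cell) * cell
    ymax = np.ceil((points[:, 1].max() + pad) / cell) * cell
    ncols = int(round((xmax - xmin) / cell))
    nrows = int(round((ymax - ymin) / cell))
    counts, _, _ = np.histogram2d(
        points[:, 0], points[:, 1],
        bins=[ncols, nrows], range=[[xmin, xmax], [ymin, ymax]],
    )
    # histogram2d: first axis x -> transpose to (row=y, col=x), flip so row 0 = north
    counts = counts.T[::-1]
    dens = ndimage.gaussian_filter(counts, sigma=h / cell, mode="constant", truncate=6.0)
    total = dens.sum() * cell * cell
    dens = dens / total
    return Raster(dens, xll=xmin, yll=ymin, cell=cell)


@dataclasses.dataclass
class Isopleth:
    """A utilisation-distribution isopleth as a cell mask on the KDE grid."""

    mask: np.ndarray  # boolean, same shape as the source surface
    surface: Raster
    level: float
    mass: float  # realized mass inside the mask (>= level by construction)

    @property
    def area(self) -> float:
        """Isopleth area in m^2 (cell count times cell area)."""
        return float(self.mask.sum()) * self.surface.cell**2

    def contains(self, x, y):
        """Boundary-inclusive membership test via cell lookup."""
        inside = self.surface.inside(x, y)
        out = np.zeros_like(inside, dtype=bool)
        if np.any(inside):
            xs = np.asarray(x, dtype=float)[inside]
            ys = np.asarray(y, dtype=float)[inside]
            row, col = self.surface.index_of(xs, ys)
            out[inside] = self.mask[row, col]
        return out

    def to_polygon(self):
        """Dissolved polygon of the mask's cells (for GeoJSON export)."""
        s = self.surface
        rows, cols = np.nonzero(self.mask)
        boxes = shapely.box(
            s.xll + cols * s.cell,
            s.yll + (s.nrows - rows - 1) * s.cell,
            s.xll + (cols + 1) * s.cell,
            s.yll + (s.nrows - rows) * s.cell,
        )
        return shapely.unary_union(boxes)


def isopleth(surface: Raster, level: float = 0.95) -> Isopleth:
    """Smallest set of cells holding ``level`` of the distribution's mass.

    Cells are ranked by density descending and accumulated until the summed
    mass reaches ``level``; because the ranking is by density this is a
    superlevel set of the surface.
    """
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    cell_area = surface.cell**2
    mass = surface.values.ravel() * cell_area
    order = np.argsort(mass)[::-1]
    csum = np.cumsum(mass[order])
    n_in = int(np.searchsorted(csum, level * csum[-1]) + 1)
    n_in = min(n_in, len(mass))
    if level == 1.0:
        keep = mass > 0
    else:
        keep = np.zeros(mass.shape, dtype=bool)
        keep[order[:n_in]] = True
    realized = float(mass[keep].sum())
    return Isopleth(
        mask=keep.reshape(surface.values.shape),
        surface=surface,
        level=level,
        mass=realized,
    )


def grid_sample(
    region,
    spacing: float = 90.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Systematic lattice sample of a region, boundary-inclusive.

    ``region`` may be a shapely polygon or an :class:`Isopleth`.  Lattice
    points sit at ``origin + (i * spacing, j * spacing)``; the lattice is
    anchored at the given origin (by default the raster origin), not at a
    random phase, so repeated samples of the same region coincide.
    Returns an (n, 2) array.  An empty sample (region smaller than one
    cell) is returned as an empty array.
    """
    if isinstance(region, Isopleth):
        xmin, ymin, xmax, ymax = region.surface.bounds
    else:
        xmin, ymin, xmax, ymax = region.bounds
    ox, oy = origin
    i0 = int(np.ceil((xmin - ox) / spacing - 1e-9))
    i1 = int(np.floor((xmax - ox) / spacing + 1e-9))
    j0 = int(np.ceil((ymin - oy) / spacing - 1e-9))
    j1 = int(np.floor((ymax - oy) / spacing + 1e-9))
    if i1 < i0 or j1 < j0:
        return np.empty((0, 2))
    xs = ox + np.arange(i0, i1 + 1) * spacing
    ys = oy + np.arange(j0, j1 + 1) * spacing
    X, Y = np.meshgrid(xs, ys)
    x = X.ravel()
    y = Y.ravel()
    if isinstance(region, Isopleth):
        keep = region.contains(x, y)
    else:
        shapely.prepare(region)
        keep = shapely.intersects_xy(region, x, y)
    return np.column_stack([x[keep], y[keep]])
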