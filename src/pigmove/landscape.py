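"""Landscape covariates: rasters, distance layers, extraction, screening.

Rasters are 30-m single-band grids held in a small :class:`Raster` class
(row 0 is the northernmost row) and stored on disk as ESRI ASCII grids — a
plain-text format with an xllcorner/yllcorner/cellsize header.  Vector
features (streams, roads) are shapely geometries, stored as GeoJSON.  All
geometry is assumed to be in one projected metric CRS.

Covariates follow the distance-based convention: each land-cover class and
each linear feature contributes a Euclidean-distance layer (metres, 0 on
the feature itself), plus percent canopy cover.  Before model fitting,
covariates are standardized ((x - mean)/SD, with the statistics retained
for back-transformation of coefficients) and screened for collinearity by
dropping the lower-priority member of any pair with Pearson |r| above 0.6.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import mapping, shape

logger = logging.getLogger(__name__)

#: land-cover class codes (fixed vocabulary)
CLASS_CODES = {
    "upland_pine": 1,
    "bottomland_hardwood": 2,
    "shrub_herb": 3,
    "upland_hardwood": 4,
    "developed": 5,
    "other": 6,
}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}

#: default covariate priority for the collinearity screen (first = kept)
DEFAULT_PRIORITY = [
    "d_pine",
    "d_bottomland",
    "d_stream",
    "d_shrub",
    "d_uplandhw",
    "d_secondary_rd",
    "d_primary_rd",
    "canopy",
]


class Raster:
    """A single-band regular grid in a projected CRS.

    ``values[0, 0]`` is the upper-left (northwest) cell; the centre of cell
    (row, col) is at ``(xll + (col + 0.5) * cell, yll + (nrows - row - 0.5)
    * cell)``.
    """

    def __init__(self, values: np.ndarray, xll: float, yll: float, cell: float,
                 nodata: float = -9999.0):
        self.values = np.asarray(values)
        self.xll = float(xll)
        self.yll = float(yll)
        self.cell = float(cell)
        self.nodata = nodata

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self):
        """(xmin, ymin, xmax, ymax) of the grid extent."""
        return (
            self.xll,
            self.yll,
            self.xll + self.ncols * self.cell,
            self.yll + self.nrows * self.cell,
        )

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.xll, other.xll)
            and np.isclose(self.yll, other.yll)
            and np.isclose(self.cell, other.cell)
        )

    def cell_centers(self):
        """(X, Y) coordinate arrays of all cell centres, each nrows x ncols."""
        xs = self.xll + (np.arange(self.ncols) + 0.5) * self.cell
        ys = self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell
        return np.meshgrid(xs, ys)

    def index_of(self, x, y):
        """(row, col) of the cell containing each point; points on the top
        or right edge are assigned to the adjacent interior cell."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.xll) / self.cell).astype(int)
        row = np.floor((self.yll + self.nrows * self.cell - y) / self.cell).astype(int)
        # points on the outer boundary belong to the adjacent edge cell
        inside = self.inside(x, y)
        col = np.where(inside, np.clip(col, 0, self.ncols - 1), col)
        row = np.where(inside, np.clip(row, 0, self.nrows - 1), row)
        return row, col

    def inside(self, x, y):
        xmin, ymin, xmax, ymax = self.bounds
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)

    def value_at(self, x, y):
        """Nearest-cell lookup (no interpolation)."""
        row, col = self.index_of(x, y)
        return self.values[row, col]

    # -- plain-text I/O (ESRI ASCII grid) ---------------------------------
    def write_ascii(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.xll!r}\n")
            fh.write(f"yllcorner {self.yll!r}\n")
            fh.write(f"cellsize {self.cell!r}\n")
            fh.write(f"NODATA_value {self.nodata!r}\n")
            np.savetxt(fh, self.values, fmt="%.8g")

    @classmethod
    def read_ascii(cls, path) -> "Raster":
        header = {}
        with open(path) as fh:
            for _ in range(6):
                key, val = fh.readline().split()
                header[key.lower()] = float(val)
            values = np.loadtxt(fh)
        values = np.atleast_2d(values)
        return cls(
            values,
            xll=header["xllcorner"],
            yll=header["yllcorner"],
            cell=header["cellsize"],
            nodata=header.get("nodata_value", -9999.0),
        )


@dataclasses.dataclass
class Landscape:
    """Co-registered habitat layers: land-cover classes, linear features,
    and percent canopy cover."""

    classes: Raster  # integer CLASS_CODES
    canopy: Raster  # percent in [0, 100]
    streams: shapely.Geometry
    primary_roads: shapely.Geometry
    secondary_roads: shapely.Geometry

    def __post_init__(self):
        if not self.classes.same_grid(self.canopy):
            raise ValueError("class and canopy rasters are not co-registered")

    @property
    def cell(self) -> float:
        return self.classes.cell


class TargetAbsentError(ValueError):
    """The requested distance target does not occur in the landscape."""


def distance_raster(landscape: Landscape, target: str) -> Raster:
    """Euclidean-distance layer (m) to a land-cover class or linear feature.

    ``target`` is a class name from :data:`CLASS_CODES` or one of
    ``"stream"``, ``"primary_rd"``, ``"secondary_rd"``.  Class distances
    are cell-centre to nearest target cell-centre (0 inside the class);
    feature distances are point-to-segment from each cell centre.
    """
    grid = landscape.classes
    if target in CLASS_CODES:
        mask = grid.values == CLASS_CODES[target]
        if not mask.any():
            raise TargetAbsentError(f"class {target!r} absent from landscape")
        dist = ndimage.distance_transform_edt(~mask, sampling=grid.cell)
        return Raster(dist, grid.xll, grid.yll, grid.cell)
    feature = {
        "stream": landscape.streams,
        "primary_rd": landscape.primary_roads,
        "secondary_rd": landscape.secondary_roads,
    }.get(target)
    if feature is None:
        raise TargetAbsentError(f"unknown distance target {target!r}")
    if feature.is_empty:
        raise TargetAbsentError(f"feature {target!r} absent from landscape")
    X, Y = grid.cell_centers()
    pts = shapely.points(X.ravel(), Y.ravel())
    shapely.prepare(feature)
    dist = shapely.distance(pts, feature).reshape(grid.values.shape)
    return Raster(dist, grid.xll, grid.yll, grid.cell)


def covariate_rasters(
    landscape: Landscape, include_developed: bool = False
) -> dict[str, Raster]:
    """The standard covariate stack: class and feature distances + canopy.

    The distance-to-developed layer is built only on request: by default
    the developed class is excluded from modelling (it is strongly
    collinear with the primary-road network it accompanies).
    """
    out = {
        "d_pine": distance_raster(landscape, "upland_pine"),
        "d_bottomland": distance_raster(landscape, "bottomland_hardwood"),
        "d_shrub": distance_raster(landscape, "shrub_herb"),
        "d_uplandhw": distance_raster(landscape, "upland_hardwood"),
        "d_stream": distance_raster(landscape, "stream"),
        "d_primary_rd": distance_raster(landscape, "primary_rd"),
        "d_secondary_rd": distance_raster(landscape, "secondary_rd"),
        "canopy": landscape.canopy,
    }
    if include_developed:
        out["d_developed"] = distance_raster(landscape, "developed")
    return out


class EmptyExtractionError(ValueError):
    """All points fell outside the raster extent."""


def extract(
    points: pd.DataFrame, rasters: Mapping[str, Raster]
) -> pd.DataFrame:
    """Nearest-cell covariate lookup for a point table.

    ``points`` needs columns ``x`` and ``y``; any other columns (ids,
    labels, strata) are carried through.  Points outside the raster extent
    are dropped with a warning; if none remain an
    :class:`EmptyExtractionError` is raised.
    """
    rasters = dict(rasters)
    first = next(iter(rasters.values()))
    x = points["x"].to_numpy(dtype=float)
    y = points["y"].to_numpy(dtype=float)
    ok = first.inside(x, y)
    n_out = int((~ok).sum())
    if n_out:
        logger.warning("extract: dropping %d point(s) outside raster extent", n_out)
    if not ok.any():
        raise EmptyExtractionError("all points fall outside the raster extent")
    out = points.loc[ok].reset_index(drop=True).copy()
    for name, rast in rasters.items():
        if not first.same_grid(rast):
            raise ValueError(f"raster {name!r} is not co-registered")
        out[name] = rast.value_at(out["x"].to_numpy(), out["y"].to_numpy())
    out.attrs["n_dropped"] = n_out
    return out


@dataclasses.dataclass
class StandardizationStats:
    """Per-column mean and SD of the fitting set, kept for back-transforming
    standardized coefficients to natural units."""

    mean: pd.Series
    sd: pd.Series

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy()
        for c in self.mean.index:
            out[c] = (table[c] - self.mean[c]) / self.sd[c]
        return out

    def inverse(self, ztable: pd.DataFrame) -> pd.DataFrame:
        out = ztable.copy()
        for c in self.mean.index:
            out[c] = ztable[c] * self.sd[c] + self.mean[c]
        return out


def standardize(
    table: pd.DataFrame, columns: Optional[Sequence[str]] = None
):
    """Centre and scale covariate columns: z = (x - mean) / SD.

    Statistics are computed on the given (used + available) fitting set and
    returned so that standardized coefficients can be mapped back to
    per-metre / per-percent units.  A constant column is an error.
    """
    if columns is None:
        columns = [c for c in table.columns
                   if pd.api.types.is_numeric_dtype(table[c])]
    if len(table) < 2:
        raise ValueError("need at least 2 rows to standardize")
    mean = table[columns].mean()
    sd = table[columns].std(ddof=1)
    const = sd.index[~(sd > 0)].tolist()
    if const:
        raise ValueError(f"constant column(s) cannot be standardized: {const}")
    stats = StandardizationStats(mean=mean, sd=sd)
    return stats.transform(table), stats


def pearson_screen(
    table: pd.DataFrame,
    threshold: float = 0.6,
    priority: Optional[Sequence[str]] = None,
    columns: Optional[Sequence[str]] = None,
):
    """Collinearity screen: drop the lower-priority member of every pair
    with Pearson |r| > threshold.

    Returns ``(retained_columns, correlation_matrix)``.  ``priority`` is an
    ordered list, earlier = more important; columns absent from it rank
    last in the order given.
    """
    if columns is None:
        columns = [c for c in table.columns
                   if pd.api.types.is_numeric_dtype(table[c])]
    columns = list(columns)
    if priority is None:
        priority = DEFAULT_PRIORITY
    rank = {c: i for i, c in enumerate(priority)}
    order = sorted(columns, key=lambda c: rank.get(c, len(priority) + columns.index(c)))
    corr = table[columns].corr(method="pearson")
    retained: list[str] = []
    for c in order:
        clash = [r for r in retained if abs(corr.loc[c, r]) > threshold]
        if clash:
            logger.info(
                "pearson_screen: dropping %s (|r| > %.2f with %s)",
                c, threshold, ", ".join(clash),
            )
        else:
            retained.append(c)
    retained = [c for c in columns if c in retained]
    return retained, corr


# -- GeoJSON helpers -------------------------------------------------------

def write_geojson(path, geoms, properties: Optional[Iterable[dict]] = None) -> None:
    """Write shapely geometries as a GeoJSON FeatureCollection."""
    geoms = list(geoms)
    props = list(properties) if properties is not None else [{}] * len(geoms)
    fc = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(g), "properties": p}
            for g, p in zip(geoms, props)
        ],
    }
    with open(path, "w") as fh:
        json.dump(fc, fh)


def read_geojson(path):
    """Read a GeoJSON file; returns a list of shapely geometries."""
    with open(path) as fh:
        data = json.load(fh)
    if data.get("type") == "FeatureCollection":
        return [shape(f["geometry"]) for f in data["features"]]
    if data.get("type") == "Feature":
        return [shape(data["geometry"])]
    return [shape(data)]
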