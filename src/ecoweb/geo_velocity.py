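"""Climate-change velocity from paired current / Last Glacial Maximum rasters.

Velocity at a site is the temporal climate gradient (absolute difference
between the current and LGM value of the variable at the site's cell)
divided by the spatial gradient (local slope of the current climate surface,
in variable units per km, from 4-neighbor central differences).  The result
has units of km and is log-transformed before regression.

Rasters are stored as ESRI ASCII grids (plain text: ncols/nrows, lower-left
corner in decimal degrees, cell size, nodata sentinel, then values row-wise
from the northern edge).  Distances assume a spherical Earth, R = 6371 km.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

EARTH_RADIUS_KM = 6371.0


@dataclass
class RasterGrid:
    """Regular lat/lon grid of a climate variable.

    ``values[0, 0]`` is the north-west cell; ``origin`` is the (latitude,
    longitude) of the lower-left (south-west) grid corner; ``cell_size`` in
    decimal degrees.  Missing cells are NaN.
    """

    values: np.ndarray
    cell_size: float
    origin: tuple[float, float]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.values.shape[0] < 3 or self.values.shape[1] < 3:
            raise ValueError("raster needs at least 3x3 cells for slope computation")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(latitude, longitude) of a cell center; row 0 is the northern edge."""
        lat0, lon0 = self.origin
        lat = lat0 + (self.n_rows - row - 0.5) * self.cell_size
        lon = lon0 + (col + 0.5) * self.cell_size
        return lat, lon

    def locate(self, lat: float, lon: float) -> tuple[int, int]:
        """Grid cell containing a point; raises if the point is outside."""
        lat0, lon0 = self.origin
        col = int(math.floor((lon - lon0) / self.cell_size))
        row = self.n_rows - 1 - int(math.floor((lat - lat0) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"site ({lat}, {lon}) lies outside the raster")
        return row, col

    def aligned_with(self, other: "RasterGrid") -> bool:
        return (
            self.values.shape == other.values.shape
            and math.isclose(self.cell_size, other.cell_size)
            and math.isclose(self.origin[0], other.origin[0])
            and math.isclose(self.origin[1], other.origin[1])
        )


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid (.asc) from plain text."""
    header: dict[str, float] = {}
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(x) for x in parts])
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing header field {key}")
    values = np.array(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: data shape {values.shape} does not match header")
    nodata = header.get("nodata_value")
    if nodata is not None:
        values = np.where(values == nodata, np.nan, values)
    return RasterGrid(values, header["cellsize"], (header["yllcorner"], header["xllcorner"]))


def write_ascii_grid(raster: RasterGrid, path: str | Path, nodata: float = -9999.0) -> None:
    vals = np.where(np.isnan(raster.values), nodata, raster.values)
    with open(path, "w") as fh:
        fh.write(f"ncols {raster.n_cols}\n")
        fh.write(f"nrows {raster.n_rows}\n")
        fh.write(f"xllcorner {raster.origin[1]:.10g}\n")
        fh.write(f"yllcorner {raster.origin[0]:.10g}\n")
        fh.write(f"cellsize {raster.cell_size:.10g}\n")
        fh.write(f"NODATA_value {nodata:.10g}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")


def local_slope_4n(raster: RasterGrid, row: int, col: int) -> float:
    """Local slope (variable units per km) from the 4 rook neighbors.

    Central differences: dz/dx over the east-west pair (spacing shrinks with
    cos(latitude)), dz/dy over the north-south pair; slope is the gradient
    magnitude.  Edge cells or missing neighbors yield NaN with a warning.
    """
    v = raster.values
    if not (1 <= row < raster.n_rows - 1 and 1 <= col < raster.n_cols - 1):
        warnings.warn(f"cell ({row}, {col}) is on the raster edge; slope undefined")
        return float("nan")
    north = v[row - 1, col]
    south = v[row + 1, col]
    east = v[row, col + 1]
    west = v[row, col - 1]
    if any(math.isnan(x) for x in (north, south, east, west)):
        warnings.warn(f"cell ({row}, {col}) has missing neighbors; slope undefined")
        return float("nan")
    lat, _ = raster.cell_center(row, col)
    km_per_deg = EARTH_RADIUS_KM * math.pi / 180.0
    dy_km = raster.cell_size * km_per_deg
    dx_km = raster.cell_size * km_per_deg * math.cos(math.radians(lat))
    dzdx = (east - west) / (2.0 * dx_km)
    dzdy = (north - south) / (2.0 * dy_km)
    return math.hypot(dzdx, dzdy)


@dataclass
class VelocityResult:
    """Climate-change velocity at one site."""

    temporal_gradient: float
    spatial_gradient: float
    velocity: float
    log_velocity: float
    defined: bool = True


def climate_velocity(
    current: RasterGrid,
    lgm: RasterGrid,
    lat: float,
    lon: float,
    log_eps: float = 1e-6,
) -> VelocityResult:
    """Velocity = |current - LGM| / local slope of the current surface.

    A zero or undefined spatial gradient gives a flagged-undefined result
    (velocity NaN) rather than an invented floor value.
    """
    if not current.aligned_with(lgm):
        raise ValueError("current and LGM rasters are not aligned")
    row, col = current.locate(lat, lon)
    temporal = abs(current.values[row, col] - lgm.values[row, col])
    if math.isnan(temporal):
        return VelocityResult(float("nan"), float("nan"), float("nan"), float("nan"), False)
    spatial = local_slope_4n(current, row, col)
    if math.isnan(spatial) or spatial == 0.0:
        return VelocityResult(temporal, spatial, float("nan"), float("nan"), False)
    velocity = temporal / spatial
    return VelocityResult(temporal, spatial, velocity, math.log(velocity + log_eps), True)


def log_transform(values, eps: float | None = None) -> np.ndarray:
    """Natural log of nonnegative velocities with a small positive offset.

    The offset defaults to 1e-6 times the smallest positive value (1e-6
    absolute when everything is zero), guarding zero-velocity sites.
    """
    arr = np.asarray(values, dtype=float)
    if np.any(arr < 0):
        raise ValueError("log transform requires nonnegative values")
    if eps is None:
        positive = arr[arr > 0]
        eps = 1e-6 * float(positive.min()) if positive.size else 1e-6
    return np.log(arr + eps)
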