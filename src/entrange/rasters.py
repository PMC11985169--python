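"""Co-registered raster stacks and plain-text raster I/O.

A :class:`PredictorStack` is an ordered, named collection of 2-D float
arrays sharing one :class:`RasterGeometry`.  Rasters are read and written
as ESRI ASCII grids (``.asc``), a self-describing plain-text format that
round-trips values to full float precision here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geo import cell_area_km2 as _cell_area_km2

NODATA_DEFAULT = -9999.0


@dataclass(frozen=True)
class RasterGeometry:
    """Grid placement: plate carree (unprojected lon/lat) with square cells.

    ``xll``/``yll`` are the lower-left *corner* coordinates in decimal
    degrees; rows are stored north-to-south (row 0 is the top row), the
    ESRI ASCII convention.
    """

    rows: int
    cols: int
    xll: float
    yll: float
    cellsize: float  # degrees
    nodata: float = NODATA_DEFAULT

    def __post_init__(self):
        if self.rows < 1 or self.cols < 1:
            raise ValueError(f"degenerate grid {self.rows}x{self.cols}")
        if self.cellsize <= 0:
            raise ValueError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of shape (rows, cols) at cell centers."""
        lon = self.xll + (np.arange(self.cols) + 0.5) * self.cellsize
        lat_top = self.yll + self.rows * self.cellsize
        lat = lat_top - (np.arange(self.rows) + 0.5) * self.cellsize
        return np.broadcast_to(lon, (self.rows, self.cols)).copy(), \
            np.broadcast_to(lat[:, None], (self.rows, self.cols)).copy()

    def row_cell_areas_km2(self) -> np.ndarray:
        """Per-row geodesic cell area (km^2), row 0 = northernmost."""
        lat_top = self.yll + self.rows * self.cellsize
        tops = lat_top - np.arange(self.rows) * self.cellsize
        return _cell_area_km2(tops - self.cellsize, tops, self.cellsize)

    def cell_area_km2(self, row: int) -> float:
        """Geodesic area of a single cell at the given row index."""
        return float(self.row_cell_areas_km2()[row])

    def approx_equal(self, other: "RasterGeometry", tol: float = 1e-9) -> bool:
        return (self.rows == other.rows and self.cols == other.cols
                and abs(self.xll - other.xll) <= tol
                and abs(self.yll - other.yll) <= tol
                and abs(self.cellsize - other.cellsize) <= tol)


class GeometryError(ValueError):
    """Raised when rasters that must be co-registered are not."""


@dataclass
class PredictorStack:
    """Named map of co-registered 2-D layers plus shared geometry.

    Nodata is represented as NaN in memory; the geometry's ``nodata``
    sentinel is only used on disk.
    """

    geometry: RasterGeometry
    layers: dict[str, np.ndarray] = field(default_factory=dict)
    categorical: set[str] = field(default_factory=set)

    def __post_init__(self):
        for name, arr in self.layers.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != self.geometry.shape:
                raise GeometryError(
                    f"layer {name!r} shape {arr.shape} != geometry {self.geometry.shape}")
            self.layers[name] = arr

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def __len__(self) -> int:
        return len(self.layers)

    def add(self, name: str, values: np.ndarray, categorical: bool = False) -> None:
        if name in self.layers:
            raise ValueError(f"duplicate layer name {name!r}")
        values = np.asarray(values, dtype=float)
        if values.shape != self.geometry.shape:
            raise GeometryError(f"layer {name!r} does not match stack geometry")
        self.layers[name] = values
        if categorical:
            self.categorical.add(name)

    def subset(self, names) -> "PredictorStack":
        missing = [n for n in names if n not in self.layers]
        if missing:
            raise KeyError(f"layers not in stack: {missing}")
        return PredictorStack(
            geometry=self.geometry,
            layers={n: self.layers[n].copy() for n in names},
            categorical={n for n in names if n in self.categorical},
        )

    def valid_mask(self) -> np.ndarray:
        """True where every layer has data."""
        mask = np.ones(self.geometry.shape, dtype=bool)
        for arr in self.layers.values():
            mask &= np.isfinite(arr)
        return mask

    def table(self, rows: np.ndarray, cols: np.ndarray) -> "np.ndarray":
        """Extract an (n_points, n_layers) value matrix at cell indices."""
        return np.column_stack([self.layers[n][rows, cols] for n in self.names])

    def copy(self) -> "PredictorStack":
        return PredictorStack(self.geometry,
                              {n: a.copy() for n, a in self.layers.items()},
                              set(self.categorical))


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def write_ascii_grid(path, values: np.ndarray, geometry: RasterGeometry) -> None:
    """Write one layer as an ESRI ASCII grid; NaN becomes the nodata value."""
    path = Path(path)
    values = np.asarray(values, dtype=float)
    if values.shape != geometry.shape:
        raise GeometryError("values do not match geometry")
    out = np.where(np.isfinite(values), values, geometry.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {geometry.cols}\n")
        fh.write(f"nrows {geometry.rows}\n")
        fh.write(f"xllcorner {geometry.xll:.10g}\n")
        fh.write(f"yllcorner {geometry.yll:.10g}\n")
        fh.write(f"cellsize {geometry.cellsize:.12g}\n")
        fh.write(f"NODATA_value {geometry.nodata:.10g}\n")
        for row in out:
            fh.write(" ".join(format(v, ".10g") for v in row))
            fh.write("\n")


def read_ascii_grid(path) -> tuple[np.ndarray, RasterGeometry]:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            m = re.match(r"^([A-Za-z_]+)\s+(-?[\d.eE+-]+)$", line)
            if m and len(header) < 6 and not data_lines:
                header[m.group(1).lower()] = float(m.group(2))
            else:
                data_lines.append(line)
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise ValueError(f"{path}: missing header keys {missing}")
    nodata = header.get("nodata_value", NODATA_DEFAULT)
    geom = RasterGeometry(rows=int(header["nrows"]), cols=int(header["ncols"]),
                          xll=header["xllcorner"], yll=header["yllcorner"],
                          cellsize=header["cellsize"], nodata=nodata)
    values = np.array([line.split() for line in data_lines], dtype=float)
    if values.shape != geom.shape:
        raise ValueError(f"{path}: data shape {values.shape} != header {geom.shape}")
    values[values == nodata] = np.nan
    return values, geom


def write_stack(stack: PredictorStack, directory) -> list[Path]:
    """Write every layer of a stack as ``<directory>/<name>.asc``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name in stack.names:
        p = directory / f"{name}.asc"
        write_ascii_grid(p, stack[name], stack.geometry)
        paths.append(p)
    return paths


def read_stack(paths, names=None) -> PredictorStack:
    """Assemble a stack from ASCII grid paths (must be co-registered).

    ``names`` defaults to the file stems.
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("no raster paths given")
    if names is None:
        names = [p.stem for p in paths]
    stack = None
    for name, p in zip(names, paths):
        values, geom = read_ascii_grid(p)
        if stack is None:
            stack = PredictorStack(geometry=geom)
        elif not stack.geometry.approx_equal(geom):
            raise GeometryError(f"{p}: geometry differs from first raster")
        stack.add(name, values)
    return stack


# ---------------------------------------------------------------------------
# Stack algebra

def resample(stack: PredictorStack, target: RasterGeometry,
             method: str = "bilinear") -> PredictorStack:
    """Resample every layer onto a target geometry.

    ``nearest`` picks the source cell containing each target cell center
    and is required for categorical layers; ``bilinear`` interpolates from
    the four surrounding source cell centers.
    """
    if method not in ("nearest", "bilinear"):
        raise ValueError(f"unknown resampling method {method!r}")
    if method == "bilinear" and stack.categorical:
        raise ValueError(
            f"bilinear resampling requested for categorical layers {sorted(stack.categorical)}")
    src = stack.geometry
    if src.approx_equal(target):
        out = stack.copy()
        return out

    tlon, tlat = target.cell_centers()
    # fractional source indices of the target centers
    fcol = (tlon - src.xll) / src.cellsize - 0.5
    src_top = src.yll + src.rows * src.cellsize
    frow = (src_top - tlat) / src.cellsize - 0.5

    out = PredictorStack(geometry=target)
    if method == "nearest":
        rr = np.clip(np.round(frow).astype(int), 0, src.rows - 1)
        cc = np.clip(np.round(fcol).astype(int), 0, src.cols - 1)
        for name in stack.names:
            out.add(name, stack[name][rr, cc], categorical=name in stack.categorical)
        return out

    r0 = np.clip(np.floor(frow).astype(int), 0, src.rows - 1)
    c0 = np.clip(np.floor(fcol).astype(int), 0, src.cols - 1)
    r1 = np.clip(r0 + 1, 0, src.rows - 1)
    c1 = np.clip(c0 + 1, 0, src.cols - 1)
    wr = np.clip(frow - r0, 0.0, 1.0)
    wc = np.clip(fcol - c0, 0.0, 1.0)
    for name in stack.names:
        a = stack[name]
        val = (a[r0, c0] * (1 - wr) * (1 - wc) + a[r0, c1] * (1 - wr) * wc
               + a[r1, c0] * wr * (1 - wc) + a[r1, c1] * wr * wc)
        out.add(name, val)
    return out


def ensemble_mean(stacks: list[PredictorStack]) -> PredictorStack:
    """Cellwise mean of co-registered stacks (e.g. a GCM ensemble).

    A cell is nodata in the result if it is nodata in any member.
    """
    if not stacks:
        raise ValueError("no stacks to average")
    first = stacks[0]
    names = first.names
    for s in stacks[1:]:
        if s.names != names:
            raise ValueError("ensemble members have differing layer names")
        if not s.geometry.approx_equal(first.geometry):
            raise GeometryError("ensemble members are not co-registered")
    out = PredictorStack(geometry=first.geometry, categorical=set(first.categorical))
    for name in names:
        arrs = np.stack([s[name] for s in stacks])
        out.add(name, arrs.mean(axis=0))  # NaN propagates
    return out
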