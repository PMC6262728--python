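"""Raster data model and core grid operations.

The :class:`Grid` is the universal raster currency of the pipeline: a 2D
array of values with square pixels, an outer top-left origin, rows increasing
southward, and a nodata sentinel excluded from every statistic.  On top of it
this module provides the focal (moving-window) mean, Euclidean distance
transforms, connected-component labeling, and summary statistics — the
primitive raster operations every downstream stage is built from.

Coordinate convention: the center of pixel ``(row r, col c)`` is
``(origin_x + (c + 0.5) * cell_size, origin_y - (r + 0.5) * cell_size)``.
All distances are measured center-to-center, in meters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal

from .errors import (
    EmptyRegionError,
    GridFormatError,
    ParameterError,
    UnsupportedGeometryError,
)

__all__ = [
    "Grid",
    "LabeledRegions",
    "read_grid",
    "write_grid",
    "focal_mean",
    "circular_kernel",
    "square_kernel",
    "distance_to",
    "label_components",
    "grid_stats",
]

_DEFAULT_NODATA = -9999.0


@dataclass
class Grid:
    """A single-band raster with square pixels.

    Parameters
    ----------
    values : ndarray, shape (n_rows, n_cols)
        Cell values; dtype float or int or bool.  ``nodata`` cells carry the
        sentinel value and never participate in statistics.
    cell_size : float
        Pixel edge length in meters (> 0).
    origin_x, origin_y : float
        Map coordinates of the OUTER corner of the top-left pixel.
    nodata : float
        Sentinel excluded from all statistics.
    crs_label : str
        Opaque coordinate-system tag, carried through unchanged.
    """

    values: np.ndarray
    cell_size: float = 30.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata: float = _DEFAULT_NODATA
    crs_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ParameterError("Grid values must be a 2D array")
        if not self.cell_size > 0:
            raise ParameterError("cell_size must be > 0")

    # -- basic geometry -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Map coordinates of a pixel center."""
        return (
            self.origin_x + (col + 0.5) * self.cell_size,
            self.origin_y - (row + 0.5) * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) center coordinate arrays, each shaped like ``values``."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.broadcast_to(x, self.shape).copy(), np.broadcast_to(
            y[:, None], self.shape
        ).copy()

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Pixel (row, col) containing map point (x, y)."""
        col = int(math.floor((x - self.origin_x) / self.cell_size))
        row = int(math.floor((self.origin_y - y) / self.cell_size))
        return row, col

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the outer raster rectangle."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    # -- nodata handling ------------------------------------------------
    def valid_mask(self) -> np.ndarray:
        """Boolean array: True where a cell holds usable (non-nodata, finite) data."""
        vals = self.values
        if vals.dtype == bool:
            return np.ones(self.shape, dtype=bool)
        with np.errstate(invalid="ignore"):
            ok = np.isfinite(vals.astype(float))
        return ok & (vals != self.nodata)

    def like(self, values: np.ndarray, nodata: float | None = None) -> "Grid":
        """A new Grid sharing this grid's georeferencing."""
        return replace(
            self,
            values=np.asarray(values),
            nodata=self.nodata if nodata is None else nodata,
        )

    def same_georeference(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and math.isclose(self.cell_size, other.cell_size)
            and math.isclose(self.origin_x, other.origin_x)
            and math.isclose(self.origin_y, other.origin_y)
        )


@dataclass
class LabeledRegions:
    """Connected components of a mask: 0 = background, 1..region_count = regions."""

    labels: Grid
    region_count: int

    def region_mask(self, k: int) -> Grid:
        return self.labels.like(self.labels.values == k)


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

_ASCII_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_grid(path, dialect: str = "ascii_grid") -> Grid:
    """Read a raster file.

    ``dialect`` is ``"ascii_grid"`` (ESRI ASCII grid) or ``"geotiff"``.
    ASCII round-trips are bit-exact; GeoTIFF stores float32.
    """
    if dialect == "ascii_grid":
        return _read_ascii(path)
    if dialect == "geotiff":
        return _read_geotiff(path)
    raise ParameterError(f"unknown raster dialect: {dialect!r}")


def write_grid(grid: Grid, path, dialect: str = "ascii_grid") -> None:
    """Write a raster file readable by :func:`read_grid`."""
    if dialect == "ascii_grid":
        _write_ascii(grid, path)
    elif dialect == "geotiff":
        _write_geotiff(grid, path)
    else:
        raise ParameterError(f"unknown raster dialect: {dialect!r}")


def _read_ascii(path) -> Grid:
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            pos = fh.tell()
            line = fh.readline()
            if not line:
                raise GridFormatError(f"{path}: truncated ASCII grid")
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in _ASCII_KEYS + ("nodata_value", "crs"):
                key = parts[0].lower()
                if key == "crs":
                    header["__crs__"] = parts[1]  # type: ignore[assignment]
                else:
                    try:
                        header[key] = float(parts[1])
                    except ValueError as exc:
                        raise GridFormatError(
                            f"{path}: bad value for header field {parts[0]!r}"
                        ) from exc
            else:
                fh.seek(pos)
                break
        for key in _ASCII_KEYS:
            if key not in header:
                raise GridFormatError(f"{path}: missing header field {key!r}")
        ncols = int(header["ncols"])
        nrows = int(header["nrows"])
        data = np.loadtxt(fh, dtype=float)
    data = np.atleast_2d(data)
    if data.size != nrows * ncols:
        raise GridFormatError(
            f"{path}: expected {nrows * ncols} values, found {data.size}"
        )
    data = data.reshape(nrows, ncols)
    cell = header["cellsize"]
    if cell <= 0:
        raise GridFormatError(f"{path}: bad value for header field 'cellsize'")
    nodata = header.get("nodata_value", _DEFAULT_NODATA)
    return Grid(
        values=data,
        cell_size=cell,
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + nrows * cell,
        nodata=nodata,
        crs_label=str(header.get("__crs__", "")),
    )


def _write_ascii(grid: Grid, path) -> None:
    vals = np.asarray(grid.values, dtype=float)
    xll = grid.origin_x
    yll = grid.origin_y - grid.n_rows * grid.cell_size
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {float(xll)!r}\n")
        fh.write(f"yllcorner {float(yll)!r}\n")
        fh.write(f"cellsize {float(grid.cell_size)!r}\n")
        fh.write(f"NODATA_value {float(grid.nodata)!r}\n")
        for row in vals:
            # repr of a Python float round-trips float64 exactly
            fh.write(" ".join(repr(v) for v in row.tolist()))
            fh.write("\n")


def _write_geotiff(grid: Grid, path) -> None:
    import tifffile

    vals = np.asarray(grid.values, dtype=np.float32)
    cs = float(grid.cell_size)
    # GeoTIFF georeferencing: pixel scale + a tiepoint at the raster's
    # outer top-left corner (raster coordinate 0,0).
    extratags = [
        (33550, "d", 3, (cs, cs, 0.0)),  # ModelPixelScaleTag
        (33922, "d", 6, (0.0, 0.0, 0.0, grid.origin_x, grid.origin_y, 0.0)),
        (42113, "s", 0, repr(float(grid.nodata))),  # GDAL_NODATA
    ]
    desc = json.dumps({"crs_label": grid.crs_label})
    tifffile.imwrite(path, vals, extratags=extratags, description=desc)


def _read_geotiff(path) -> Grid:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        vals = page.asarray()
        tags = {}
        for t in page.tags.values():
            # keep the description we wrote, not tifffile's shape metadata
            if t.code in tags and not (
                t.code == 270 and isinstance(t.value, str) and "crs_label" in t.value
            ):
                continue
            tags[t.code] = t.value
    if vals.ndim != 2:
        raise GridFormatError(f"{path}: expected a single-band raster")
    if 33550 not in tags or 33922 not in tags:
        raise GridFormatError(f"{path}: missing GeoTIFF georeferencing tags")
    sx, sy = float(tags[33550][0]), float(tags[33550][1])
    if not math.isclose(sx, sy):
        raise UnsupportedGeometryError(
            f"{path}: non-square pixels ({sx} x {sy}) are not supported"
        )
    tie = tags[33922]
    origin_x = float(tie[3]) - float(tie[0]) * sx
    origin_y = float(tie[4]) + float(tie[1]) * sy
    nodata = float(tags.get(42113, _DEFAULT_NODATA))
    crs_label = ""
    desc = tags.get(270)
    if desc:
        try:
            crs_label = json.loads(desc).get("crs_label", "")
        except (json.JSONDecodeError, AttributeError):
            crs_label = str(desc)
    return Grid(
        values=np.asarray(vals, dtype=float),
        cell_size=sx,
        origin_x=origin_x,
        origin_y=origin_y,
        nodata=nodata,
        crs_label=crs_label,
    )


# ----------------------------------------------------------------------
# Focal statistics
# ----------------------------------------------------------------------


def circular_kernel(window_area_km2: float, cell_size: float) -> np.ndarray:
    """Boolean footprint of the circle with area ``window_area_km2``.

    A pixel offset belongs to the kernel when its center lies within radius
    r of the focal center, with pi * r^2 = window area (boundary inclusive).
    """
    area_m2 = window_area_km2 * 1e6
    if area_m2 < cell_size**2:
        raise ParameterError("window smaller than one pixel")
    r = math.sqrt(area_m2 / math.pi)
    half = int(math.floor(r / cell_size))
    off = np.arange(-half, half + 1)
    dj, di = np.meshgrid(off, off)
    return (di**2 + dj**2) * cell_size**2 <= r**2 + 1e-9 * r**2


def square_kernel(window_area_km2: float, cell_size: float) -> np.ndarray:
    """Boolean w x w footprint, w = round(sqrt(area)/cell_size) forced odd."""
    area_m2 = window_area_km2 * 1e6
    if area_m2 < cell_size**2:
        raise ParameterError("window smaller than one pixel")
    w = int(round(math.sqrt(area_m2) / cell_size))
    if w % 2 == 0:
        w += 1
    w = max(w, 1)
    return np.ones((w, w), dtype=bool)


def focal_mean(grid: Grid, window_area_km2: float, shape: str = "circle") -> Grid:
    """Moving-window mean of a grid.

    Each output pixel is the mean of the non-nodata input pixels whose
    centers fall inside the kernel centered on it.  At the grid edge the
    kernel shrinks to the available pixels (no nodata padding), so the
    statistic never erodes features at the study-area boundary.  Output is
    nodata exactly where the input is nodata.
    """
    if shape == "circle":
        kernel = circular_kernel(window_area_km2, grid.cell_size)
    elif shape == "square":
        kernel = square_kernel(window_area_km2, grid.cell_size)
    else:
        raise ParameterError(f"unknown kernel shape: {shape!r}")

    valid = grid.valid_mask()
    vals = np.where(valid, np.asarray(grid.values, dtype=float), 0.0)
    kf = kernel.astype(float)
    # exact correlation for small kernels, FFT for large ones
    if kernel.size <= 49:
        s = ndimage.correlate(vals, kf, mode="constant", cval=0.0)
        n = ndimage.correlate(valid.astype(float), kf, mode="constant", cval=0.0)
    else:
        s = signal.fftconvolve(vals, kf, mode="same")
        n = signal.fftconvolve(valid.astype(float), kf, mode="same")
    n = np.round(n)  # counts are integers; undo FFT jitter
    with np.errstate(invalid="ignore", divide="ignore"):
        out = s / n
    # clamp to the windowed min/max: keeps the mean exactly bounded by its
    # inputs (so a constant grid maps to itself bit-exactly) despite
    # accumulation round-off
    lo = ndimage.minimum_filter(
        np.where(valid, vals, np.inf), footprint=kernel, mode="constant", cval=np.inf
    )
    hi = ndimage.maximum_filter(
        np.where(valid, vals, -np.inf), footprint=kernel, mode="constant", cval=-np.inf
    )
    out = np.clip(out, lo, hi)
    out = np.where(valid & (n > 0), out, grid.nodata)
    return grid.like(out)


# ----------------------------------------------------------------------
# Distance transform / labeling / statistics
# ----------------------------------------------------------------------


def distance_to(mask: Grid, cell_size: float | None = None) -> Grid:
    """Euclidean distance (m) from each pixel center to the nearest True pixel center.

    0 on feature pixels; +inf everywhere when the mask is empty.
    """
    cs = mask.cell_size if cell_size is None else cell_size
    m = np.asarray(mask.values, dtype=bool)
    if not m.any():
        return mask.like(np.full(m.shape, np.inf), nodata=_DEFAULT_NODATA)
    d = ndimage.distance_transform_edt(~m, sampling=cs)
    return mask.like(d, nodata=_DEFAULT_NODATA)


_STRUCT4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
_STRUCT8 = np.ones((3, 3), dtype=bool)


def label_components(mask: Grid, connectivity: int = 8) -> LabeledRegions:
    """Connected components of a boolean mask, labeled by decreasing size.

    Ties in pixel count break by the top-left-most pixel in row-major order.
    """
    if connectivity == 4:
        structure = _STRUCT4
    elif connectivity == 8:
        structure = _STRUCT8
    else:
        raise ParameterError("connectivity must be 4 or 8")
    m = np.asarray(mask.values, dtype=bool)
    raw, n = ndimage.label(m, structure=structure)
    if n == 0:
        return LabeledRegions(mask.like(np.zeros(m.shape, dtype=int), nodata=0), 0)
    sizes = np.bincount(raw.ravel())[1:]  # per raw label 1..n
    flat = raw.ravel()
    first_index = np.full(n + 1, flat.size, dtype=np.int64)
    # first occurrence of each raw label in row-major order
    idx = np.flatnonzero(flat)
    np.minimum.at(first_index, flat[idx], idx)
    order = sorted(range(1, n + 1), key=lambda k: (-sizes[k - 1], first_index[k]))
    remap = np.zeros(n + 1, dtype=int)
    for new, old in enumerate(order, start=1):
        remap[old] = new
    return LabeledRegions(mask.like(remap[raw], nodata=0), n)


def grid_stats(grid: Grid, region: Grid | None = None) -> dict:
    """Summary statistics over the non-nodata pixels of a grid.

    ``region``, when given, is a boolean mask limiting the pixels considered.
    ``sd`` is the sample (n-1) standard deviation, 0.0 for a single pixel.
    """
    valid = grid.valid_mask()
    if region is not None:
        if region.shape != grid.shape:
            raise ParameterError("region mask shape differs from grid")
        valid = valid & np.asarray(region.values, dtype=bool)
    vals = np.asarray(grid.values, dtype=float)[valid]
    if vals.size == 0:
        raise EmptyRegionError("no eligible pixels in region")
    sd = float(np.std(vals, ddof=1)) if vals.size > 1 else 0.0
    return {
        "mean": float(np.mean(vals)),
        "sd": sd,
        "min": float(np.min(vals)),
        "max": float(np.max(vals)),
        "pixel_count": int(vals.size),
        "area_km2": float(vals.size * grid.cell_size**2 / 1e6),
    }
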