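"""Raster data model and I/O.

The pipeline works on planar rasters in meters: a single :class:`RasterGrid`
type is the currency of every stage (covariate layers, suitability maps, cost
surfaces, current maps).  Row 0 is the top (northernmost) row and covariate
values are carried at cell centers.  Two on-disk dialects are supported: ESRI
ASCII grid (plain text) and GeoTIFF (via tifffile, with ModelPixelScale /
ModelTiepoint / GDAL_NODATA tags).

No geodesy: coordinates are planar meters, appropriate for study areas of a
few tens of kilometres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

DEFAULT_NODATA = -9999.0

# GeoTIFF tag codes
_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


class RasterFormatError(ValueError):
    """Raised when a raster file cannot be parsed in the requested dialect."""


@dataclass
class RasterGrid:
    """A georeferenced 2-D cell array on a regular square grid.

    Parameters
    ----------
    values
        2-D float array, row 0 at the top (north).  Cells are either finite
        or equal to ``nodata``.
    cell_size
        Cell edge length in meters (> 0).
    origin_x, origin_y
        Planar coordinates (m) of the lower-left corner of the grid.
    nodata
        Sentinel marking missing / impassable cells.
    """

    values: np.ndarray
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        bad = ~np.isfinite(self.values) & ~self.is_nodata(self.values)
        if bad.any():
            raise ValueError("raster cells must be finite or equal to nodata")

    # -- geometry -----------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_cols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def is_nodata(self, v) -> np.ndarray:
        return np.isclose(v, self.nodata, rtol=0.0, atol=1e-6)

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.is_nodata(self.values)

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def finite_values(self) -> np.ndarray:
        """1-D array of the non-nodata cell values."""
        return self.values[self.valid_mask]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Planar (x, y) of the center of cell (row, col); row 0 is the top."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"cell ({row}, {col}) outside {self.shape} grid")
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - row - 0.5) * self.cell_size
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (n_rows, n_cols) of cell-center x and y coordinates."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y + (self.n_rows - rows - 0.5) * self.cell_size
        return np.broadcast_to(x, self.shape).copy(), np.broadcast_to(
            y[:, None], self.shape
        ).copy()

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Inverse of :meth:`cell_center`: the cell containing point (x, y)."""
        col = int(np.floor((x - self.origin_x) / self.cell_size))
        row = self.n_rows - 1 - int(np.floor((y - self.origin_y) / self.cell_size))
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"point ({x}, {y}) outside grid extent")
        return row, col

    @property
    def diagonal(self) -> float:
        """Grid diagonal in meters (used as the 'no feature' distance cap)."""
        return float(
            np.hypot(self.n_rows * self.cell_size, self.n_cols * self.cell_size)
        )

    def same_geometry(self, other: "RasterGrid", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= atol
            and abs(self.origin_x - other.origin_x) <= atol
            and abs(self.origin_y - other.origin_y) <= atol
        )

    def like(self, values: np.ndarray) -> "RasterGrid":
        """A new grid with this geometry and the given values."""
        if np.asarray(values).shape != self.shape:
            raise ValueError("values shape does not match grid")
        return replace(self, values=np.asarray(values, dtype=float))

    def copy(self) -> "RasterGrid":
        return replace(self, values=self.values.copy())


@dataclass
class CovariateStack:
    """Named raster layers sharing one grid geometry.

    ``layer_kind`` tags each layer ``"continuous"`` or ``"categorical"``;
    categorical layers hold integer category codes indexing the ordered
    label list in ``category_labels``.
    """

    layers: dict[str, RasterGrid]
    layer_kind: dict[str, str] = field(default_factory=dict)
    category_labels: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = list(self.layers.values())
        for g in grids[1:]:
            if not g.same_geometry(grids[0]):
                raise ValueError("all stack layers must share grid geometry")
        for name in self.layers:
            self.layer_kind.setdefault(name, "continuous")
        for name, kind in self.layer_kind.items():
            if kind == "categorical":
                labels = self.category_labels.get(name)
                if not labels:
                    raise ValueError(f"categorical layer {name!r} needs labels")
                g = self.layers[name]
                vals = g.finite_values()
                codes = np.unique(vals)
                if not np.all(np.isin(codes, np.arange(len(labels)))):
                    raise ValueError(
                        f"layer {name!r} has codes outside its label list"
                    )

    @property
    def grid(self) -> RasterGrid:
        """Representative grid carrying the shared geometry."""
        return next(iter(self.layers.values()))

    def __getitem__(self, name: str) -> RasterGrid:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def names(self) -> list[str]:
        return list(self.layers)

    def copy(self) -> "CovariateStack":
        return CovariateStack(
            {k: v.copy() for k, v in self.layers.items()},
            dict(self.layer_kind),
            {k: list(v) for k, v in self.category_labels.items()},
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_raster(grid: RasterGrid, path, format: str = "ascii_grid") -> None:
    """Write ``grid`` to ``path`` in the named dialect.

    Overwriting an existing file succeeds with a logged warning.
    """
    import os

    if os.path.exists(path):
        warnings.warn(f"overwriting existing raster {path}", stacklevel=2)
    if format == "ascii_grid":
        _write_ascii(grid, path)
    elif format == "geotiff":
        _write_geotiff(grid, path)
    else:
        raise ValueError(f"unknown raster format {format!r}")


def read_raster(path, format: str = "ascii_grid") -> RasterGrid:
    """Read a raster written by :func:`write_raster` (or any file in the
    same dialect)."""
    import os

    if not os.path.exists(path):
        raise FileNotFoundError(f"raster file not found: {path}")
    if format == "ascii_grid":
        return _read_ascii(path)
    if format == "geotiff":
        return _read_geotiff(path)
    raise ValueError(f"unknown raster format {format!r}")


def _write_ascii(grid: RasterGrid, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.origin_x!r}\n")
        fh.write(f"yllcorner {grid.origin_y!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {grid.nodata!r}\n")
        for row in grid.values:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


_ASCII_HEADER_KEYS = {
    "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
}


def _read_ascii(path) -> RasterGrid:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            key = parts[0].lower()
            if not data_lines and key in _ASCII_HEADER_KEYS and len(parts) == 2:
                try:
                    header[key] = float(parts[1])
                except ValueError as exc:
                    raise RasterFormatError(
                        f"bad header value in {path}: {line!r}"
                    ) from exc
            else:
                data_lines.append(line)
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    missing = required - header.keys()
    if missing:
        raise RasterFormatError(
            f"malformed ASCII grid header in {path}: missing {sorted(missing)}"
        )
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    rows = []
    for i, line in enumerate(data_lines):
        vals = line.split()
        if len(vals) != ncols:
            raise RasterFormatError(
                f"row {i} of {path} has {len(vals)} values, header declares {ncols}"
            )
        try:
            rows.append([float(v) for v in vals])
        except ValueError as exc:
            raise RasterFormatError(f"non-numeric value in row {i} of {path}") from exc
    if len(rows) != nrows:
        raise RasterFormatError(
            f"{path} has {len(rows)} data rows, header declares {nrows}"
        )
    return RasterGrid(
        np.array(rows, dtype=float),
        cell_size=header["cellsize"],
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"],
        nodata=nodata,
    )


def _write_geotiff(grid: RasterGrid, path) -> None:
    import tifffile

    top_y = grid.origin_y + grid.n_rows * grid.cell_size
    scale = (grid.cell_size, grid.cell_size, 0.0)
    tiepoint = (0.0, 0.0, 0.0, grid.origin_x, top_y, 0.0)
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, scale, True),
        (_TAG_TIEPOINT, "d", 6, tiepoint, True),
        (_TAG_GDAL_NODATA, "s", 0, repr(grid.nodata), True),
    ]
    tifffile.imwrite(path, grid.values.astype(np.float64), extratags=extratags)


def _read_geotiff(path) -> RasterGrid:
    import tifffile

    try:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            values = page.asarray().astype(float)
            tags = page.tags
            if _TAG_PIXEL_SCALE not in tags or _TAG_TIEPOINT not in tags:
                raise RasterFormatError(
                    f"{path} lacks georeferencing tags (not a GeoTIFF?)"
                )
            scale = tags[_TAG_PIXEL_SCALE].value
            tiepoint = tags[_TAG_TIEPOINT].value
            nodata = DEFAULT_NODATA
            if _TAG_GDAL_NODATA in tags:
                nodata = float(tags[_TAG_GDAL_NODATA].value)
    except tifffile.TiffFileError as exc:
        raise RasterFormatError(f"cannot parse {path} as TIFF: {exc}") from exc
    cell = float(scale[0])
    origin_x = float(tiepoint[3])
    origin_y = float(tiepoint[4]) - values.shape[0] * cell
    return RasterGrid(values, cell_size=cell, origin_x=origin_x,
                      origin_y=origin_y, nodata=nodata)


# ---------------------------------------------------------------------------
# Aggregation from finer grids
# ---------------------------------------------------------------------------

def aggregate(grid: RasterGrid, factor: int, how: str = "mean") -> RasterGrid:
    """Aggregate a fine grid to a coarser one by an integer ``factor``.

    ``how="mean"`` for continuous layers, ``how="mode"`` (dominant value)
    for categorical ones; nodata cells are excluded from each block
    statistic, and all-nodata blocks stay nodata.
    """
    if factor < 1:
        raise ValueError("factor must be >= 1")
    nr, nc = grid.n_rows // factor, grid.n_cols // factor
    if nr == 0 or nc == 0:
        raise ValueError("grid too small for aggregation factor")
    v = grid.values[: nr * factor, : nc * factor]
    blocks = v.reshape(nr, factor, nc, factor).swapaxes(1, 2).reshape(nr, nc, -1)
    out = np.full((nr, nc), grid.nodata)
    for i in range(nr):
        for j in range(nc):
            b = blocks[i, j]
            b = b[~grid.is_nodata(b)]
            if b.size == 0:
                continue
            if how == "mean":
                out[i, j] = b.mean()
            elif how == "mode":
                vals, counts = np.unique(b, return_counts=True)
                out[i, j] = vals[np.argmax(counts)]
            else:
                raise ValueError(f"unknown aggregation {how!r}")
    top_y = grid.origin_y + grid.n_rows * grid.cell_size
    new_cell = grid.cell_size * factor
    return RasterGrid(out, cell_size=new_cell, origin_x=grid.origin_x,
                      origin_y=top_y - nr * new_cell, nodata=grid.nodata)
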