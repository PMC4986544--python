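"""Planar raster grids and co-registered covariate stacks.

All rasters in this package live on a single north-up, row-major grid in a
planar equal-area coordinate frame: pixel (0, 0) is the top-left pixel, rows
increase southward, columns increase eastward.  Pixel footprints are half-open,
``[x, x + s) x (y - s, y]`` for pixel side ``s``, so every point in the grid's
extent belongs to exactly one pixel and point-in-raster joins are
deterministic.

On-disk representation is the ESRI ASCII grid (``.asc``) — a plain-text,
GIS-standard single-band raster — with a JSON sidecar recording band names,
nodata and the coordinate frame for multi-band stacks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["GridSpec", "CovariateStack", "read_ascii_grid", "write_ascii_grid"]


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up raster grid in a planar equal-area frame.

    Parameters
    ----------
    n_rows, n_cols
        Pixel counts; must be >= 1.
    pixel_side_m
        Side length of the square pixels in metres; must be > 0.
    origin
        ``(x, y)`` of the grid's top-left corner in the planar frame.
    crs
        Free-text label of the coordinate reference frame, recorded in
        metadata.  The package performs no reprojection.
    """

    n_rows: int
    n_cols: int
    pixel_side_m: float
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str = "local-equal-area"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(f"grid dimensions must be >= 1, got {self.n_rows}x{self.n_cols}")
        if not self.pixel_side_m > 0:
            raise ValueError(f"pixel_side_m must be > 0, got {self.pixel_side_m}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def n_pixels(self) -> int:
        return self.n_rows * self.n_cols

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(x, y)`` arrays of shape ``(n_rows, n_cols)`` of pixel centres."""
        s = self.pixel_side_m
        x0, y0 = self.origin
        xs = x0 + (np.arange(self.n_cols) + 0.5) * s
        ys = y0 - (np.arange(self.n_rows) + 0.5) * s
        return np.meshgrid(xs, ys)

    def point_to_pixel(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map planar points to (row, col) under the half-open footprint rule.

        A point on a shared vertical edge belongs to the pixel on its right
        (``x`` interval closed on the left); a point on a shared horizontal
        edge belongs to the pixel above (``y`` interval closed on the top).
        Returns ``(row, col, inside)`` where ``inside`` flags points whose
        containing pixel lies within the grid.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        s = self.pixel_side_m
        x0, y0 = self.origin
        col = np.floor((x - x0) / s).astype(int)
        # With t = (y0 - y)/s, row r spans t in [r, r+1): a point on the top
        # edge of row r has t == r exactly, so floor(t) realises the
        # closed-top / open-bottom convention.
        row = np.floor((y0 - y) / s).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        return row, col, inside


@dataclass
class CovariateStack:
    """Named, co-registered raster bands on one :class:`GridSpec`.

    Invariants: every band has shape ``grid.shape``; band names are unique.
    ``nodata`` cells are stored as NaN.
    """

    grid: GridSpec
    bands: dict[str, np.ndarray] = field(default_factory=dict)
    nodata: float = float("nan")

    def __post_init__(self) -> None:
        for name, band in self.bands.items():
            band = np.asarray(band, dtype=np.float64)
            if band.shape != self.grid.shape:
                raise ValueError(
                    f"band {name!r} has shape {band.shape}, expected {self.grid.shape}"
                )
            self.bands[name] = band

    @property
    def names(self) -> list[str]:
        return list(self.bands)

    def band(self, name: str) -> np.ndarray:
        try:
            return self.bands[name]
        except KeyError:
            raise KeyError(f"no band named {name!r}; available: {sorted(self.bands)}") from None

    def add_band(self, name: str, values: np.ndarray) -> None:
        if name in self.bands:
            raise ValueError(f"band {name!r} already present")
        values = np.asarray(values, dtype=np.float64)
        if values.shape != self.grid.shape:
            raise ValueError(f"band {name!r} has shape {values.shape}, expected {self.grid.shape}")
        self.bands[name] = values

    def design_matrix(self, terms: list[str]) -> np.ndarray:
        """Stack the named bands into an ``(n_pixels, len(terms))`` matrix, row-major."""
        return np.column_stack([self.band(t).ravel() for t in terms]) if terms else np.empty((self.grid.n_pixels, 0))

    def write(self, directory: str | Path, dtype: str = "float32") -> None:
        """Write one ``.asc`` file per band plus a ``stack.json`` sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, band in self.bands.items():
            write_ascii_grid(directory / f"{name}.asc", band.astype(dtype), self.grid)
        meta = {
            "bands": self.names,
            "crs": self.grid.crs,
            "pixel_side_m": self.grid.pixel_side_m,
            "origin": list(self.grid.origin),
            "shape": list(self.grid.shape),
        }
        (directory / "stack.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def read(cls, directory: str | Path) -> "CovariateStack":
        directory = Path(directory)
        meta = json.loads((directory / "stack.json").read_text())
        bands = {}
        grid = None
        for name in meta["bands"]:
            band, grid = read_ascii_grid(directory / f"{name}.asc")
            bands[name] = band
        assert grid is not None
        grid = GridSpec(grid.n_rows, grid.n_cols, grid.pixel_side_m, tuple(meta["origin"]), meta["crs"])
        return cls(grid=grid, bands=bands)


_NODATA_SENTINEL = -9999.0


def write_ascii_grid(path: str | Path, values: np.ndarray, grid: GridSpec) -> None:
    """Write a single band as an ESRI ASCII grid (north-up, row-major)."""
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"values shape {values.shape} != grid shape {grid.shape}")
    x0, y0 = grid.origin
    yll = y0 - grid.n_rows * grid.pixel_side_m
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {x0!r}\n"
        f"yllcorner {yll!r}\n"
        f"cellsize {grid.pixel_side_m!r}\n"
        f"NODATA_value {_NODATA_SENTINEL!r}\n"
    )
    body = np.where(np.isnan(values), _NODATA_SENTINEL, values)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.10g")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Read an ESRI ASCII grid; NODATA cells become NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    values = values.reshape(n_rows, n_cols)
    nodata = header.get("nodata_value", _NODATA_SENTINEL)
    values = np.where(values == nodata, np.nan, values)
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + n_rows * cell)
    return values, GridSpec(n_rows, n_cols, cell, origin)
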