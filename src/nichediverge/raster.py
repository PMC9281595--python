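"""Lightweight geographic rasters on regular lon/lat grids.

Rasters are stored as dense numpy arrays with a north-up affine transform.
Persistence uses the plain-text ESRI ASCII grid format (one ``.asc`` file per
layer plus a small JSON manifest for a multilayer stack), which keeps all
artifacts human-readable and diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GridTransform",
    "ClimateStack",
    "SuitabilityMap",
    "read_ascii_grid",
    "write_ascii_grid",
]

DEFAULT_NODATA = -9999.0


@dataclass(frozen=True)
class GridTransform:
    """North-up affine transform for a regular grid.

    ``x_origin``/``y_origin`` are the coordinates of the *outer* top-left
    corner; rows increase southwards, columns eastwards.
    """

    x_origin: float
    y_origin: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError("cell sizes dx, dy must be positive")

    def cell_center(self, row, col):
        """(lon, lat) of cell centers; accepts scalars or arrays."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        lon = self.x_origin + (col + 0.5) * self.dx
        lat = self.y_origin - (row + 0.5) * self.dy
        return lon, lat

    def index_of(self, lon, lat):
        """(row, col) integer indices of the cells containing the points."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.x_origin) / self.dx).astype(int)
        row = np.floor((self.y_origin - lat) / self.dy).astype(int)
        return row, col


@dataclass
class ClimateStack:
    """Aligned multilayer environmental raster.

    ``grid`` has shape (rows, cols, n_layers); the nodata mask must be
    identical across layers.
    """

    layer_names: list[str]
    grid: np.ndarray
    transform: GridTransform
    crs: str = "EPSG:4326"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError("grid must be rows x cols x n_layers")
        if self.grid.shape[2] != len(self.layer_names):
            raise ValueError("layer_names length must match grid depth")
        if len(set(self.layer_names)) != len(self.layer_names):
            raise ValueError("layer_names must be unique")
        masks = self.grid == self.nodata
        if masks.any() and not (masks.all(axis=2) | (~masks).all(axis=2)).all():
            raise ValueError("nodata mask must be identical across layers")

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape[:2]

    @property
    def n_layers(self) -> int:
        return self.grid.shape[2]

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean (rows, cols) mask of cells with data in every layer."""
        return ~(self.grid == self.nodata).any(axis=2)

    def layer(self, name: str) -> np.ndarray:
        try:
            idx = self.layer_names.index(name)
        except ValueError:
            raise KeyError(f"unknown layer {name!r}") from None
        return self.grid[:, :, idx]

    def extract(self, lon, lat) -> np.ndarray:
        """Per-layer values at the cells containing the points.

        Points outside the extent or on nodata cells yield NaN rows.
        """
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        rows, cols = self.transform.index_of(lon, lat)
        nr, nc = self.shape
        inside = (rows >= 0) & (rows < nr) & (cols >= 0) & (cols < nc)
        out = np.full((lon.size, self.n_layers), np.nan)
        if inside.any():
            vals = self.grid[rows[inside], cols[inside], :]
            vals = np.where(vals == self.nodata, np.nan, vals)
            out[inside] = vals
        return out

    def valid_cell_table(self) -> pd.DataFrame:
        """One row per non-nodata cell: row, col, lon, lat, layer columns."""
        rows, cols = np.nonzero(self.valid_mask)
        lon, lat = self.transform.cell_center(rows, cols)
        df = pd.DataFrame({"row": rows, "col": cols, "lon": lon, "lat": lat})
        for j, name in enumerate(self.layer_names):
            df[name] = self.grid[rows, cols, j]
        return df

    def with_grid(self, grid: np.ndarray) -> "ClimateStack":
        return replace(self, grid=grid, layer_names=list(self.layer_names))

    # ---- persistence -----------------------------------------------------

    def write(self, directory) -> None:
        """Write one ``<layer>.asc`` per layer plus ``stack.json``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for j, name in enumerate(self.layer_names):
            write_ascii_grid(
                directory / f"{name}.asc",
                self.grid[:, :, j],
                self.transform,
                nodata=self.nodata,
            )
        manifest = {
            "layer_names": self.layer_names,
            "crs": self.crs,
            "nodata": self.nodata,
        }
        (directory / "stack.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def read(cls, directory) -> "ClimateStack":
        directory = Path(directory)
        manifest = json.loads((directory / "stack.json").read_text())
        layers = []
        transform = None
        for name in manifest["layer_names"]:
            arr, tr, nodata = read_ascii_grid(directory / f"{name}.asc")
            arr = np.where(arr == nodata, manifest["nodata"], arr)
            layers.append(arr)
            transform = tr
        grid = np.stack(layers, axis=2)
        return cls(
            layer_names=list(manifest["layer_names"]),
            grid=grid,
            transform=transform,
            crs=manifest.get("crs", "EPSG:4326"),
            nodata=manifest["nodata"],
        )


@dataclass
class SuitabilityMap:
    """Per-cell suitability in [0, 1] (or nodata) on a ClimateStack grid."""

    grid: np.ndarray
    transform: GridTransform
    crs: str = "EPSG:4326"
    nodata: float = DEFAULT_NODATA
    period: str = "present"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        vals = self.grid[self.grid != self.nodata]
        if vals.size and (np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9):
            raise ValueError("suitability values must lie in [0, 1]")

    @property
    def valid_mask(self) -> np.ndarray:
        return self.grid != self.nodata

    def write(self, path) -> None:
        write_ascii_grid(path, self.grid, self.transform, nodata=self.nodata)


def write_ascii_grid(path, array: np.ndarray, transform: GridTransform,
                     nodata: float = DEFAULT_NODATA) -> None:
    """Write a 2-D array as an ESRI ASCII grid (requires square cells)."""
    array = np.asarray(array, dtype=float)
    if abs(transform.dx - transform.dy) > 1e-9 * max(transform.dx, transform.dy):
        raise ValueError("ASCII grid format requires square cells")
    nrows, ncols = array.shape
    header = (
        f"ncols {ncols}\n"
        f"nrows {nrows}\n"
        f"xllcorner {transform.x_origin!r}\n"
        f"yllcorner {transform.y_origin - nrows * transform.dy!r}\n"
        f"cellsize {transform.dx!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    body = np.where(np.isnan(array), nodata, array)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, body, fmt="%.10g")


def read_ascii_grid(path) -> tuple[np.ndarray, GridTransform, float]:
    """Read an ESRI ASCII grid; returns (array, transform, nodata)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and not _is_number(parts[0]):
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        array = np.loadtxt(fh, ndmin=2)
    nrows = int(header["nrows"])
    ncols = int(header["ncols"])
    if array.shape != (nrows, ncols):
        raise ValueError(f"grid body shape {array.shape} != header ({nrows}, {ncols})")
    cell = header["cellsize"]
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    transform = GridTransform(
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + nrows * cell,
        dx=cell,
        dy=cell,
    )
    return array, transform, nodata


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False
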