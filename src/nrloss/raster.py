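"""Minimal single-band raster container with plain-text (Esri ASCII grid) I/O.

Grids are north-up, row 0 is the northernmost row, and cell values are
registered to cell centers. The ASCII-grid format (``.asc``) is readable
by GDAL, QGIS and ArcGIS, which keeps exported inventories portable
without binary formats.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_NODATA = -9999.0


@dataclass
class Raster:
    """A single-band grid.

    Parameters
    ----------
    data : 2-D float array, shape (ny, nx); NaN marks nodata.
    xll, yll : coordinates of the lower-left corner of the grid (not of
        the first cell center).
    cellsize : edge length of the square cells, in CRS units.
    crs : free-text CRS tag recorded in sidecar metadata (synthetic runs
        default to a local planar system).
    """

    data: np.ndarray
    xll: float = 0.0
    yll: float = 0.0
    cellsize: float = 1.0
    crs: str = "local-planar"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("raster data must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def same_grid(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.xll, other.xll)
            and np.isclose(self.yll, other.yll)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinates, each shaped like ``data``."""
        ny, nx = self.data.shape
        xs = self.xll + (np.arange(nx) + 0.5) * self.cellsize
        ys = self.yll + (ny - np.arange(ny) - 0.5) * self.cellsize  # row 0 = north
        return np.meshgrid(xs, ys)

    def copy_with(self, data: np.ndarray) -> "Raster":
        if np.shape(data) != self.shape:
            raise ValueError("replacement data has wrong shape")
        return Raster(np.asarray(data, float), self.xll, self.yll, self.cellsize, self.crs)


def write_ascii_grid(raster: Raster, path: str | Path) -> Path:
    """Write an Esri ASCII grid plus a small JSON sidecar with the CRS."""
    path = Path(path)
    ny, nx = raster.shape
    body = np.where(np.isnan(raster.data), _NODATA, raster.data)
    header = (
        f"ncols {nx}\n"
        f"nrows {ny}\n"
        f"xllcorner {raster.xll!r}\n"
        f"yllcorner {raster.yll!r}\n"
        f"cellsize {raster.cellsize!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in body:
            fh.write(" ".join(format(v, ".17g") for v in row) + "\n")
    path.with_suffix(path.suffix + ".aux.json").write_text(
        json.dumps({"crs": raster.crs}) + "\n"
    )
    return path


def read_ascii_grid(path: str | Path) -> Raster:
    path = Path(path)
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value", _NODATA)
    data[data == nodata] = np.nan
    crs = "local-planar"
    sidecar = path.with_suffix(path.suffix + ".aux.json")
    if sidecar.exists():
        crs = json.loads(sidecar.read_text()).get("crs", crs)
    return Raster(
        data,
        xll=header["xllcorner"],
        yll=header["yllcorner"],
        cellsize=header["cellsize"],
        crs=crs,
    )


@dataclass
class RasterStack:
    """Aligned named layers sharing one grid definition."""

    layers: dict[str, Raster] = field(default_factory=dict)

    def add(self, name: str, raster: Raster) -> None:
        if self.layers:
            ref = next(iter(self.layers.values()))
            if not ref.same_grid(raster):
                raise ValueError(f"layer {name!r} is not aligned with the stack")
        self.layers[name] = raster

    def __getitem__(self, name: str) -> Raster:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers
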