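"""Gridded climate rasters.

:class:`ClimateGrid` holds one 2-D array per bioclimatic variable on a shared
regular lon/lat grid with a shared no-data mask and an epoch tag.  Grids
round-trip through the ESRI ASCII grid text format (one ``.asc`` file per
variable).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["ClimateGrid", "read_ascii_grid", "write_ascii_grid"]

_NODATA = -9999.0


@dataclass
class ClimateGrid:
    """Raster stack: variable -> (ny, nx) array; rows north to south."""

    variables: dict[str, np.ndarray]
    x: np.ndarray               # cell-centre longitudes, ascending
    y: np.ndarray               # cell-centre latitudes, descending (row order)
    mask: np.ndarray | None = None   # True where valid
    epoch: str = "current"

    def __post_init__(self) -> None:
        shape = (len(self.y), len(self.x))
        for name, arr in self.variables.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != shape:
                raise ValueError(f"variable {name!r} shape {arr.shape} != {shape}")
            self.variables[name] = arr
        if self.mask is None:
            self.mask = np.ones(shape, dtype=bool)
        if self.mask.shape != shape:
            raise ValueError("mask shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.y), len(self.x))

    def same_geometry(self, other: "ClimateGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.x, other.x)
            and np.allclose(self.y, other.y)
            and bool(np.array_equal(self.mask, other.mask))
        )

    def cell_index(self, lat: float, lon: float) -> tuple[int, int]:
        """(row, col) of the cell containing the point."""
        col = int(np.argmin(np.abs(self.x - lon)))
        row = int(np.argmin(np.abs(self.y - lat)))
        return row, col

    def extract(self, coords: dict[str, tuple[float, float]]):
        """Per-site values of every variable at the containing cell."""
        import pandas as pd

        rows = {}
        for site, (lat, lon) in coords.items():
            r, c = self.cell_index(lat, lon)
            rows[site] = {v: self.variables[v][r, c] for v in self.variables}
        return pd.DataFrame(rows).T

    def with_variables(self, variables: dict[str, np.ndarray],
                       epoch: str | None = None) -> "ClimateGrid":
        return ClimateGrid(
            variables={k: v.copy() for k, v in variables.items()},
            x=self.x.copy(), y=self.y.copy(), mask=self.mask.copy(),
            epoch=epoch or self.epoch,
        )

    # -- text I/O ---------------------------------------------------------
    def write(self, directory, prefix: str = "") -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, arr in self.variables.items():
            write_ascii_grid(directory / f"{prefix}{name}.asc", arr, self.x,
                             self.y, self.mask)

    @classmethod
    def read(cls, directory, epoch: str = "current") -> "ClimateGrid":
        directory = Path(directory)
        variables = {}
        x = y = mask = None
        for path in sorted(directory.glob("*.asc")):
            arr, x, y, mask = read_ascii_grid(path)
            variables[path.stem] = arr
        if not variables:
            raise FileNotFoundError(f"no .asc grids in {directory}")
        return cls(variables=variables, x=x, y=y, mask=mask, epoch=epoch)


def write_ascii_grid(path, arr, x, y, mask) -> None:
    cell = float(x[1] - x[0]) if len(x) > 1 else 1.0
    vals = np.where(mask, arr, _NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {len(x)}\nnrows {len(y)}\n")
        fh.write(f"xllcorner {x[0] - cell / 2}\nyllcorner {y[-1] - cell / 2}\n")
        fh.write(f"cellsize {cell}\nNODATA_value {_NODATA}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def read_ascii_grid(path):
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    data = data.reshape(nrows, ncols)
    cell = header["cellsize"]
    x = header["xllcorner"] + cell / 2 + cell * np.arange(ncols)
    y = header["yllcorner"] + cell / 2 + cell * np.arange(nrows)[::-1]
    nodata = header.get("nodata_value", _NODATA)
    mask = data != nodata
    return np.where(mask, data, np.nan), x, y, mask
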