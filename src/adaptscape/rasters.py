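"""Gridded raster layers and ESRI ASCII grid I/O.

All spatial stages of the pipeline (landscape simulation, niche modelling,
circuit-theory connectivity) operate on small co-registered grids held in a
:class:`RasterStack`.  The only on-disk raster format supported is the plain
text ESRI ASCII grid (``.asc``), which is what the pipeline reads and writes.

Grid convention: ``values[0, 0]`` is the upper-left cell; cell centers sit at
half-cell offsets from the lower-left corner (``xllcorner``, ``yllcorner``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Raster", "RasterStack", "read_ascii_grid", "write_ascii_grid", "GeometryError"]


class GeometryError(ValueError):
    """Raised when rasters that must be co-registered are not."""


@dataclass
class Raster:
    """A single grid layer with georeferencing.

    Parameters
    ----------
    values : ndarray of shape (nrows, ncols)
        Cell values; ``nodata`` cells hold the nodata marker.
    xllcorner, yllcorner : float
        Coordinates of the lower-left corner of the grid.
    cellsize : float
        Side length of a (square) cell, in map units.
    nodata : float
        Marker for missing cells.
    """

    values: np.ndarray
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 1.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GeometryError("raster values must be 2-D")
        if self.cellsize <= 0:
            raise GeometryError("cellsize must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isclose(self.values, self.nodata) & np.isfinite(self.values)

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    def same_geometry(self, other: "Raster") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.xllcorner, other.xllcorner)
            and np.isclose(self.yllcorner, other.yllcorner)
            and np.isclose(self.cellsize, other.cellsize)
        )

    def copy_with(self, values: np.ndarray) -> "Raster":
        return Raster(np.array(values, dtype=float), self.xllcorner, self.yllcorner, self.cellsize, self.nodata)

    # -- coordinate helpers ---------------------------------------------------
    def rowcol_to_xy(self, row: np.ndarray, col: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map row/col indices to cell-center coordinates."""
        nrows = self.shape[0]
        x = self.xllcorner + (np.asarray(col) + 0.5) * self.cellsize
        y = self.yllcorner + (nrows - np.asarray(row) - 0.5) * self.cellsize
        return x, y

    def xy_to_rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to the row/col of the containing cell."""
        nrows = self.shape[0]
        col = np.floor((np.asarray(x) - self.xllcorner) / self.cellsize).astype(int)
        row = nrows - 1 - np.floor((np.asarray(y) - self.yllcorner) / self.cellsize).astype(int)
        return row, col

    def contains_xy(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        nrows, ncols = self.shape
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (
            (x >= self.xllcorner)
            & (x < self.xllcorner + ncols * self.cellsize)
            & (y >= self.yllcorner)
            & (y < self.yllcorner + nrows * self.cellsize)
        )


@dataclass
class RasterStack:
    """Named, co-registered raster layers (e.g. bioclimatic variables)."""

    layers: dict[str, Raster] = field(default_factory=dict)

    def __post_init__(self) -> None:
        rasters = list(self.layers.values())
        for r in rasters[1:]:
            if not rasters[0].same_geometry(r):
                raise GeometryError("all layers in a RasterStack must share geometry")

    @property
    def names(self) -> list[str]:
        return list(self.layers)

    def __len__(self) -> int:
        return len(self.layers)

    def __getitem__(self, name: str) -> Raster:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    @property
    def template(self) -> Raster:
        return next(iter(self.layers.values()))

    @property
    def valid_mask(self) -> np.ndarray:
        """Cells valid in every layer."""
        mask = np.ones(self.template.shape, dtype=bool)
        for r in self.layers.values():
            mask &= r.valid_mask
        return mask

    def add(self, name: str, raster: Raster) -> None:
        if self.layers and not self.template.same_geometry(raster):
            raise GeometryError(f"layer {name!r} does not match stack geometry")
        self.layers[name] = raster

    def subset(self, names: list[str]) -> "RasterStack":
        return RasterStack({n: self.layers[n] for n in names})

    def env_at_rowcol(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Environmental values at cells, as an (n_points, n_layers) array."""
        return np.column_stack([self.layers[n].values[rows, cols] for n in self.names])

    def same_geometry(self, other: "RasterStack") -> bool:
        return self.template.same_geometry(other.template)


def read_ascii_grid(path) -> Raster:
    """Read an ESRI ASCII grid (.asc)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise GeometryError(f"missing {key} in ASCII grid header: {path}")
    body = "\n".join(lines[i:]).split()
    values = np.array(body, dtype=float) if body else np.array([])
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if values.size != nrows * ncols:
        raise GeometryError(
            f"ASCII grid {path}: expected {nrows * ncols} values, found {values.size}"
        )
    return Raster(
        values.reshape(nrows, ncols),
        xllcorner=header.get("xllcorner", 0.0),
        yllcorner=header.get("yllcorner", 0.0),
        cellsize=header["cellsize"],
        nodata=header.get("nodata_value", -9999.0),
    )


def write_ascii_grid(raster: Raster, path) -> None:
    """Write an ESRI ASCII grid (.asc) with the canonical 6-line header."""
    nrows, ncols = raster.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {raster.xllcorner:.6f}\n")
        fh.write(f"yllcorner {raster.yllcorner:.6f}\n")
        fh.write(f"cellsize {raster.cellsize:.6f}\n")
        fh.write(f"NODATA_value {raster.nodata:g}\n")
        for row in raster.values:
            fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")
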