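"""Gridded ecophysiological layers from temperature grids and fitted curves.

A :class:`ClimateGrid` stacks 12 monthly maximum-air-temperature layers on a
common rectangular grid with one shared nodata mask. Applying a fitted
Richards curve cellwise turns temperature layers into hours-of-activity or
hours-of-restriction layers — the species-specific predictors a
distribution model can consume alongside generic bioclimatic variables.
Layers are exchanged as ESRI ASCII grids (plain text, first data row is the
northernmost), so no geospatial library is required; the grid is abstract
unless a real-world origin/cell size is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from thermovuln.restriction import RichardsParams, richards_eval

__all__ = ["ClimateGrid", "grid_apply", "read_ascii_grid", "write_ascii_grid",
           "suitability_mask"]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


@dataclass(frozen=True)
class ClimateGrid:
    """Twelve monthly layers sharing shape, origin and nodata mask."""

    layers: np.ndarray                       # (12, ny, nx)
    nodata: float = -9999.0
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.layers, dtype=float)
        if arr.ndim != 3 or arr.shape[0] != 12:
            raise ValueError("layers must be a (12, ny, nx) stack")
        object.__setattr__(self, "layers", arr)
        masks = arr == self.nodata
        if not np.all(masks == masks[0]):
            raise ValueError("nodata mask must be identical across months")

    @property
    def shape(self) -> tuple[int, int]:
        return self.layers.shape[1:]

    @property
    def mask(self) -> np.ndarray:
        return self.layers[0] == self.nodata

    def crop(self, row_slice: slice, col_slice: slice) -> "ClimateGrid":
        return replace(self, layers=self.layers[:, row_slice, col_slice])

    def offset(self, delta: float) -> "ClimateGrid":
        """Uniform warming offset on valid cells; nodata preserved."""
        shifted = np.where(self.mask, self.nodata, self.layers + delta)
        return replace(self, layers=shifted)


def grid_apply(grid: ClimateGrid, p: RichardsParams) -> dict:
    """Evaluate a Richards curve on every valid cell of every month.

    Returns ``{"monthly": (12, ny, nx) hours, "annual": (ny, nx) mean of the
    12 months, "nodata": sentinel}``; nodata cells propagate unchanged. A
    bracket-domain violation anywhere on the valid cells raises, naming the
    offending temperature range.
    """
    mask = grid.mask
    valid = grid.layers[:, ~mask]  # (12, n_valid)
    try:
        hours_valid = richards_eval(valid, p)
    except ValueError as exc:
        raise ValueError(
            f"curve undefined over grid temperatures "
            f"[{valid.min():.2f}, {valid.max():.2f}] degC: {exc}") from exc
    monthly = np.full_like(grid.layers, grid.nodata)
    monthly[:, ~mask] = hours_valid
    annual = np.full(grid.shape, grid.nodata)
    annual[~mask] = hours_valid.mean(axis=0)
    return {"monthly": monthly, "annual": annual, "nodata": grid.nodata}


def suitability_mask(annual_ha: np.ndarray, annual_hr: np.ndarray,
                     nodata: float, min_ha: float = 6.0, max_hr: float = 6.0
                     ) -> np.ndarray:
    """Convenience binary layer: enough activity, tolerable restriction.

    1 where annual mean h_a >= ``min_ha`` and annual mean h_r <= ``max_hr``,
    0 elsewhere, nodata propagated. A screening product only — not a
    distribution model.
    """
    valid = (annual_ha != nodata) & (annual_hr != nodata)
    out = np.where((annual_ha >= min_ha) & (annual_hr <= max_hr), 1.0, 0.0)
    return np.where(valid, out, nodata)


def write_ascii_grid(layer: np.ndarray, path: str | Path, nodata: float = -9999.0,
                     cell_size: float = 1.0, origin: tuple[float, float] = (0.0, 0.0),
                     fmt: str = "%.4f") -> None:
    """Write one layer as an ESRI ASCII grid (row 0 = northernmost row)."""
    arr = np.asarray(layer, dtype=float)
    if arr.ndim != 2:
        raise ValueError("layer must be 2-D")
    ny, nx = arr.shape
    header = (f"ncols {nx}\nnrows {ny}\n"
              f"xllcorner {origin[0]}\nyllcorner {origin[1]}\n"
              f"cellsize {cell_size}\nNODATA_value {nodata}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, arr, fmt=fmt)


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns ``(layer, header)``.

    The header dict carries ncols, nrows, xllcorner, yllcorner, cellsize and
    nodata_value (defaulting to -9999 when the optional key is absent).
    Raises on malformed headers and ragged or mis-sized data blocks.
    """
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in _HEADER_KEYS + ("nodata_value",):
                if len(parts) != 2:
                    raise ValueError(f"malformed header line: {line!r}")
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for key in _HEADER_KEYS:
        if key not in header:
            raise ValueError(f"missing required header key {key!r}")
    header.setdefault("nodata_value", -9999.0)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    rows = []
    for line in data_lines:
        vals = [float(v) for v in line.split()]
        rows.append(vals)
    flat = [v for r in rows for v in r]
    if len(flat) != ncols * nrows:
        raise ValueError(f"expected {ncols * nrows} cells, found {len(flat)}")
    for r in rows[:-1]:
        if len(r) != ncols and len(rows) == nrows:
            raise ValueError("ragged data rows")
    layer = np.array(flat, dtype=float).reshape(nrows, ncols)
    return layer, header
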