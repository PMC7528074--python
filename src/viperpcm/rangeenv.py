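"""Ecogeographic range descriptors from monthly climate raster stacks.

For each lineage range (a set of grid cells at 10-arcmin resolution, WGS84)
the module computes 21 descriptors:

* monthly variables, summarized as spatial range means per month and then
  across months — ``TAVGavg/max/min``, ``TMAXmax/min``, ``TMINmax/min``,
  ``VPRavg/max/min``;
* annually summed variables, summarized spatially over the annual raster —
  ``SRADavg/max/min``, ``PRECmax/min``;
* static layers — ``ELEVavg/max/min`` and the cell-centre latitudes
  ``LATavg/max/min``.

Before any climatic or topographic summary, the 5% lower and upper sample
quantiles are trimmed within each value distribution, except for ranges
smaller than 20 cells (and never for latitude, which describes the range
itself rather than sampling an environment).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RasterGrid",
    "RangeMask",
    "RasterStack",
    "RangeEnvError",
    "DESCRIPTOR_NAMES",
    "MONTHLY_VARIABLES",
    "ANNUAL_VARIABLES",
    "trim_quantiles",
    "temperature_descriptors",
    "annual_sum_descriptors",
    "static_descriptors",
    "latitude_descriptors",
    "range_descriptor_table",
    "mask_from_polygon",
    "read_masks_csv",
    "write_masks_csv",
]

DESCRIPTOR_NAMES = [
    "PRECmax", "PRECmin",
    "SRADavg", "SRADmax", "SRADmin",
    "TAVGavg", "TAVGmax", "TAVGmin",
    "TMAXmax", "TMAXmin",
    "TMINmax", "TMINmin",
    "VPRavg", "VPRmax", "VPRmin",
    "ELEVavg", "ELEVmax", "ELEVmin",
    "LATavg", "LATmax", "LATmin",
]

#: monthly variables summarized across months (prefix -> reported stats)
MONTHLY_VARIABLES = {
    "tavg": ("avg", "max", "min"),
    "tmax": ("max", "min"),
    "tmin": ("max", "min"),
    "vpr": ("avg", "max", "min"),
}

#: variables summed to annual rasters and summarized spatially
ANNUAL_VARIABLES = {
    "srad": ("avg", "max", "min"),
    "prec": ("max", "min"),
}

#: 10 arcmin in decimal degrees
TEN_ARCMIN = 1.0 / 6.0


class RangeEnvError(ValueError):
    """Raised on grid/mask inconsistencies or empty extractions."""


@dataclass
class RasterGrid:
    """A regular lon/lat grid of values; NaN marks missing data.

    ``origin_lon``/``origin_lat`` locate the lower-left corner of the grid;
    row indices increase northwards, column indices eastwards, and cell
    centres sit half a cell in from the corner.
    """

    values: np.ndarray
    origin_lon: float = 0.0
    origin_lat: float = 0.0
    cell_size: float = TEN_ARCMIN

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise RangeEnvError("raster values must be a 2-D matrix")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_grid(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.origin_lon, other.origin_lon)
            and np.isclose(self.origin_lat, other.origin_lat)
            and np.isclose(self.cell_size, other.cell_size)
        )

    def cell_center_lat(self, row) -> np.ndarray | float:
        return self.origin_lat + (np.asarray(row) + 0.5) * self.cell_size

    def cell_center_lon(self, col) -> np.ndarray | float:
        return self.origin_lon + (np.asarray(col) + 0.5) * self.cell_size

    def cell_of(self, lon: float, lat: float) -> tuple[int, int]:
        """Grid cell containing a point; raises if outside the extent."""
        n_rows, n_cols = self.shape
        col = int(np.floor((lon - self.origin_lon) / self.cell_size))
        row = int(np.floor((lat - self.origin_lat) / self.cell_size))
        if not (0 <= row < n_rows and 0 <= col < n_cols):
            raise RangeEnvError(
                f"point ({lon:.4f}, {lat:.4f}) is outside the grid extent"
            )
        return row, col

    # -- plain-grid CSV dialect --------------------------------------------
    def to_csv(self, path) -> None:
        header = (
            f"# grid n_rows={self.shape[0]} n_cols={self.shape[1]} "
            f"origin_lon={self.origin_lon!r} origin_lat={self.origin_lat!r} "
            f"cell_size={self.cell_size!r}"
        )
        with open(path, "w") as fh:
            fh.write(header + "\n")
            np.savetxt(fh, self.values, delimiter=",", fmt="%.10g")

    @classmethod
    def from_csv(cls, path) -> "RasterGrid":
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("# grid"):
                raise RangeEnvError(f"{path}: missing plain-grid header line")
            meta = dict(
                item.split("=") for item in header.replace("# grid", "").split()
            )
            values = np.loadtxt(fh, delimiter=",", ndmin=2)
        grid = cls(
            values,
            origin_lon=float(meta["origin_lon"]),
            origin_lat=float(meta["origin_lat"]),
            cell_size=float(meta["cell_size"]),
        )
        if grid.shape != (int(meta["n_rows"]), int(meta["n_cols"])):
            raise RangeEnvError(f"{path}: value matrix does not match header shape")
        return grid


@dataclass(frozen=True)
class RangeMask:
    """Set of member grid cells of one lineage's distribution range."""

    lineage_id: str
    cells: frozenset

    def __post_init__(self) -> None:
        if not self.cells:
            raise RangeEnvError(f"range mask {self.lineage_id!r} is empty")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def rows_cols(self) -> tuple[np.ndarray, np.ndarray]:
        cells = sorted(self.cells)
        rows = np.array([c[0] for c in cells], dtype=int)
        cols = np.array([c[1] for c in cells], dtype=int)
        return rows, cols

    def check_extent(self, grid: RasterGrid) -> None:
        rows, cols = self.rows_cols()
        n_rows, n_cols = grid.shape
        if rows.min() < 0 or cols.min() < 0 or rows.max() >= n_rows or cols.max() >= n_cols:
            raise RangeEnvError(
                f"range mask {self.lineage_id!r} has cells outside the grid"
            )


def mask_from_polygon(lineage_id: str, polygon, grid: RasterGrid) -> RangeMask:
    """Rasterize a polygon: a cell is a member if its centre lies inside."""
    import shapely

    n_rows, n_cols = grid.shape
    rows, cols = np.meshgrid(np.arange(n_rows), np.arange(n_cols), indexing="ij")
    lats = grid.cell_center_lat(rows)
    lons = grid.cell_center_lon(cols)
    inside = shapely.contains_xy(polygon, lons.ravel(), lats.ravel()).reshape(
        n_rows, n_cols
    )
    cells = frozenset(zip(*np.nonzero(inside)))
    return RangeMask(lineage_id, cells)


def write_masks_csv(masks: Mapping[str, RangeMask], grid: RasterGrid, path) -> None:
    """Two-column mask export: lineage_id, cell_index (row-major)."""
    n_cols = grid.shape[1]
    rows = []
    for lid in sorted(masks):
        for r, c in sorted(masks[lid].cells):
            rows.append({"lineage_id": lid, "cell_index": r * n_cols + c})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_masks_csv(path, grid: RasterGrid) -> dict[str, RangeMask]:
    df = pd.read_csv(path, dtype={"lineage_id": str})
    n_cols = grid.shape[1]
    masks = {}
    for lid, grp in df.groupby("lineage_id"):
        idx = grp["cell_index"].to_numpy(dtype=int)
        cells = frozenset((int(i) // n_cols, int(i) % n_cols) for i in idx)
        mask = RangeMask(str(lid), cells)
        mask.check_extent(grid)
        masks[str(lid)] = mask
    return masks


# ---------------------------------------------------------------------------
# quantile trimming


def trim_quantiles(values, q: float = 0.05, min_cells: int = 20) -> np.ndarray:
    """Drop values strictly outside the [q, 1-q] sample quantile band.

    Quantiles use the linear-interpolation convention.  Distributions with
    fewer than ``min_cells`` values are returned unchanged (small ranges are
    exempt from trimming).
    """
    if not 0 <= q < 0.5:
        raise ValueError(f"q must lie in [0, 0.5), got {q}")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise RangeEnvError("cannot trim an empty value distribution")
    if values.size < min_cells or q == 0:
        return values
    lo, hi = np.quantile(values, [q, 1.0 - q])
    return values[(values >= lo) & (values <= hi)]


def _mask_values(grid: RasterGrid, mask: RangeMask) -> np.ndarray:
    mask.check_extent(grid)
    rows, cols = mask.rows_cols()
    vals = grid.values[rows, cols]
    return vals[~np.isnan(vals)]


def _spatial_stats(
    grid: RasterGrid, mask: RangeMask, q: float, min_cells: int
) -> tuple[float, float, float]:
    vals = _mask_values(grid, mask)
    if vals.size == 0:
        raise RangeEnvError(
            f"range {mask.lineage_id!r} has no non-missing cells in a layer"
        )
    vals = trim_quantiles(vals, q=q, min_cells=min_cells)
    return float(vals.mean()), float(vals.max()), float(vals.min())


def _check_stack(monthly: Sequence[RasterGrid]) -> None:
    if len(monthly) != 12:
        raise RangeEnvError(f"expected 12 monthly layers, got {len(monthly)}")
    first = monthly[0]
    for layer in monthly[1:]:
        if not first.same_grid(layer):
            raise RangeEnvError("monthly layers are not on a common grid")


def temperature_descriptors(
    monthly: Sequence[RasterGrid],
    mask: RangeMask,
    family: str,
    q: float = 0.05,
    min_cells: int = 20,
) -> dict[str, float]:
    """Monthly-variable descriptors (tavg, tmax, tmin, vpr families).

    The spatial range mean is computed per month (after quantile trimming of
    the in-mask values); the family statistics are then taken across the 12
    monthly means.
    """
    if family not in MONTHLY_VARIABLES:
        raise ValueError(f"unknown monthly family {family!r}")
    _check_stack(monthly)
    means = np.array(
        [_spatial_stats(layer, mask, q, min_cells)[0] for layer in monthly]
    )
    prefix = family.upper()
    stats = {"avg": means.mean(), "max": means.max(), "min": means.min()}
    return {f"{prefix}{s}": float(stats[s]) for s in MONTHLY_VARIABLES[family]}


def annual_sum_descriptors(
    monthly: Sequence[RasterGrid],
    mask: RangeMask,
    family: str,
    q: float = 0.05,
    min_cells: int = 20,
) -> dict[str, float]:
    """Annual-sum descriptors (prec, srad): cell-wise annual totals, then
    trimmed spatial statistics over the range."""
    if family not in ANNUAL_VARIABLES:
        raise ValueError(f"unknown annual family {family!r}")
    _check_stack(monthly)
    annual = RasterGrid(
        np.sum([layer.values for layer in monthly], axis=0),
        origin_lon=monthly[0].origin_lon,
        origin_lat=monthly[0].origin_lat,
        cell_size=monthly[0].cell_size,
    )
    avg, vmax, vmin = _spatial_stats(annual, mask, q, min_cells)
    prefix = family.upper()
    stats = {"avg": avg, "max": vmax, "min": vmin}
    return {f"{prefix}{s}": stats[s] for s in ANNUAL_VARIABLES[family]}


def static_descriptors(
    elevation: RasterGrid,
    mask: RangeMask,
    q: float = 0.05,
    min_cells: int = 20,
) -> dict[str, float]:
    """Trimmed spatial elevation statistics over the range."""
    avg, vmax, vmin = _spatial_stats(elevation, mask, q, min_cells)
    return {"ELEVavg": avg, "ELEVmax": vmax, "ELEVmin": vmin}


def latitude_descriptors(mask: RangeMask, grid: RasterGrid) -> dict[str, float]:
    """Cell-centre latitude statistics of the range (never trimmed)."""
    mask.check_extent(grid)
    rows, _ = mask.rows_cols()
    lats = np.asarray(grid.cell_center_lat(rows), dtype=float)
    return {
        "LATavg": float(lats.mean()),
        "LATmax": float(lats.max()),
        "LATmin": float(lats.min()),
    }


# ---------------------------------------------------------------------------
# stacks and the full table


@dataclass
class RasterStack:
    """All layers of one study: 12 monthly grids per climate variable plus
    a static elevation grid, all on one grid definition."""

    monthly: dict[str, list[RasterGrid]]
    elevation: RasterGrid

    def __post_init__(self) -> None:
        expected = set(MONTHLY_VARIABLES) | set(ANNUAL_VARIABLES)
        missing = expected - set(self.monthly)
        if missing:
            raise RangeEnvError(f"raster stack missing variables: {sorted(missing)}")
        for var, layers in self.monthly.items():
            _check_stack(layers)
            if not layers[0].same_grid(self.elevation):
                raise RangeEnvError(f"{var} layers not on the elevation grid")

    @property
    def grid(self) -> RasterGrid:
        return self.elevation

    def write_dir(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for var, layers in self.monthly.items():
            for m, layer in enumerate(layers, start=1):
                layer.to_csv(directory / f"{var}_{m:02d}.csv")
        self.elevation.to_csv(directory / "elev.csv")

    @classmethod
    def read_dir(cls, directory) -> "RasterStack":
        directory = Path(directory)
        monthly = {
            var: [
                RasterGrid.from_csv(directory / f"{var}_{m:02d}.csv")
                for m in range(1, 13)
            ]
            for var in sorted(set(MONTHLY_VARIABLES) | set(ANNUAL_VARIABLES))
        }
        return cls(monthly, RasterGrid.from_csv(directory / "elev.csv"))


def range_descriptor_table(
    stack: RasterStack,
    masks: Mapping[str, RangeMask],
    q: float = 0.05,
    min_cells: int = 20,
) -> pd.DataFrame:
    """The 21-descriptor table, one row per lineage (index: lineage_id)."""
    rows = {}
    for lid in sorted(masks):
        mask = masks[lid]
        rec: dict[str, float] = {}
        for family in MONTHLY_VARIABLES:
            rec.update(
                temperature_descriptors(stack.monthly[family], mask, family, q, min_cells)
            )
        for family in ANNUAL_VARIABLES:
            rec.update(
                annual_sum_descriptors(stack.monthly[family], mask, family, q, min_cells)
            )
        rec.update(static_descriptors(stack.elevation, mask, q, min_cells))
        rec.update(latitude_descriptors(mask, stack.grid))
        rows[lid] = rec
    table = pd.DataFrame.from_dict(rows, orient="index")[DESCRIPTOR_NAMES]
    table.index.name = "lineage_id"
    return table
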