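"""Gridded layer I/O and assembly into the harmonized cell table.

Layers live on a regular lat/lon grid with cell-center registration.
Rows are ordered north to south, columns west to east, and ``cell_id``
is the row-major index — the traversal order later used by the
forward-fill step of preprocessing, so it is fixed here once.

Supported on-disk formats: CSV (``cell_id,value``), plain (Geo)TIFF
pixel arrays via :mod:`tifffile` (grid geometry is supplied by the
caller's :class:`GridSpec`; georeferencing tags are not interpreted),
and NetCDF via :mod:`xarray`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .cells import CELL_COLUMNS, validate_cell_table

__all__ = [
    "GridSpec",
    "RasterLayer",
    "read_layer",
    "resample_nearest",
    "align_layers",
    "reclassify_tillage",
    "DEFAULT_TILLAGE_MERGE",
]


@dataclass(frozen=True)
class GridSpec:
    """Regular lat/lon grid, cell-center registration.

    Parameters
    ----------
    resolution_arcmin
        Cell size in arc-minutes (default 5, the working resolution).
    lon_min, lon_max, lat_min, lat_max
        Grid extent in degrees; the resolution must divide it evenly.
    nodata
        Sentinel for missing cells in numeric rasters.  Physical layers
        are all non-negative, so a large negative default never collides.
    """

    resolution_arcmin: float = 5.0
    lon_min: float = -180.0
    lon_max: float = 180.0
    lat_min: float = -90.0
    lat_max: float = 90.0
    nodata: float = -9999.0

    def __post_init__(self):
        res = self.resolution_arcmin / 60.0
        for lo, hi, name in [
            (self.lon_min, self.lon_max, "lon"),
            (self.lat_min, self.lat_max, "lat"),
        ]:
            span = hi - lo
            if span <= 0:
                raise ValueError(f"empty {name} extent")
            n = span / res
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"resolution {self.resolution_arcmin}' does not divide the {name} extent evenly"
                )

    @property
    def res_deg(self) -> float:
        return self.resolution_arcmin / 60.0

    @property
    def n_rows(self) -> int:
        return round((self.lat_max - self.lat_min) / self.res_deg)

    @property
    def n_cols(self) -> int:
        return round((self.lon_max - self.lon_min) / self.res_deg)

    @property
    def n_cells(self) -> int:
        return self.n_rows * self.n_cols

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(lon, lat) arrays of length ``n_cells`` in cell_id order."""
        lons = self.lon_min + (np.arange(self.n_cols) + 0.5) * self.res_deg
        lats = self.lat_max - (np.arange(self.n_rows) + 0.5) * self.res_deg
        lon_g, lat_g = np.meshgrid(lons, lats)
        return lon_g.ravel(), lat_g.ravel()

    def index_of(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Row-major cell index of the cell containing each point."""
        col = np.floor((np.asarray(lon) - self.lon_min) / self.res_deg).astype(int)
        row = np.floor((self.lat_max - np.asarray(lat)) / self.res_deg).astype(int)
        col = np.clip(col, 0, self.n_cols - 1)
        row = np.clip(row, 0, self.n_rows - 1)
        return row * self.n_cols + col


@dataclass
class RasterLayer:
    """One value per grid cell (NaN = missing), plus its grid and name."""

    grid: GridSpec
    name: str
    values: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.values.size != self.grid.n_cells:
            raise ValueError(
                f"layer {self.name!r}: {self.values.size} values for a "
                f"{self.grid.n_rows}x{self.grid.n_cols} grid"
            )

    def as_array(self) -> np.ndarray:
        return self.values.reshape(self.grid.n_rows, self.grid.n_cols)


def resample_nearest(layer: RasterLayer, grid: GridSpec) -> RasterLayer:
    """Nearest-neighbour resampling onto ``grid``.

    Each target cell takes the value of the source cell containing its
    center.  Used for both categorical and rate layers: the rates are
    intensive (per-hectare) quantities, for which value-preserving
    nearest assignment is appropriate; nothing is conserved by design.
    """
    lon, lat = grid.cell_centers()
    idx = layer.grid.index_of(lon, lat)
    return RasterLayer(grid=grid, name=layer.name, values=layer.values[idx], units=layer.units)


def read_layer(
    path,
    grid: GridSpec,
    *,
    name: str | None = None,
    src_grid: GridSpec | None = None,
    resample: str | None = None,
    variable: str | None = None,
    units: str = "",
) -> RasterLayer:
    """Read one gridded layer and align it to ``grid``.

    CSV files carry ``cell_id,value`` pairs on the target grid (absent
    ids become missing).  TIFF and NetCDF files carry a full 2-D array;
    if its shape differs from the target grid, ``resample="nearest"``
    must be requested, with the source geometry taken from ``src_grid``
    (default: same extent as ``grid`` at the file's own shape).
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".csv":
        df = pd.read_csv(path)
        if not {"cell_id", "value"} <= set(df.columns):
            raise ValueError(f"{path}: CSV layer needs cell_id,value columns")
        values = np.full(grid.n_cells, np.nan)
        ids = df["cell_id"].to_numpy(dtype=int)
        if ids.min() < 0 or ids.max() >= grid.n_cells:
            raise ValueError(f"{path}: cell_id outside grid")
        values[ids] = df["value"].to_numpy(dtype=float)
        arr, arr_grid = values, grid
    elif suffix in (".tif", ".tiff"):
        import tifffile

        raw = np.asarray(tifffile.imread(path), dtype=float)
        if raw.ndim != 2:
            raise ValueError(f"{path}: expected a single-band 2-D raster")
        arr_grid = src_grid or _implied_grid(grid, raw.shape)
        arr = raw.ravel()
    elif suffix == ".nc":
        import xarray as xr

        ds = xr.open_dataset(path, engine="scipy")
        var = variable or next(iter(ds.data_vars))
        raw = np.asarray(ds[var].values, dtype=float)
        if raw.ndim != 2:
            raise ValueError(f"{path}:{var}: expected a 2-D variable")
        arr_grid = src_grid or _implied_grid(grid, raw.shape)
        arr = raw.ravel()
    else:
        raise ValueError(f"unreadable layer format: {path}")

    arr = np.where(arr == arr_grid.nodata, np.nan, arr)
    layer = RasterLayer(grid=arr_grid, name=name or path.stem, values=arr, units=units)
    if arr_grid != grid:
        if resample != "nearest":
            raise ValueError(
                f"layer {layer.name!r} is on a {arr_grid.n_rows}x{arr_grid.n_cols} grid; "
                "pass resample='nearest' to align it"
            )
        layer = resample_nearest(layer, grid)
    return layer


def _implied_grid(grid: GridSpec, shape: tuple[int, int]) -> GridSpec:
    """Grid with the target extent but the file's own shape."""
    n_rows, n_cols = shape
    res_lat = (grid.lat_max - grid.lat_min) / n_rows * 60.0
    res_lon = (grid.lon_max - grid.lon_min) / n_cols * 60.0
    if abs(res_lat - res_lon) > 1e-9:
        raise ValueError("non-square cells; provide src_grid explicitly")
    return GridSpec(
        resolution_arcmin=res_lat,
        lon_min=grid.lon_min,
        lon_max=grid.lon_max,
        lat_min=grid.lat_min,
        lat_max=grid.lat_max,
        nodata=grid.nodata,
    )


# Six-system tillage codes of the gridded tillage product, reclassified
# to a binary machinery indicator.  Conservation agriculture counts as
# mechanized (reduced tillage, but practiced where farms are motorized);
# the two "traditional" systems rest on human and animal draft power.
DEFAULT_TILLAGE_MERGE: dict[int, int] = {
    1: 1,  # conventional annual
    2: 1,  # conventional rotational
    3: 1,  # rotational
    4: 0,  # traditional annual (draft power)
    5: 0,  # traditional rotational (draft power)
    6: 1,  # conservation agriculture
}


def reclassify_tillage(
    tillage: RasterLayer, merge_map: Mapping[int, int] | None = None
) -> RasterLayer:
    """Collapse the tillage-system layer to binary mechanization.

    Unknown codes are reported (as a warning) and mapped to missing;
    missing cells stay missing.
    """
    merge_map = dict(DEFAULT_TILLAGE_MERGE if merge_map is None else merge_map)
    values = tillage.values
    out = np.full_like(values, np.nan)
    known = np.zeros(values.shape, dtype=bool)
    for code, binary in merge_map.items():
        hit = values == code
        out[hit] = binary
        known |= hit
    unknown = ~known & ~np.isnan(values)
    if unknown.any():
        import warnings

        codes = sorted(set(values[unknown].astype(int).tolist()))
        warnings.warn(
            f"tillage layer: {int(unknown.sum())} cells with unknown codes {codes} set to missing",
            stacklevel=2,
        )
    return RasterLayer(grid=tillage.grid, name="mechanized", values=out)


#: layer names align_layers understands besides per-crop yield/area
_SHARED_LAYERS = [
    "n_fert",
    "n_manure",
    "pesticides",
    "irrigation_tot",
    "irrigation_reliant",
    "mechanized",
    "thz_class",
    "mst_class",
    "soil_class",
    "region",
]


def align_layers(
    layers: Mapping[str, RasterLayer],
    grid: GridSpec,
    *,
    region_lookup: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Assemble aligned layers into one long-format cell table.

    ``layers`` maps names to layers on ``grid``: per-crop pairs keyed
    ``"yield:<crop>"`` / ``"area:<crop>"`` plus any of the shared input
    layers (``n_fert`` ... ``region``).  The output holds one row per
    (cell with positive crop area, crop); where a shared layer is
    missing for a cell, the field is missing — misalignment between
    sources produces gaps, never errors.  ``region_lookup`` translates
    integer region codes to continent labels.
    """
    names = list(layers)
    if len(set(names)) != len(names):
        raise ValueError("duplicate layer names")
    crops = sorted({n.split(":", 1)[1] for n in names if n.startswith("yield:")})
    for crop in crops:
        if f"area:{crop}" not in layers:
            raise ValueError(f"crop {crop!r} has a yield layer but no area layer")
    for lname, layer in layers.items():
        if layer.grid != grid:
            raise ValueError(f"layer {lname!r} not aligned to the target grid")

    lon, lat = grid.cell_centers()
    frames = []
    for crop in crops:
        area = layers[f"area:{crop}"].values
        mask = ~np.isnan(area) & (area > 0)
        ids = np.nonzero(mask)[0]
        row = {
            "cell_id": ids,
            "lon": lon[ids],
            "lat": lat[ids],
            "crop": crop,
            "yield_kg_ha": layers[f"yield:{crop}"].values[ids],
            "area_ha": area[ids],
        }
        for lname in _SHARED_LAYERS:
            if lname == "region":
                continue
            if lname in layers:
                row[lname] = layers[lname].values[ids]
            else:
                row[lname] = np.nan
        if "region" in layers:
            codes = layers["region"].values[ids]
            if region_lookup is not None:
                row["region"] = [
                    region_lookup.get(int(c), np.nan) if not np.isnan(c) else np.nan
                    for c in codes
                ]
            else:
                row["region"] = codes
        else:
            row["region"] = np.nan
        frames.append(pd.DataFrame(row))

    if not frames:
        return pd.DataFrame(columns=CELL_COLUMNS)
    table = pd.concat(frames, ignore_index=True)
    for col in ("thz_class", "mst_class", "soil_class"):
        # class codes travel as "T3"-style labels once tabulated
        if table[col].notna().any() and not table[col].dtype == object:
            table[col] = table[col].astype(object)
    table["n_total"] = np.nan  # filled by preprocessing after outlier trims
    table = table[[c for c in CELL_COLUMNS if c in table.columns]]
    table = table.sort_values(["crop", "cell_id"], kind="stable").reset_index(drop=True)
    return validate_cell_table(table)
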