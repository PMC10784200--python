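"""The harmonized per-cell, per-crop table every pipeline stage consumes.

A *cell table* is a long-format :class:`pandas.DataFrame` with one row per
(grid cell, crop) combination.  It is the single interchange structure of
the package: the raster reader assembles one, the synthetic generator
emits one, and preprocessing, model fitting, scenario construction and
aggregation all consume and produce them.

Columns (units in brackets):

======================  =====================================================
``cell_id``             row-major grid index (north->south, west->east)
``lon``, ``lat``        cell-center coordinates [degrees]
``region``              continent / region label
``crop``                crop identifier (e.g. ``"wheat"``)
``yield_kg_ha``         observed yield [kg ha^-1]
``area_ha``             crop-specific harvested area in the cell [ha]
``n_fert``              mineral N fertilizer application rate [kg ha^-1]
``n_manure``            manure N application rate [kg ha^-1]
``n_total``             combined N input [kg ha^-1] (filled by preprocessing)
``pesticides``          cumulated pesticide application rate [kg ha^-1]
``irrigation_tot``      irrigated fraction of cropland [0..1]
``irrigation_reliant``  fraction of irrigated area reliant on powered pumps
``mechanized``          0/1 machinery use
``thz_class``           thermal regime class code
``mst_class``           moisture regime class code
``soil_class``          soil/terrain class code
======================  =====================================================
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: canonical column order of a cell table
CELL_COLUMNS = [
    "cell_id",
    "lon",
    "lat",
    "region",
    "crop",
    "yield_kg_ha",
    "area_ha",
    "n_fert",
    "n_manure",
    "n_total",
    "pesticides",
    "irrigation_tot",
    "irrigation_reliant",
    "mechanized",
    "thz_class",
    "mst_class",
    "soil_class",
]

QUANTITATIVE_COLUMNS = [
    "yield_kg_ha",
    "area_ha",
    "n_fert",
    "n_manure",
    "n_total",
    "pesticides",
]

FRACTION_COLUMNS = ["irrigation_tot", "irrigation_reliant"]

CLASS_COLUMNS = ["thz_class", "mst_class", "soil_class"]

# CSV interchange uses short physical names for the two SPAM quantities
_CSV_RENAME = {"yield_kg_ha": "yield", "area_ha": "area"}
_CSV_RENAME_BACK = {v: k for k, v in _CSV_RENAME.items()}


def validate_cell_table(table: pd.DataFrame, *, require_all: bool = False) -> pd.DataFrame:
    """Check cell-table invariants; return the table unchanged.

    Quantitative fields must be non-negative where present, irrigation
    fractions in [0, 1], ``mechanized`` in {0, 1}.  With ``require_all``
    every canonical column must be present (missing values still allowed).
    """
    missing = [c for c in ("cell_id", "crop") if c not in table.columns]
    if missing:
        raise ValueError(f"cell table lacks required columns: {missing}")
    if require_all:
        absent = [c for c in CELL_COLUMNS if c not in table.columns]
        if absent:
            raise ValueError(f"cell table lacks columns: {absent}")
    for col in QUANTITATIVE_COLUMNS:
        if col in table.columns:
            vals = pd.to_numeric(table[col], errors="coerce")
            if (vals.dropna() < 0).any():
                raise ValueError(f"column {col!r} contains negative values")
    for col in FRACTION_COLUMNS:
        if col in table.columns:
            vals = table[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"column {col!r} outside [0, 1]")
    if "mechanized" in table.columns:
        vals = table["mechanized"].dropna()
        if not vals.isin([0, 1, 0.0, 1.0]).all():
            raise ValueError("column 'mechanized' must be 0/1")
    dup = table.duplicated(subset=["cell_id", "crop"])
    if dup.any():
        raise ValueError(f"{int(dup.sum())} duplicate (cell_id, crop) rows")
    return table


def write_cell_table(table: pd.DataFrame, path) -> None:
    """Write a cell table to CSV using the interchange header."""
    out = table.rename(columns=_CSV_RENAME)
    out.to_csv(path, index=False)


def read_cell_table(path) -> pd.DataFrame:
    """Read a cell table written by :func:`write_cell_table`."""
    df = pd.read_csv(
        path,
        dtype={c: "string" for c in ("region", "crop", *CLASS_COLUMNS)},
        float_precision="round_trip",
    )
    df = df.rename(columns=_CSV_RENAME_BACK)
    for col in CLASS_COLUMNS + ["region", "crop"]:
        if col in df.columns:
            df[col] = df[col].astype(object).where(df[col].notna(), np.nan)
    return validate_cell_table(df)
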