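"""Per-crop data cleaning and multicollinearity screening.

The cleaning ledger applies, in a fixed order, the operations a gridded
crop-input table needs before a yield response can be fitted to it:

1. drop rows whose harvested area is below 100 ha (strictly), recording
   how much production the dropped rows carried;
2. drop rows missing pesticides or mechanization (no defensible basis
   for imputing them), forward-fill short gaps in N fertilizer and the
   agro-climatic classes in cell-id order, dropping leading gaps;
3. trim implausible values strictly above the 99.9th percentile of
   N fertilizer, pesticides and yield and the 99th percentile of manure,
   per crop;
4. merge N fertilizer and manure into ``n_total`` (after trimming, so
   outliers are caught in the source columns first) and trim the merged
   column at its own 99.9th percentile;
5. collapse sparse agro-climatic class levels (coldest thermal regimes
   into T7, moisture extremes into M2/M6).

Every step appends a row to a :class:`CleaningReport` whose counts
telescope: rows_out of one step is rows_in of the next.

:func:`compute_gvif` screens the dummy-coded design for
multicollinearity with the generalized variance inflation factor, the
determinant-ratio generalisation of the VIF that stays meaningful for
multi-level categorical predictors; predictors are compared on the
GVIF^(1/(2*Df)) scale, whose square reduces to the ordinary VIF for
single-column predictors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cells import validate_cell_table

__all__ = [
    "CleaningReport",
    "ClassMergeMap",
    "DEFAULT_CLASS_MERGE",
    "DEFAULT_TRIM_SPEC",
    "filter_min_area",
    "handle_missing",
    "trim_outliers",
    "combine_nitrogen",
    "merge_classes",
    "preprocess",
    "compute_gvif",
]


@dataclass
class CleaningReport:
    """Telescoping ledger of cleaning steps."""

    steps: list[dict] = field(default_factory=list)

    def add(self, name: str, rows_in: int, rows_removed: int, **details) -> None:
        if rows_removed < 0 or rows_removed > rows_in:
            raise ValueError(f"step {name!r}: invalid removal count")
        self.steps.append(
            {
                "step": name,
                "rows_in": rows_in,
                "rows_removed": rows_removed,
                "rows_out": rows_in - rows_removed,
                "fraction_removed": rows_removed / rows_in if rows_in else 0.0,
                "details": details,
            }
        )

    def extend(self, other: "CleaningReport") -> None:
        self.steps.extend(other.steps)

    @property
    def rows_in(self) -> int:
        return self.steps[0]["rows_in"] if self.steps else 0

    @property
    def rows_out(self) -> int:
        return self.steps[-1]["rows_out"] if self.steps else 0

    @property
    def total_removed(self) -> int:
        return sum(s["rows_removed"] for s in self.steps)

    def check_telescoping(self) -> bool:
        for prev, nxt in zip(self.steps, self.steps[1:]):
            if prev["rows_out"] != nxt["rows_in"]:
                return False
        return self.rows_in - self.total_removed == self.rows_out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            row = {k: v for k, v in s.items() if k != "details"}
            row["details"] = "; ".join(f"{k}={v}" for k, v in s["details"].items())
            rows.append(row)
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        lines = ["cleaning ledger"]
        for s in self.steps:
            lines.append(
                f"  {s['step']}: {s['rows_in']} -> {s['rows_out']} "
                f"(-{s['rows_removed']}, {100 * s['fraction_removed']:.1f}%)"
            )
            for k, v in s["details"].items():
                lines.append(f"      {k}: {v}")
        return "\n".join(lines)


def _production(table: pd.DataFrame) -> float:
    prod = table["yield_kg_ha"] * table["area_ha"]
    return float(prod.sum(skipna=True))


def filter_min_area(
    table: pd.DataFrame, min_ha: float = 100.0
) -> tuple[pd.DataFrame, CleaningReport]:
    """Drop rows with harvested area strictly below ``min_ha``.

    Cells at exactly the threshold are retained.  The report records the
    removed rows' share of total production (sum of yield x area), the
    quantity that shows sub-threshold cells are irrelevant for food
    security even when they are numerous.
    """
    report = CleaningReport()
    n_in = len(table)
    if n_in == 0:
        report.add("area_filter", 0, 0, min_ha=min_ha, production_share_removed=0.0)
        return table, report
    keep = table["area_ha"] >= min_ha
    removed = table.loc[~keep]
    total = _production(table)
    share = _production(removed) / total if total > 0 else 0.0
    report.add(
        "area_filter",
        n_in,
        int((~keep).sum()),
        min_ha=min_ha,
        production_share_removed=share,
    )
    return table.loc[keep].reset_index(drop=True), report


_FFILL_COLS = ["n_fert", "thz_class", "mst_class", "soil_class"]


def handle_missing(table: pd.DataFrame) -> tuple[pd.DataFrame, CleaningReport]:
    """Resolve missing values per crop in cell-id order.

    Rows missing pesticides or mechanization are dropped — no
    established dependence on the other variables justifies gap
    filling.  Missing N fertilizer and class codes are forward-filled
    (last observed value carried forward) along the row-major grid
    order; leading gaps with nothing to carry are dropped.
    """
    report = CleaningReport()
    n_in = len(table)
    table = table.sort_values(["crop", "cell_id"], kind="stable").reset_index(drop=True)

    for col in _FFILL_COLS:
        by_crop = table.groupby("crop", sort=False)[col]
        all_missing = by_crop.apply(lambda s: s.isna().all())
        if len(table) and all_missing.any():
            crops = list(all_missing[all_missing].index)
            raise ValueError(f"column {col!r} entirely missing for crop(s) {crops}")

    keep = table["pesticides"].notna() & table["mechanized"].notna()
    report.add("drop_missing_pesticides_mechanized", n_in, int((~keep).sum()))
    table = table.loc[keep].reset_index(drop=True)

    filled = {}
    for col in _FFILL_COLS:
        before = table[col].isna().sum()
        table[col] = table.groupby("crop", sort=False)[col].ffill()
        filled[col] = int(before - table[col].isna().sum())
    keep = table[_FFILL_COLS].notna().all(axis=1)
    report.add(
        "forward_fill",
        len(table),
        int((~keep).sum()),
        **{f"filled_{k}": v for k, v in filled.items()},
    )
    return table.loc[keep].reset_index(drop=True), report


DEFAULT_TRIM_SPEC: dict[str, float] = {
    "n_fert": 99.9,
    "pesticides": 99.9,
    "yield_kg_ha": 99.9,
    "n_manure": 99.0,
}


def trim_outliers(
    table: pd.DataFrame, spec: dict[str, float] | None = None
) -> tuple[pd.DataFrame, CleaningReport]:
    """Remove rows strictly above per-crop, per-column percentile
    thresholds (linear interpolation between order statistics).

    Values exactly at the threshold are retained.  The thresholds are
    recorded in the report so the trim is auditable.
    """
    spec = DEFAULT_TRIM_SPEC if spec is None else spec
    report = CleaningReport()
    for col, q in spec.items():
        n_in = len(table)
        thresholds = {}
        keep = pd.Series(True, index=table.index)
        for crop, group in table.groupby("crop", sort=False):
            vals = group[col].dropna()
            if vals.empty:
                continue
            thr = float(np.percentile(vals, q))  # linear interpolation
            thresholds[crop] = thr
            keep.loc[group.index] &= ~(group[col] > thr)
        report.add(
            f"trim_{col}",
            n_in,
            int((~keep).sum()),
            percentile=q,
            **{f"threshold_{c}": t for c, t in thresholds.items()},
        )
        table = table.loc[keep].reset_index(drop=True)
    return table, report


def combine_nitrogen(
    table: pd.DataFrame, percentile: float = 99.9
) -> tuple[pd.DataFrame, CleaningReport]:
    """Sum fertilizer and manure N into ``n_total``, then trim the
    merged column at its own percentile.

    The merge happens after the source columns were trimmed, so data
    errors are detectable in each source before they are blended.
    """
    for col in ("n_fert", "n_manure"):
        if col not in table.columns or table[col].isna().any():
            raise ValueError(f"combine_nitrogen requires complete {col!r}")
    table = table.copy()
    table["n_total"] = table["n_fert"] + table["n_manure"]
    return trim_outliers(table, {"n_total": percentile})


@dataclass(frozen=True)
class ClassMergeMap:
    """Total maps from raw agro-climatic codes to merged model levels."""

    thermal: dict[str, str]
    moisture: dict[str, str]
    soil: dict[str, str] | None = None  # identity when None


DEFAULT_CLASS_MERGE = ClassMergeMap(
    # three coldest regimes pooled: temperate-cool + boreal + arctic
    thermal={
        "T1": "T1", "T2": "T2", "T3": "T3", "T4": "T4", "T5": "T5",
        "T6": "T6", "T7": "T7", "T8": "T7", "T9": "T7",
    },
    # moisture extremes pooled: growing period <120 d and 270+ d
    moisture={
        "M1": "M2", "M2": "M2", "M3": "M3", "M4": "M4", "M5": "M5",
        "M6": "M6", "M7": "M6",
    },
)


def merge_classes(
    table: pd.DataFrame, merge_map: ClassMergeMap | None = None
) -> tuple[pd.DataFrame, CleaningReport]:
    """Relabel class codes to the merged level sets; no rows removed."""
    merge_map = DEFAULT_CLASS_MERGE if merge_map is None else merge_map
    table = table.copy()
    report = CleaningReport()
    counts = {}
    for col, mapping in [
        ("thz_class", merge_map.thermal),
        ("mst_class", merge_map.moisture),
        ("soil_class", merge_map.soil),
    ]:
        if mapping is None:
            continue
        raw = table[col]
        unmapped = sorted(set(raw.dropna()) - set(mapping))
        if unmapped:
            raise ValueError(f"{col}: unmapped codes {unmapped}")
        table[col] = raw.map(mapping)
        counts.update(
            {f"{col}_{lvl}": int(n) for lvl, n in table[col].value_counts().items()}
        )
    report.add("merge_classes", len(table), 0, **counts)
    return table, report


def preprocess(
    table: pd.DataFrame,
    *,
    min_area_ha: float = 100.0,
    trim_spec: dict[str, float] | None = None,
    n_total_percentile: float = 99.9,
    merge_map: ClassMergeMap | None = None,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Run the full cleaning ledger in its fixed order."""
    validate_cell_table(table)
    report = CleaningReport()
    table, rep = filter_min_area(table, min_area_ha)
    report.extend(rep)
    table, rep = handle_missing(table)
    report.extend(rep)
    table, rep = trim_outliers(table, trim_spec)
    report.extend(rep)
    table, rep = combine_nitrogen(table, n_total_percentile)
    report.extend(rep)
    table, rep = merge_classes(table, merge_map)
    report.extend(rep)
    assert report.check_telescoping()
    return table, report


# ---------------------------------------------------------------------------
# generalized variance inflation factor


def _dummy_design(
    table: pd.DataFrame, predictors: list[str]
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Dummy-code the predictors (first level dropped per categorical)."""
    blocks: dict[str, list[str]] = {}
    cols = {}
    for pred in predictors:
        series = table[pred]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(series, prefix=pred, drop_first=True, dtype=float)
            if dummies.shape[1] == 0:
                raise ValueError(f"predictor {pred!r} is constant")
            blocks[pred] = list(dummies.columns)
            for c in dummies.columns:
                cols[c] = dummies[c]
        else:
            vals = series.astype(float)
            if vals.nunique(dropna=True) <= 1:
                raise ValueError(f"predictor {pred!r} is constant")
            blocks[pred] = [pred]
            cols[pred] = vals
    return pd.DataFrame(cols), blocks


def compute_gvif(
    table: pd.DataFrame, predictors: list[str], *, singular_tol: float = 1e-12
) -> pd.DataFrame:
    """Generalized variance inflation factors of a predictor set.

    For predictor j with dummy columns indexed ``J`` in the correlation
    matrix ``R`` of the full dummy-coded design,

        GVIF_j = det(R[J, J]) * det(R[-J, -J]) / det(R)

    (Fox & Monette's determinant-ratio construction).  The returned
    frame carries, per predictor: ``df`` (number of dummy columns),
    ``gvif``, ``gvif_adj`` = GVIF^(1/(2*df)), its square
    ``gvif_adj_sq`` — the ordinary-VIF scale on which the usual
    thresholds apply — and boolean flags at 5 and 10.  A singular
    design yields infinite GVIFs, not an exception.
    """
    if len(predictors) < 2:
        raise ValueError("GVIF needs at least two predictors")
    design, blocks = _dummy_design(table, predictors)
    X = design.to_numpy(dtype=float)
    X = X[~np.isnan(X).any(axis=1)]
    if X.shape[0] < X.shape[1] + 1:
        raise ValueError("not enough complete rows for GVIF")
    R = np.corrcoef(X, rowvar=False)
    det_R = float(np.linalg.det(R))
    col_index = {c: i for i, c in enumerate(design.columns)}

    rows = []
    for pred in predictors:
        idx = [col_index[c] for c in blocks[pred]]
        other = [i for i in range(R.shape[0]) if i not in idx]
        df = len(idx)
        if det_R <= singular_tol:
            gvif = math.inf
        else:
            det_jj = float(np.linalg.det(R[np.ix_(idx, idx)]))
            det_oo = float(np.linalg.det(R[np.ix_(other, other)])) if other else 1.0
            gvif = det_jj * det_oo / det_R
        adj = gvif ** (1.0 / (2.0 * df)) if math.isfinite(gvif) else math.inf
        adj_sq = adj**2 if math.isfinite(adj) else math.inf
        rows.append(
            {
                "predictor": pred,
                "df": df,
                "gvif": gvif,
                "gvif_adj": adj,
                "gvif_adj_sq": adj_sq,
                "flag_5": not adj_sq < 5,
                "flag_10": not adj_sq < 10,
            }
        )
    return pd.DataFrame(rows).set_index("predictor")
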