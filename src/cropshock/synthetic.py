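"""Synthetic gridded agricultural landscapes with known model ground truth.

The generator emits cell tables (see :mod:`cropshock.cells`) whose joint
structure mirrors what the pipeline expects from real 5-arcmin crop
products: right-skewed gamma-distributed yields that respond
log-linearly to agronomic inputs, spatially blocky agro-climatic class
mosaics, harvested areas spanning garden plots to whole-cell fields,
missing cells in the pesticide and mechanization layers, and occasional
implausible outliers in the input rates.

Because the true coefficients are known, every downstream stage —
cleaning, GLM fitting, scenario construction, aggregation — can be
tested for parameter recovery and for its documented invariants without
any external data.

Randomness is organised as one independent stream per column, all
spawned from the master seed, so that e.g. toggling missingness does not
perturb the yield draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cells import CELL_COLUMNS, validate_cell_table
from .grid import GridSpec

__all__ = [
    "CropCoefficients",
    "SyntheticConfig",
    "default_config",
    "generate_landscape",
    "make_worked_fixture",
    "WORKED_FIXTURES",
]

# Raw agro-climatic class codes as they arrive from a zoning product.
# The three coldest thermal regimes (T7 temperate-cool, T8 boreal,
# T9 arctic) and the moisture extremes (M1, M7) are rare by construction
# and get collapsed by preprocessing into T7 / M2 / M6.
RAW_THZ_LEVELS = ["T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9"]
RAW_MST_LEVELS = ["M1", "M2", "M3", "M4", "M5", "M6", "M7"]
RAW_SOIL_LEVELS = ["S1", "S2", "S3", "S4", "S5", "L3"]

_DEFAULT_THZ_PROBS = [0.18, 0.10, 0.16, 0.12, 0.10, 0.24, 0.06, 0.03, 0.01]
_DEFAULT_MST_PROBS = [0.04, 0.14, 0.22, 0.22, 0.18, 0.16, 0.04]
_DEFAULT_SOIL_PROBS = [0.08, 0.10, 0.34, 0.24, 0.14, 0.10]

#: merged-level keys the true model is defined on (reference level first)
MERGED_THZ = ["T1", "T2", "T3", "T4", "T5", "T6", "T7"]
MERGED_MST = ["M2", "M3", "M4", "M5", "M6"]
MERGED_SOIL = ["S1", "S2", "S3", "S4", "S5", "L3"]

_RAW_TO_MERGED_THZ = {**{t: t for t in MERGED_THZ}, "T8": "T7", "T9": "T7"}
_RAW_TO_MERGED_MST = {**{m: m for m in MERGED_MST}, "M1": "M2", "M7": "M6"}


@dataclass(frozen=True)
class CropCoefficients:
    """True log-link coefficients of one crop's yield response.

    Continuous effects are per unit of the predictor (kg ha^-1 for the
    rates, the fraction itself for irrigation); categorical effects are
    offsets of each merged class level against the references T1/M2/S1.
    """

    intercept: float
    n_total: float
    pesticides: float
    irrigation_tot: float
    mechanized: float
    thz: dict[str, float] = field(default_factory=dict)
    mst: dict[str, float] = field(default_factory=dict)
    soil: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SyntheticConfig:
    seed: int = 0
    n_rows: int = 40
    n_cols: int = 50
    crops: tuple[str, ...] = ("corn", "rice", "soybean", "wheat")
    coefficients: dict[str, CropCoefficients] = field(default_factory=dict)
    gamma_shape: float = 2.0
    # log-normal (mu, sigma) of the input-rate distributions
    n_fert_lognorm: tuple[float, float] = (np.log(50.0), 0.8)
    n_manure_lognorm: tuple[float, float] = (np.log(15.0), 0.9)
    pesticides_lognorm: tuple[float, float] = (np.log(1.0), 0.8)
    area_lognorm: tuple[float, float] = (np.log(150.0), 2.0)
    area_max_ha: float = 20000.0
    irrigation_beta: tuple[float, float] = (0.5, 1.5)
    reliant_beta: tuple[float, float] = (2.0, 2.0)
    mechanized_prob: float = 0.6
    # fraction of cells set to missing, per column
    missing_pesticides: float = 0.15
    missing_mechanized: float = 0.10
    missing_n_fert: float = 0.015
    missing_classes: float = 0.02
    # implausible-value injection: multiplicative x10..x100 spikes
    outlier_rate: float = 0.002
    outlier_magnitude: tuple[float, float] = (10.0, 100.0)
    # per-variable block edge lengths; distinct sizes keep the three
    # mosaics from aliasing into a rank-deficient dummy design
    class_block_cells: tuple[int, int, int] = (8, 6, 5)
    thz_probs: tuple[float, ...] = tuple(_DEFAULT_THZ_PROBS)
    mst_probs: tuple[float, ...] = tuple(_DEFAULT_MST_PROBS)
    soil_probs: tuple[float, ...] = tuple(_DEFAULT_SOIL_PROBS)
    regions: tuple[str, ...] = ("Africa", "Americas", "Asia", "Europe", "Oceania")

    def validate(self) -> "SyntheticConfig":
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be positive")
        for name, rate in [
            ("missing_pesticides", self.missing_pesticides),
            ("missing_mechanized", self.missing_mechanized),
            ("missing_n_fert", self.missing_n_fert),
            ("missing_classes", self.missing_classes),
            ("outlier_rate", self.outlier_rate),
            ("mechanized_prob", self.mechanized_prob),
        ]:
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} outside [0, 1]")
        for name, probs, levels in [
            ("thz_probs", self.thz_probs, RAW_THZ_LEVELS),
            ("mst_probs", self.mst_probs, RAW_MST_LEVELS),
            ("soil_probs", self.soil_probs, RAW_SOIL_LEVELS),
        ]:
            if len(probs) != len(levels):
                raise ValueError(f"{name}: need {len(levels)} probabilities")
            if min(probs) <= 0:
                raise ValueError(f"{name}: every level needs positive probability")
            if abs(sum(probs) - 1) > 1e-9:
                raise ValueError(f"{name}: probabilities must sum to 1")
        if not self.crops:
            raise ValueError("at least one crop required")
        return self


def _default_coefficients() -> dict[str, CropCoefficients]:
    """Plausible per-crop responses: intercepts near ln(1-2 t/ha) and
    input effects whose min-to-max yield swings sit in the tens of
    percent, as field-scale intensification studies report."""

    def classes(scale: float) -> tuple[dict, dict, dict]:
        thz = {"T2": -0.05 * scale, "T3": 0.10 * scale, "T4": 0.06 * scale,
               "T5": -0.04 * scale, "T6": 0.12 * scale, "T7": -0.25 * scale}
        mst = {"M3": 0.10 * scale, "M4": 0.16 * scale, "M5": 0.20 * scale,
               "M6": 0.22 * scale}
        soil = {"S2": -0.08 * scale, "S3": 0.18 * scale, "S4": 0.05 * scale,
                "S5": -0.15 * scale, "L3": 0.20 * scale}
        return thz, mst, soil

    out = {}
    for crop, (b0, bn, bp, bi, bm, sc) in {
        "corn": (7.2, 0.0045, 0.06, 0.55, 0.30, 1.0),
        "rice": (7.6, 0.0035, -0.04, 0.45, 0.25, 0.8),
        "soybean": (6.9, 0.0005, 0.05, 0.40, 0.45, 0.9),
        "wheat": (7.1, 0.0050, 0.08, 0.35, 0.35, 1.1),
    }.items():
        thz, mst, soil = classes(sc)
        out[crop] = CropCoefficients(
            intercept=b0, n_total=bn, pesticides=bp, irrigation_tot=bi,
            mechanized=bm, thz=thz, mst=mst, soil=soil,
        )
    return out


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    cfg = SyntheticConfig(seed=seed, coefficients=_default_coefficients())
    if overrides:
        cfg = replace(cfg, **overrides)
    if set(cfg.coefficients) < set(cfg.crops):
        base = _default_coefficients()
        coefs = dict(cfg.coefficients)
        for crop in cfg.crops:
            coefs.setdefault(crop, coefs.get(crop, base.get(crop, base["wheat"])))
        cfg = replace(cfg, coefficients=coefs)
    return cfg.validate()


_STREAMS = [
    "area", "n_fert", "n_manure", "pesticides", "irrigation_tot",
    "irrigation_reliant", "mechanized", "thz_class", "mst_class",
    "soil_class", "yield", "missing", "outliers",
]


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(child) for name, child in zip(_STREAMS, children)}


def _blocky_classes(rng, n_rows, n_cols, levels, probs, block) -> np.ndarray:
    """Spatially blocky categorical mosaic: one draw per coarse block."""
    br = -(-n_rows // block)
    bc = -(-n_cols // block)
    blocks = rng.choice(len(levels), size=(br, bc), p=probs)
    full = np.repeat(np.repeat(blocks, block, axis=0), block, axis=1)
    codes = full[:n_rows, :n_cols].ravel()
    return np.asarray(levels, dtype=object)[codes]


def linear_predictor(coef: CropCoefficients, df: pd.DataFrame) -> np.ndarray:
    """eta = b0 + sum(b_j x_j) on merged class levels (log-link scale)."""
    thz = df["thz_class"].map(lambda c: _RAW_TO_MERGED_THZ.get(c, c))
    mst = df["mst_class"].map(lambda c: _RAW_TO_MERGED_MST.get(c, c))
    eta = (
        coef.intercept
        + coef.n_total * df["_n_total_true"].to_numpy()
        + coef.pesticides * df["pesticides"].to_numpy()
        + coef.irrigation_tot * df["irrigation_tot"].to_numpy()
        + coef.mechanized * df["mechanized"].to_numpy()
        + thz.map(lambda c: coef.thz.get(c, 0.0)).to_numpy()
        + mst.map(lambda c: coef.mst.get(c, 0.0)).to_numpy()
        + df["soil_class"].map(lambda c: coef.soil.get(c, 0.0)).to_numpy()
    )
    return np.asarray(eta, dtype=float)


def generate_landscape(config: SyntheticConfig) -> pd.DataFrame:
    """Draw one synthetic landscape as a long-format cell table.

    Yields are Gamma(shape, mu/shape) with ln mu given by the true
    per-crop coefficients evaluated on the *clean* inputs; outliers and
    missingness are injected afterwards into the recorded input columns,
    so they behave as data errors rather than real signal. Deterministic
    given ``config.seed``.
    """
    config.validate()
    grid = GridSpec(
        resolution_arcmin=5.0,
        lon_min=0.0,
        lon_max=config.n_cols * 5 / 60.0,
        lat_min=0.0,
        lat_max=config.n_rows * 5 / 60.0,
    )
    n = grid.n_cells
    rngs = _rngs(config.seed)
    lon, lat = grid.cell_centers()

    b_thz, b_mst, b_soil = config.class_block_cells
    thz = _blocky_classes(rngs["thz_class"], config.n_rows, config.n_cols,
                          RAW_THZ_LEVELS, list(config.thz_probs), b_thz)
    mst = _blocky_classes(rngs["mst_class"], config.n_rows, config.n_cols,
                          RAW_MST_LEVELS, list(config.mst_probs), b_mst)
    soil = _blocky_classes(rngs["soil_class"], config.n_rows, config.n_cols,
                           RAW_SOIL_LEVELS, list(config.soil_probs), b_soil)

    # continent bands by longitude column
    band = np.minimum(
        (np.arange(grid.n_cols) * len(config.regions)) // grid.n_cols,
        len(config.regions) - 1,
    )
    region_by_cell = np.asarray(config.regions, dtype=object)[
        np.tile(band, config.n_rows)
    ]

    frames = []
    for crop in config.crops:
        coef = config.coefficients[crop]

        def lognorm(stream, params):
            mu, sigma = params
            return rngs[stream].lognormal(mu, sigma, size=n)

        area = np.minimum(lognorm("area", config.area_lognorm), config.area_max_ha)
        n_fert = lognorm("n_fert", config.n_fert_lognorm)
        n_manure = lognorm("n_manure", config.n_manure_lognorm)
        pest = lognorm("pesticides", config.pesticides_lognorm)
        irr = rngs["irrigation_tot"].beta(*config.irrigation_beta, size=n)
        reliant = rngs["irrigation_reliant"].beta(*config.reliant_beta, size=n)
        mech = (rngs["mechanized"].random(n) < config.mechanized_prob).astype(float)

        df = pd.DataFrame(
            {
                "cell_id": np.arange(n),
                "lon": lon,
                "lat": lat,
                "region": region_by_cell,
                "crop": crop,
                "area_ha": area,
                "n_fert": n_fert,
                "n_manure": n_manure,
                "pesticides": pest,
                "irrigation_tot": irr,
                "irrigation_reliant": reliant,
                "mechanized": mech,
                "thz_class": thz,
                "mst_class": mst,
                "soil_class": soil,
            }
        )
        df["_n_total_true"] = df["n_fert"] + df["n_manure"]
        mu = np.exp(linear_predictor(coef, df))
        df["yield_kg_ha"] = rngs["yield"].gamma(
            shape=config.gamma_shape, scale=mu / config.gamma_shape
        )
        df = df.drop(columns="_n_total_true")

        # data corruption: multiplicative spikes, then missingness
        rate_cols = ["n_fert", "n_manure", "pesticides"]
        if config.outlier_rate > 0:
            for col in rate_cols:
                hit = rngs["outliers"].random(n) < config.outlier_rate
                factor = rngs["outliers"].uniform(*config.outlier_magnitude, size=n)
                df.loc[hit, col] = df.loc[hit, col] * factor[hit]
        for col, rate in [
            ("pesticides", config.missing_pesticides),
            ("mechanized", config.missing_mechanized),
            ("n_fert", config.missing_n_fert),
        ]:
            if rate > 0:
                df.loc[rngs["missing"].random(n) < rate, col] = np.nan
        if config.missing_classes > 0:
            for col in ("thz_class", "mst_class", "soil_class"):
                df.loc[rngs["missing"].random(n) < config.missing_classes, col] = np.nan

        df["n_total"] = np.nan
        frames.append(df)

    table = pd.concat(frames, ignore_index=True)[CELL_COLUMNS]
    table = table.sort_values(["crop", "cell_id"], kind="stable").reset_index(drop=True)
    return validate_cell_table(table)


# ---------------------------------------------------------------------------
# tiny worked fixtures for single-cell arithmetic


def _fixture_row(**over) -> pd.DataFrame:
    base = {
        "cell_id": 0, "lon": 0.5, "lat": 0.5, "region": "Europe",
        "crop": "wheat", "yield_kg_ha": 3000.0, "area_ha": 100.0,
        "n_fert": 50.0, "n_manure": 10.0, "n_total": np.nan,
        "pesticides": 1.0, "irrigation_tot": 0.3, "irrigation_reliant": 0.5,
        "mechanized": 1.0, "thz_class": "T6", "mst_class": "M4",
        "soil_class": "S3",
    }
    base.update(over)
    return pd.DataFrame([base])[CELL_COLUMNS]


WORKED_FIXTURES = {
    # one cell holding the entire crop area: applying a 10% surplus
    # fraction to a baseline rate of 100 units must return 10 units
    "n_phase1_100units": lambda: _fixture_row(n_fert=100.0, area_ha=1.0),
    # 100 ha worked by draft cattle at 5 ha/head: 20 head, 7.954 kg N/ha
    "draft_cattle_100ha": lambda: _fixture_row(area_ha=100.0),
    # baseline yield far below what its inputs support, so a fitted
    # response surface predicts above baseline and the relative change
    # clips to zero
    "clip_positive_rc": lambda: _fixture_row(
        yield_kg_ha=200.0, n_fert=200.0, pesticides=3.0,
        irrigation_tot=0.9, mechanized=1.0,
    ),
}


def make_worked_fixture(name: str) -> pd.DataFrame:
    """Return one of the registered single-cell arithmetic fixtures."""
    try:
        builder = WORKED_FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(WORKED_FIXTURES)}"
        ) from None
    return validate_cell_table(builder())
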