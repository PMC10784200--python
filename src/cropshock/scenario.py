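"""Phase-1 / phase-2 input scenarios after a global infrastructure loss.

The scenario assumes a sudden, worldwide loss of the electrical grid and
the industry depending on it.  Agriculture then runs on whatever is in
storage.  *Phase 1* is the first year: fuel stocks keep machinery
running, and the accumulated production surplus of N fertilizer and
pesticides (roughly a tenth of one year's use) is spread over the same
cells in proportion to their current application.  *Phase 2* starts
when stocks are gone: no mineral fertilizer, no pesticides, no
machinery.  In both phases, irrigation shrinks to the fraction not
reliant on powered pumps, and manure N comes only from the draft cattle
kept to work the land.

Phase-1 fertilizer reallocation (per crop):

    N_frac      = N_fert * A / sum(N_fert * A)          (cell share)
    N_total,1   = sum(N_fert * A) / T_NG * T_NG1        (surplus pool)
    N_fert,1    = N_total,1 * N_frac / A                (new rate)

which collapses algebraically to uniform scaling by the surplus ratio
T_NG1 / T_NG; both routes are computed and their equality asserted, as
a guard against mis-implementing the printed chain.  Pesticides follow
the same construction with the same surplus ratio (the global pesticide
total cancels).  Draft-cattle manure per cell:

    C = A / ha_per_head ;  M = excretion_rate * C / A

i.e. a constant excretion_rate / ha_per_head kg N per hectare.
Remaining irrigation: I_gcil = I_AC * (1 - I_RC).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ScenarioParams",
    "PhaseInputs",
    "FuelCoverage",
    "nitrogen_phase1",
    "pesticides_phase1",
    "draft_cattle_manure",
    "irrigation_gcil",
    "fuel_coverage",
    "build_phase_inputs",
]


@dataclass(frozen=True)
class ScenarioParams:
    """Scenario constants, defaulting to the published global figures.

    Units: nutrient totals in kt N yr^-1, fuel in ktoe, excretion in
    kg N head^-1 yr^-1, working capacity in ha head^-1.
    """

    t_ng: float = 118763.0        # global N use for crop fertilization, 2020 projection
    t_ng1: float = 14477.0        # projected 2020 N production surplus
    surplus_ratio_pesticides: float | None = None  # None -> same as N surplus ratio
    excretion_rate: float = 39.77  # kg N per head of cattle per year
    ha_per_head: float = 5.0       # conservative working capacity (7.4 typical)
    fuel_demand_ktoe: float = 111062.0  # annual agricultural oil-product demand, 2018
    fuel_stock_gasoline_ktoe: float = 172000.0
    fuel_stock_diesel_ktoe: float = 147000.0
    # provenance of the excretion rate: 2014 manure N total, cattle share,
    # and herd size, from which ~40 kg N/head/yr follows
    manure_total_kt: float = 131000.0
    manure_cattle_share: float = 0.437
    cattle_head: float = 1.44e9

    def __post_init__(self):
        for name in ("t_ng", "t_ng1", "excretion_rate", "ha_per_head",
                     "fuel_demand_ktoe", "manure_total_kt", "cattle_head"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # ratio 1 is the identity limit used for pipeline diagnostics
        if not 0 < self.surplus_ratio_n <= 1:
            raise ValueError("N surplus ratio must lie in (0, 1]")

    @property
    def surplus_ratio_n(self) -> float:
        return self.t_ng1 / self.t_ng

    @property
    def pesticide_ratio(self) -> float:
        if self.surplus_ratio_pesticides is None:
            return self.surplus_ratio_n
        return self.surplus_ratio_pesticides

    def derived_excretion_rate(self) -> float:
        """kg N head^-1 yr^-1 implied by the herd-level figures."""
        return self.manure_total_kt * 1e6 * self.manure_cattle_share / self.cattle_head


def _reallocate(rate: pd.Series, area: pd.Series, crop: pd.Series, ratio: float,
                what: str) -> pd.Series:
    """Fraction -> new pool -> reallocation chain, per crop."""
    out = pd.Series(np.nan, index=rate.index)
    for c, idx in rate.groupby(crop).groups.items():
        r = rate.loc[idx]
        a = area.loc[idx]
        applied = r * a
        total = applied.sum()
        if total <= 0:
            if (r.fillna(0) != 0).any():
                raise ValueError(f"{what}: zero global application for crop {c!r}")
            out.loc[idx] = 0.0
            continue
        frac = applied / total          # cell share of the global pool
        new_total = total * ratio       # surplus pool for this crop
        out.loc[idx] = new_total * frac / a
    return out


def nitrogen_phase1(
    table: pd.DataFrame, params: ScenarioParams | None = None
) -> pd.Series:
    """Phase-1 per-cell N fertilizer rate via the reallocation chain.

    Computes both the fraction/pool/reallocate route and the equivalent
    uniform scaling by the surplus ratio, and asserts their equality to
    machine precision.  The returned values use the direct scaling,
    which is the numerically cleaner of the two identical expressions
    (it is exact in the ratio-1 identity limit).
    """
    params = params or ScenarioParams()
    ratio = params.surplus_ratio_n
    via_chain = _reallocate(
        table["n_fert"], table["area_ha"], table["crop"], ratio, "nitrogen_phase1"
    )
    via_scaling = table["n_fert"] * ratio
    if not np.allclose(via_chain, via_scaling, rtol=1e-12, atol=1e-12, equal_nan=True):
        raise AssertionError("reallocation chain disagrees with uniform scaling")
    return via_scaling.rename("n_fert_phase1")


def pesticides_phase1(
    table: pd.DataFrame, params: ScenarioParams | None = None
) -> pd.Series:
    """Phase-1 pesticide rates: same construction, pesticide surplus ratio.

    The global pesticide total enters the printed pool formula once in
    the numerator and once in the denominator, so it cancels and is
    never needed numerically.
    """
    params = params or ScenarioParams()
    ratio = params.pesticide_ratio
    via_chain = _reallocate(
        table["pesticides"], table["area_ha"], table["crop"], ratio, "pesticides_phase1"
    )
    via_scaling = table["pesticides"] * ratio
    if not np.allclose(via_chain, via_scaling, rtol=1e-12, atol=1e-12, equal_nan=True):
        raise AssertionError("reallocation chain disagrees with uniform scaling")
    return via_scaling.rename("pesticides_phase1")


def draft_cattle_manure(
    table: pd.DataFrame, params: ScenarioParams | None = None
) -> pd.DataFrame:
    """Draft-cattle head count and manure N rate per cell (both phases).

    C = A / ha_per_head head;  M = excretion_rate * C / A kg N ha^-1,
    a constant rate excretion_rate / ha_per_head.
    """
    params = params or ScenarioParams()
    area = table["area_ha"]
    if (area <= 0).any() or area.isna().any():
        raise ValueError("harvested area must be positive for manure accounting")
    cattle = area / params.ha_per_head
    # excretion_rate * C / A simplifies to a constant per-ha rate; using
    # the simplified form keeps the rate bit-identical across cells
    rate = params.excretion_rate / params.ha_per_head
    manure = pd.Series(rate, index=table.index)
    return pd.DataFrame({"cattle_head": cattle, "manure_n_rate": manure})


def irrigation_gcil(table: pd.DataFrame) -> pd.Series:
    """Irrigated fraction surviving the grid loss: I_AC * (1 - I_RC)."""
    iac = table["irrigation_tot"].astype(float)
    irc = table["irrigation_reliant"].astype(float)
    for name, s in [("irrigation_tot", iac), ("irrigation_reliant", irc)]:
        if ((s < 0) | (s > 1)).any():
            raise ValueError(f"{name} outside [0, 1]")
    return (iac * (1.0 - irc)).rename("irrigation_gcil")


@dataclass(frozen=True)
class FuelCoverage:
    years: float
    mechanization_unchanged: bool


def fuel_coverage(params: ScenarioParams | None = None) -> FuelCoverage:
    """Years of agricultural fuel demand covered by the diesel stock.

    Machinery runs on diesel; gasoline is reserved for critical
    transport.  Phase-1 mechanization stays at baseline iff coverage
    reaches one year (the published stock and demand figures give
    ~1.3 years).
    """
    params = params or ScenarioParams()
    years = params.fuel_stock_diesel_ktoe / params.fuel_demand_ktoe
    unchanged = years >= 1.0
    if not unchanged:
        warnings.warn(
            f"diesel stocks cover only {years:.2f} years of demand; "
            "phase-1 mechanization will be zeroed (departure from the "
            "standard stock assumptions)",
            stacklevel=2,
        )
    return FuelCoverage(years=float(years), mechanization_unchanged=unchanged)


@dataclass(frozen=True)
class PhaseInputs:
    """Predictor table for one scenario phase, plus bookkeeping."""

    phase: int
    table: pd.DataFrame  # cell table with scenario predictor values
    params: ScenarioParams
    fuel: FuelCoverage

    def __post_init__(self):
        t = self.table
        if self.phase == 2:
            assert (t["n_fert"] == 0).all()
            assert (t["pesticides"] == 0).all()
            assert (t["mechanized"] == 0).all()
        for col in ("n_fert", "n_manure", "n_total", "pesticides", "irrigation_tot"):
            assert not (t[col] < 0).any()


def build_phase_inputs(
    table: pd.DataFrame, params: ScenarioParams | None = None, phase: int = 1
) -> PhaseInputs:
    """Assemble the full predictor table for phase 1 or 2.

    Phase 1: fertilizer and pesticides scaled to the surplus pool,
    machinery unchanged while diesel stocks last, n_total = reallocated
    fertilizer + draft-cattle manure.  Phase 2: fertilizer, pesticides
    and machinery zero; manure is the sole N source.  Irrigation and
    manure are identical across phases.
    """
    params = params or ScenarioParams()
    if phase not in (1, 2):
        raise ValueError(f"phase must be 1 or 2, got {phase!r}")
    out = table.copy()
    manure = draft_cattle_manure(table, params)["manure_n_rate"]
    out["n_manure"] = manure
    out["irrigation_tot"] = irrigation_gcil(table)
    out["irrigation_reliant"] = 0.0
    fuel = fuel_coverage(params)
    if phase == 1:
        out["n_fert"] = nitrogen_phase1(table, params)
        out["pesticides"] = pesticides_phase1(table, params)
        if not fuel.mechanization_unchanged:
            log.warning("phase 1: zeroing mechanization for lack of diesel")
            out["mechanized"] = 0.0
    else:
        out["n_fert"] = 0.0
        out["pesticides"] = 0.0
        out["mechanized"] = 0.0
    out["n_total"] = out["n_fert"] + out["n_manure"]
    return PhaseInputs(phase=phase, table=out, params=params, fuel=fuel)
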