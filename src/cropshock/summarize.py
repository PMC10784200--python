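"""Per-cell scenario predictions and weighted yield-loss summaries.

For each (cell, crop, phase) the fitted response surface is evaluated
on the scenario inputs, giving a predicted yield Y_PC.  The relative
change against the baseline yield,

    RC = (Y_PC - Y_crop) / Y_crop , then clipped at zero from above,

is the headline per-cell statistic; predicted increases are read as
"yield stable despite the catastrophe", not as gains.  Summaries are
weighted: mean yields by harvested area, mean relative changes by
baseline production (yield x area), per crop x phase x region plus a
global rollup.

Two baselines are supported.  ``baseline="observed"`` divides by the
recorded baseline yield — the headline definition.  ``baseline="modeled"``
divides by the model's own prediction under current inputs, which
isolates the scenario effect from model error and is the right yardstick
for pipeline diagnostics such as the identity limit (scenario = baseline
inputs must give RC identically zero).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .scenario import PhaseInputs

__all__ = [
    "relative_change",
    "weighted_mean",
    "predict_phases",
    "summarize",
    "plot_reduction_by_crop",
]

GLOBAL_REGION = "Global"


def relative_change(y_pred, y_base) -> pd.Series:
    """(Y_PC - Y_crop) / Y_crop, clipped at zero from above."""
    y_pred = pd.Series(np.asarray(y_pred, dtype=float))
    y_base = pd.Series(np.asarray(y_base, dtype=float))
    if (y_base <= 0).any() or y_base.isna().any():
        raise ValueError("baseline yield must be strictly positive")
    rc = (y_pred - y_base) / y_base
    return rc.clip(upper=0.0).rename("rc")


def weighted_mean(values, weights, *, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """Weighted mean with a normal-approximation confidence interval.

    The CI uses the effective sample size n_eff = (sum w)^2 / sum w^2,
    appropriate when weights are known constants (areas, production).
    """
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    ok = ~np.isnan(v) & ~np.isnan(w)
    v, w = v[ok], w[ok]
    if (w < 0).any():
        raise ValueError("negative weights")
    if w.sum() <= 0:
        raise ValueError("weights sum to zero")
    mean = float(np.average(v, weights=w))
    n_eff = w.sum() ** 2 / (w**2).sum()
    var = float(np.average((v - mean) ** 2, weights=w))
    se = np.sqrt(var / n_eff) if n_eff > 1 else np.nan
    z = stats.norm.ppf(1 - alpha / 2)
    return mean, (mean - z * se, mean + z * se)


def predict_phases(
    fits: dict,
    baseline: pd.DataFrame,
    phases: dict[int, PhaseInputs],
    *,
    baseline_mode: str = "observed",
) -> pd.DataFrame:
    """Per-cell predictions and relative changes for each phase.

    Parameters
    ----------
    fits
        Mapping crop -> fitted :class:`~cropshock.glm.CropYieldResults`.
    baseline
        The preprocessed cell table (provides Y_crop, areas, regions).
    phases
        Mapping phase number -> :class:`~cropshock.scenario.PhaseInputs`
        built from the same baseline table.
    baseline_mode
        "observed" (recorded yield, headline definition) or "modeled"
        (model prediction at current inputs, diagnostic definition).

    Cells whose class levels were unseen during calibration get missing
    predictions, are excluded from the weighted means, and are counted
    in the ``n_unsupported`` attribute of the result.
    """
    if baseline_mode not in ("observed", "modeled"):
        raise ValueError("baseline_mode must be 'observed' or 'modeled'")
    records = []
    n_unsupported = 0
    for phase, inputs in sorted(phases.items()):
        ptab = inputs.table
        if len(ptab) != len(baseline):
            raise ValueError("phase inputs not aligned with baseline table")
        for crop, group in ptab.groupby("crop", sort=False):
            fit = fits[crop]
            base_rows = baseline.loc[group.index]
            # cells with class levels unseen in calibration get missing
            # predictions and fall out of the weighted means
            supported = fit.supported_mask(group)
            y_pred = pd.Series(np.nan, index=group.index)
            if supported.any():
                y_pred.loc[supported] = fit.predict(group.loc[supported]).to_numpy()
            n_unsupported += int((~supported).sum())
            if baseline_mode == "observed":
                y_base = base_rows["yield_kg_ha"].astype(float)
            else:
                y_base = pd.Series(np.nan, index=group.index)
                if supported.any():
                    y_base.loc[supported] = fit.predict(
                        base_rows.loc[supported]
                    ).to_numpy()
            rc = (y_pred.to_numpy() - y_base.to_numpy()) / y_base.to_numpy()
            rc = np.minimum(rc, 0.0)
            records.append(
                pd.DataFrame(
                    {
                        "cell_id": base_rows["cell_id"].to_numpy(),
                        "crop": crop,
                        "phase": phase,
                        "region": base_rows["region"].to_numpy(),
                        "area_ha": base_rows["area_ha"].to_numpy(),
                        "y_base": y_base.to_numpy(),
                        "y_pred": y_pred.to_numpy(),
                        "rc": rc,
                        "production": (
                            base_rows["yield_kg_ha"] * base_rows["area_ha"]
                        ).to_numpy(),
                    }
                )
            )
    out = pd.concat(records, ignore_index=True)
    out.attrs["n_unsupported"] = n_unsupported
    out.attrs["baseline_mode"] = baseline_mode
    return out


def _stats_for(group: pd.DataFrame) -> dict:
    ok = group["y_pred"].notna()
    g = group.loc[ok]
    yield_mean, yield_ci = weighted_mean(g["y_pred"], g["area_ha"])
    rc_mean, rc_ci = weighted_mean(g["rc"], g["production"])
    return {
        "n_cells": int(len(g)),
        "yield_weighted_mean": yield_mean,
        "yield_ci_low": yield_ci[0],
        "yield_ci_high": yield_ci[1],
        "yield_min": float(g["y_pred"].min()),
        "yield_max": float(g["y_pred"].max()),
        "rc_weighted_mean": rc_mean,
        "rc_ci_low": rc_ci[0],
        "rc_ci_high": rc_ci[1],
        "rc_min": float(g["rc"].min()),
        "rc_max": float(g["rc"].max()),
        "total_production": float(g["production"].sum()),
    }


def summarize(predictions: pd.DataFrame) -> pd.DataFrame:
    """Weighted summaries per crop x phase x region, plus global rows.

    Yield means are weighted by harvested area, relative-change means by
    baseline production.  Rows are permutation-invariant in the input.
    """
    if predictions["region"].isna().any():
        n = int(predictions["region"].isna().sum())
        raise ValueError(f"{n} prediction rows have no region assigned")
    rows = []
    for (crop, phase, region), group in predictions.groupby(
        ["crop", "phase", "region"], sort=True
    ):
        rows.append({"crop": crop, "phase": phase, "region": region, **_stats_for(group)})
    for (crop, phase), group in predictions.groupby(["crop", "phase"], sort=True):
        rows.append(
            {"crop": crop, "phase": phase, "region": GLOBAL_REGION, **_stats_for(group)}
        )
    return pd.DataFrame(rows)


def plot_reduction_by_crop(summary: pd.DataFrame, path=None):
    """Bar chart of global production-weighted yield reduction by crop
    and phase (percent).  Returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    glob = summary[summary["region"] == GLOBAL_REGION]
    crops = sorted(glob["crop"].unique())
    phases = sorted(glob["phase"].unique())
    width = 0.8 / max(len(phases), 1)
    fig, ax = plt.subplots(figsize=(6, 4))
    for k, phase in enumerate(phases):
        sub = glob[glob["phase"] == phase].set_index("crop")
        vals = [-100 * sub.loc[c, "rc_weighted_mean"] for c in crops]
        ax.bar(np.arange(len(crops)) + k * width, vals, width, label=f"phase {phase}")
    ax.set_xticks(np.arange(len(crops)) + width * (len(phases) - 1) / 2)
    ax.set_xticklabels(crops)
    ax.set_ylabel("yield reduction [%] (production-weighted)")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
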