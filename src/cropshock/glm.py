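"""Gamma GLM of crop yield on agronomic inputs and agro-climatic classes.

Yield per hectare is non-negative and strongly right-skewed, so the
response is modelled as Gamma(shape, scale) with mean mu = shape * scale
and a natural-log link tying the mean to a linear predictor in the
inputs:

    ln mu = eta = b0 + b1 x1 + ... + bp xp

with no interactions, and the categorical classes dummy-coded against
the lowest-ordered reference level (T1, M2, S1).  One model is fitted
per crop on a random 80% calibration split; fit quality is judged on
the held-out 20% with McFadden's pseudo-R-squared, and per-factor
influence is summarised by the yield swing between a factor's observed
minimum and maximum with everything else held constant — which, under
the log link, is exp(b_j (x_min - x_max)) - 1 regardless of where the
other factors are held.

The module follows the Model/Results idiom: build a
:class:`CropYieldModel` from a cleaned cell table, call ``fit()``, and
work with the returned :class:`CropYieldResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ModelSpec",
    "CropYieldModel",
    "CropYieldResults",
    "ValidationResult",
    "FactorEffect",
    "split_sample",
    "fit_gamma_glm",
    "DEFAULT_SPLIT_SEED",
]

#: documented default seed of the calibration/validation split
DEFAULT_SPLIT_SEED = 20100


@dataclass(frozen=True)
class ModelSpec:
    """Predictor set and coding of the yield response surface."""

    response: str = "yield_kg_ha"
    continuous: tuple[str, ...] = ("n_total", "pesticides", "irrigation_tot")
    binary: tuple[str, ...] = ("mechanized",)
    categorical: dict[str, str] = field(
        default_factory=lambda: {
            "thz_class": "T1",
            "mst_class": "M2",
            "soil_class": "S1",
        }
    )

    @property
    def predictors(self) -> list[str]:
        return [*self.continuous, *self.binary, *self.categorical]

    def formula_for(self, data: pd.DataFrame) -> str:
        """Model formula with per-categorical reference levels.

        The configured reference (lowest-ordered level) is used when it
        occurs in ``data``; otherwise the lowest observed level stands
        in, so a calibration subset missing a sparse level still fits.
        """
        terms = list(self.continuous)
        terms += list(self.binary)
        for col, ref in self.categorical.items():
            levels = sorted(data[col].dropna().unique())
            if not levels:
                raise ValueError(f"categorical {col!r} has no observed levels")
            if ref not in levels:
                ref = levels[0]
            terms.append(f"C({col}, Treatment(reference={ref!r}))")
        return f"{self.response} ~ " + (" + ".join(terms) or "1")

    @property
    def formula(self) -> str:
        terms = list(self.continuous)
        terms += list(self.binary)
        terms += [
            f"C({col}, Treatment(reference={ref!r}))"
            for col, ref in self.categorical.items()
        ]
        return f"{self.response} ~ " + " + ".join(terms)


def split_sample(
    table: pd.DataFrame, fraction: float = 0.8, seed: int = DEFAULT_SPLIT_SEED
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random, reproducible calibration/validation partition.

    Disjoint and exhaustive; the calibration size is round(fraction*n).
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    n = len(table)
    if n < 5:
        raise ValueError(f"table too small to split ({n} rows)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_cal = int(round(fraction * n))
    n_cal = min(max(n_cal, 1), n - 1)
    cal = table.iloc[perm[:n_cal]].reset_index(drop=True)
    val = table.iloc[perm[n_cal:]].reset_index(drop=True)
    return cal, val


def _check_design(X: pd.DataFrame) -> None:
    arr = np.asarray(X, dtype=float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the offending columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(arr, mode="economic", pivoting=True)
        bad = sorted(X.columns[i] for i in piv[rank:])
        raise ValueError(f"design is rank deficient; offending columns: {bad}")


class CropYieldModel:
    """Gamma(log-link) yield model bound to one crop's calibration data.

    Parameters
    ----------
    data
        Cleaned cell table (one crop) with the spec's predictors and a
        strictly positive response.
    spec
        Predictor set and dummy coding; defaults to the standard seven
        predictors.
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec | None = None, crop: str | None = None):
        self.spec = spec or ModelSpec()
        self.crop = crop or (data["crop"].iloc[0] if "crop" in data and len(data) else None)
        missing = [
            c for c in (self.spec.response, *self.spec.predictors) if c not in data.columns
        ]
        if missing:
            raise ValueError(f"data lacks columns {missing}")
        y = data[self.spec.response]
        if (y <= 0).any() or y.isna().any():
            raise ValueError("response must be strictly positive and complete")
        self.data = data.reset_index(drop=True)
        self.levels_ = {
            col: set(self.data[col].dropna().unique()) for col in self.spec.categorical
        }
        y_dm, X = patsy.dmatrices(
            self.spec.formula_for(self.data), self.data, return_type="dataframe"
        )
        _check_design(X)
        self._glm = sm.GLM(
            y_dm, X, family=sm.families.Gamma(link=sm.families.links.Log())
        )
        self._design_info = X.design_info

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, spec: ModelSpec | None = None, crop: str | None = None
    ) -> "CropYieldModel":
        return cls(data, spec=spec, crop=crop)

    def fit(self) -> "CropYieldResults":
        res = self._glm.fit()
        # intercept-only null companion, for held-out pseudo-R^2
        y = self.data[self.spec.response]
        null = sm.GLM(
            y, np.ones((len(y), 1)),
            family=sm.families.Gamma(link=sm.families.links.Log()),
        ).fit()
        return CropYieldResults(self, res, null)


def fit_gamma_glm(
    calibration: pd.DataFrame, spec: ModelSpec | None = None
) -> "CropYieldResults":
    """Convenience wrapper: build the model and fit it in one call."""
    return CropYieldModel(calibration, spec=spec).fit()


@dataclass(frozen=True)
class ValidationResult:
    """Held-out goodness of fit of one crop's model."""

    crop: str | None
    rho2: float
    loglik_model: float
    loglik_null: float
    n_validation: int
    warning: str | None = None


@dataclass(frozen=True)
class FactorEffect:
    """Min-to-max yield swing attributable to one factor."""

    factor: str
    x_min: float
    x_max: float
    mu_at_min: float
    mu_at_max: float
    percent_change: float  # (mu_min - mu_max) / mu_max * 100


class CropYieldResults:
    """Fitted gamma GLM: coefficients, intervals, dispersion, prediction.

    The gamma dispersion phi is estimated from the Pearson residuals of
    the calibration fit; the implied shape parameter is 1/phi and the
    per-observation scale is mu_i * phi (so mu = shape * scale holds
    row-wise).
    """

    def __init__(self, model: CropYieldModel, res, null_res):
        self.model = model
        self.crop = model.crop
        self._res = res
        self._null = null_res
        self.params: pd.Series = res.params
        self.pvalues: pd.Series = res.pvalues
        self.conf_int_: pd.DataFrame = res.conf_int(alpha=0.05)
        self.dispersion: float = float(res.pearson_chi2 / res.df_resid)
        self.shape_: float = 1.0 / self.dispersion
        self.nobs: int = int(res.nobs)
        self.loglike_calibration: float = float(res.llf)

    # -- presentation -------------------------------------------------

    def summary(self):
        return self._res.summary(title=f"Gamma GLM (log link): {self.crop or 'yield'}")

    def coef_table(self) -> pd.DataFrame:
        ci = self.conf_int_
        return pd.DataFrame(
            {
                "estimate": self.params,
                "ci_low": ci[0],
                "ci_high": ci[1],
                "p_value": self.pvalues,
            }
        )

    # -- prediction ---------------------------------------------------

    def predict(self, table: pd.DataFrame) -> pd.Series:
        """Mean yield mu = exp(eta) per row; strictly positive.

        Raises on categorical levels unseen during calibration, naming
        the level.
        """
        try:
            (X,) = patsy.build_design_matrices(
                [self.model._design_info], table, return_type="dataframe"
            )
        except patsy.PatsyError as err:
            raise ValueError(f"prediction failed (unseen level?): {err}") from None
        mu = np.exp(X.to_numpy(dtype=float) @ self.params.to_numpy())
        return pd.Series(mu, index=table.index, name="mu")

    def supported_mask(self, table: pd.DataFrame) -> pd.Series:
        """True where every categorical level was seen during calibration."""
        mask = pd.Series(True, index=table.index)
        for col, levels in self.model.levels_.items():
            mask &= table[col].isin(levels)
        return mask

    # -- validation ---------------------------------------------------

    def _gamma_loglik(self, y: np.ndarray, mu: np.ndarray) -> float:
        shape = self.shape_
        return float(stats.gamma.logpdf(y, a=shape, scale=mu / shape).sum())

    def mcfadden_rho2(self, validation: pd.DataFrame) -> ValidationResult:
        """McFadden's rho^2 = 1 - lnL_model / lnL_null on held-out rows.

        Both likelihoods use the calibration fit's dispersion; the null
        is the intercept-only gamma GLM fitted on calibration.  Values
        of roughly 0.2-0.4 indicate an excellent fit.
        """
        if len(validation) == 0:
            raise ValueError("validation set is empty")
        warning = None
        supported = self.supported_mask(validation)
        if not supported.all():
            n_drop = int((~supported).sum())
            warning = (
                f"{n_drop} validation rows with class levels unseen in "
                "calibration excluded from the likelihood"
            )
            warnings.warn(warning, stacklevel=2)
            validation = validation.loc[supported]
            if len(validation) == 0:
                raise ValueError("no validation rows within model support")
        y = validation[self.model.spec.response].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            warning = "validation response is constant; rho2 is not informative"
            warnings.warn(warning, stacklevel=2)
        mu = self.predict(validation).to_numpy()
        mu_null = np.full_like(mu, float(np.exp(self._null.params.iloc[0])))
        ll_model = self._gamma_loglik(y, mu)
        ll_null = self._gamma_loglik(y, mu_null)
        rho2 = 1.0 - ll_model / ll_null
        return ValidationResult(
            crop=self.crop,
            rho2=float(rho2),
            loglik_model=ll_model,
            loglik_null=ll_null,
            n_validation=len(validation),
            warning=warning,
        )

    # -- per-factor influence -----------------------------------------

    def factor_effect(self, table: pd.DataFrame, factor: str) -> FactorEffect:
        """Yield change between a factor's observed extremes.

        Predicts at the factor's minimum and maximum with all other
        predictors held constant and reports the change as a percentage
        of the maximum-input prediction.  For the log link with no
        interactions this equals exp(b_j (x_min - x_max)) - 1 whatever
        the held-constant values are.  Multi-level categorical factors
        have no single min/max axis and are unsupported.
        """
        spec = self.model.spec
        if factor in spec.categorical:
            raise ValueError(f"{factor!r} is multi-level categorical; no min/max axis")
        if factor not in (*spec.continuous, *spec.binary):
            raise ValueError(f"unknown factor {factor!r}")
        x = table[factor].dropna().astype(float)
        x_min, x_max = float(x.min()), float(x.max())
        base = table.iloc[[0]].copy()
        lo, hi = base.copy(), base.copy()
        lo[factor] = x_min
        hi[factor] = x_max
        mu_min = float(self.predict(lo).iloc[0])
        mu_max = float(self.predict(hi).iloc[0])
        return FactorEffect(
            factor=factor,
            x_min=x_min,
            x_max=x_max,
            mu_at_min=mu_min,
            mu_at_max=mu_max,
            percent_change=(mu_min - mu_max) / mu_max * 100.0,
        )
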