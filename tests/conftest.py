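import re

import numpy as np
import pandas as pd
import pytest

from cropshock.glm import ModelSpec, fit_gamma_glm
from cropshock.preprocess import merge_classes, preprocess
from cropshock.synthetic import default_config, generate_landscape


@pytest.fixture(scope="session")
def landscape():
    """Default-conditions landscape: 4 crops, missingness and outliers on."""
    return generate_landscape(default_config(seed=7, n_rows=30, n_cols=40))


@pytest.fixture(scope="session")
def preprocessed(landscape):
    table, report = preprocess(landscape)
    return table, report


def clean_crop_table(seed: int, crop: str = "wheat", n_rows: int = 100, n_cols: int = 100):
    """Uncorrupted single-crop table with merged classes and n_total filled."""
    cfg = default_config(
        seed=seed,
        n_rows=n_rows,
        n_cols=n_cols,
        crops=(crop,),
        missing_pesticides=0.0,
        missing_mechanized=0.0,
        missing_n_fert=0.0,
        missing_classes=0.0,
        outlier_rate=0.0,
    )
    table = generate_landscape(cfg)
    table, _ = merge_classes(table)
    table["n_total"] = table["n_fert"] + table["n_manure"]
    return table, cfg.coefficients[crop]


@pytest.fixture(scope="session")
def wheat_fit():
    """Fitted gamma GLM on 10,000 clean wheat cells plus its truth."""
    table, truth = clean_crop_table(seed=11)
    fit = fit_gamma_glm(table, ModelSpec())
    return fit, table, truth


_TERM_RE = re.compile(r"C\((\w+),.*\)\[T\.(\w+)\]")


def coefficient_key(name: str):
    """Map a fitted parameter name to (column, level) or the plain name."""
    m = _TERM_RE.match(name)
    if m:
        return (m.group(1), m.group(2))
    return name


def true_coefficient_map(coef) -> dict:
    out = {
        "Intercept": coef.intercept,
        "n_total": coef.n_total,
        "pesticides": coef.pesticides,
        "irrigation_tot": coef.irrigation_tot,
        "mechanized": coef.mechanized,
    }
    for col, d in [
        ("thz_class", coef.thz),
        ("mst_class", coef.mst),
        ("soil_class", coef.soil),
    ]:
        for lvl, v in d.items():
            out[(col, lvl)] = v
    return out
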