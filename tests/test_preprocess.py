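"""Cleaning ledger semantics and the GVIF multicollinearity screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cropshock.preprocess import (
    ClassMergeMap,
    combine_nitrogen,
    compute_gvif,
    filter_min_area,
    handle_missing,
    merge_classes,
    preprocess,
    trim_outliers,
)
from cropshock.synthetic import default_config, generate_landscape


def tiny_table(**cols) -> pd.DataFrame:
    n = max(
        len(v) for v in cols.values() if isinstance(v, (list, np.ndarray, pd.Series))
    )
    base = {
        "cell_id": np.arange(n),
        "crop": "wheat",
        "yield_kg_ha": 1000.0,
        "area_ha": 200.0,
        "n_fert": 50.0,
        "n_manure": 10.0,
        "pesticides": 1.0,
        "mechanized": 1.0,
        "thz_class": "T3",
        "mst_class": "M4",
        "soil_class": "S3",
    }
    base.update(cols)
    return pd.DataFrame(base)


class TestAreaFilter:
    def test_strictly_below_threshold_removed(self):
        t = tiny_table(area_ha=[99.9, 100.0, 150.0])
        out, rep = filter_min_area(t)
        assert sorted(out["area_ha"]) == [100.0, 150.0]
        assert rep.steps[0]["rows_removed"] == 1

    def test_empty_table(self):
        t = tiny_table(area_ha=[1.0]).iloc[:0]
        out, rep = filter_min_area(t)
        assert len(out) == 0 and rep.rows_in == 0

    def test_production_share_removed(self):
        # sub-100-ha rows hold exactly 2% of production by construction
        t = tiny_table(
            area_ha=[50.0, 1000.0], yield_kg_ha=[40.0, 98.0]
        )  # 2000 vs 98000 => 2%
        _, rep = filter_min_area(t)
        assert rep.steps[0]["details"]["production_share_removed"] == pytest.approx(0.02)


class TestHandleMissing:
    def test_missing_pesticides_row_dropped(self):
        t = tiny_table(pesticides=[1.0, np.nan, 2.0])
        out, _ = handle_missing(t)
        assert list(out["pesticides"]) == [1.0, 2.0]

    def test_class_forward_fill_carries_last_value(self):
        t = tiny_table(thz_class=["T3", np.nan, np.nan])
        out, _ = handle_missing(t)
        assert list(out["thz_class"]) == ["T3", "T3", "T3"]

    def test_leading_missing_dropped(self):
        t = tiny_table(thz_class=[np.nan, "T5", np.nan])
        out, _ = handle_missing(t)
        assert list(out["thz_class"]) == ["T5", "T5"]

    def test_fill_respects_cell_id_order_not_input_order(self):
        t = tiny_table(thz_class=["T2", np.nan, "T6"], cell_id=[2, 1, 0])
        out, _ = handle_missing(t)
        # in cell_id order the sequence is [T6, NaN, T2] -> fill with T6
        assert out.set_index("cell_id").loc[1, "thz_class"] == "T6"

    def test_all_missing_column_errors_with_name(self):
        t = tiny_table(n_fert=[np.nan, np.nan])
        with pytest.raises(ValueError, match="n_fert"):
            handle_missing(t)

    def test_fill_does_not_cross_crop_boundary(self):
        t = pd.concat(
            [
                tiny_table(thz_class=["T2"], crop="corn"),
                tiny_table(thz_class=[np.nan, "T5"], crop="wheat"),
            ],
            ignore_index=True,
        )
        out, _ = handle_missing(t)
        wheat = out[out["crop"] == "wheat"]
        assert len(wheat) == 1  # leading gap in wheat not filled from corn


class TestTrimOutliers:
    def test_equal_values_nothing_removed(self):
        t = tiny_table(n_fert=np.full(1000, 5.0))
        out, _ = trim_outliers(t, {"n_fert": 99.9})
        assert len(out) == 1000

    def test_single_extreme_value_removed_per_percentile_definition(self):
        vals = np.concatenate([np.ones(999), [1000.0]])
        t = tiny_table(n_fert=vals)
        thr = np.percentile(vals, 99.9)  # linear interpolation oracle
        out, rep = trim_outliers(t, {"n_fert": 99.9})
        assert len(out) == 999
        assert rep.steps[0]["details"]["threshold_wheat"] == pytest.approx(thr)

    def test_value_exactly_at_threshold_retained(self):
        # 101 values: the 99th percentile is exactly the value 99.0
        vals = np.arange(0.0, 101.0)
        t = tiny_table(n_fert=vals)
        thr = np.percentile(vals, 99.0)
        assert thr == 99.0
        out, _ = trim_outliers(t, {"n_fert": 99.0})
        assert out["n_fert"].max() == thr  # at-threshold value kept
        assert len(out) == 100  # only the strictly-above value dropped

    def test_manure_and_fertilizer_use_different_percentiles(self):
        rng = np.random.default_rng(0)
        t = tiny_table(n_fert=rng.lognormal(3, 1, 500), n_manure=rng.lognormal(2, 1, 500))
        _, rep = trim_outliers(t, {"n_fert": 99.9, "n_manure": 99.0})
        steps = {s["step"]: s["details"] for s in rep.steps}
        assert steps["trim_n_fert"]["percentile"] == 99.9
        assert steps["trim_n_manure"]["percentile"] == 99.0

    def test_trims_are_per_crop(self):
        a = tiny_table(n_fert=np.linspace(1, 100, 200), crop="corn")
        b = tiny_table(n_fert=np.linspace(1000, 2000, 200), crop="wheat")
        t = pd.concat([a, b], ignore_index=True)
        _, rep = trim_outliers(t, {"n_fert": 99.0})
        d = rep.steps[0]["details"]
        assert d["threshold_corn"] < 100 < d["threshold_wheat"]


class TestCombineNitrogen:
    def test_simple_sum(self):
        n = 500
        t = tiny_table(
            n_fert=np.r_[np.full(n, 50.0), np.zeros(n)],
            n_manure=np.r_[np.full(n, 20.0), np.zeros(n)],
        )
        out, _ = combine_nitrogen(t)
        assert set(out["n_total"]) == {70.0, 0.0}
        assert len(out) == 2 * n  # equal-valued totals are never trimmed

    def test_post_merge_trim_removes_extreme_total(self):
        n = 1000
        t = tiny_table(n_fert=np.ones(n), n_manure=np.ones(n))
        t.loc[0, "n_fert"] = 5000.0
        out, _ = combine_nitrogen(t)
        assert len(out) == n - 1
        assert out["n_total"].max() == 2.0

    def test_missing_inputs_rejected(self):
        t = tiny_table(n_fert=[np.nan, 1.0])
        with pytest.raises(ValueError, match="n_fert"):
            combine_nitrogen(t)


class TestMergeClasses:
    @pytest.mark.parametrize(
        "col,raw,merged",
        [
            ("thz_class", "T8", "T7"),  # boreal pooled into the cold class
            ("thz_class", "T9", "T7"),
            ("mst_class", "M7", "M6"),
            ("mst_class", "M1", "M2"),
            ("thz_class", "T3", "T3"),  # interior levels unchanged
        ],
    )
    def test_default_merges(self, col, raw, merged):
        t = tiny_table(**{col: [raw]})
        out, _ = merge_classes(t)
        assert out.loc[0, col] == merged

    def test_unmapped_code_errors(self):
        t = tiny_table(thz_class=["T99"])
        with pytest.raises(ValueError, match="T99"):
            merge_classes(t)

    def test_custom_map(self):
        t = tiny_table(thz_class=["A"], mst_class=["B"])
        cmap = ClassMergeMap(thermal={"A": "T1"}, moisture={"B": "M2"})
        out, _ = merge_classes(t, cmap)
        assert out.loc[0, "thz_class"] == "T1"


class TestFullLedger:
    def test_order_and_telescoping_on_generated_landscape(self, landscape, preprocessed):
        table, report = preprocessed
        assert report.check_telescoping()
        assert report.rows_in == len(landscape)
        assert report.rows_out == len(table)
        steps = [s["step"] for s in report.steps]
        assert steps.index("area_filter") < steps.index("forward_fill")
        assert steps.index("trim_n_fert") < steps.index("trim_n_total")
        assert steps[-1] == "merge_classes"

    def test_output_is_fully_observed_and_merged(self, preprocessed):
        table, _ = preprocessed
        for col in ("n_total", "pesticides", "mechanized", "thz_class"):
            assert table[col].notna().all()
        assert set(table["thz_class"]) <= {f"T{i}" for i in range(1, 8)}
        assert set(table["mst_class"]) <= {f"M{i}" for i in range(2, 7)}

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_ledger_telescopes_for_any_seed(self, seed):
        table = generate_landscape(
            default_config(seed=seed, n_rows=12, n_cols=12, crops=("corn",))
        )
        try:
            _, report = preprocess(table)
        except ValueError:
            return  # tiny tables may lose a whole column; the error is the contract
        assert report.check_telescoping()


class TestGvif:
    def test_independent_predictors_give_unit_gvif(self):
        # exactly orthogonal columns by construction
        n = 64
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        t = pd.DataFrame({"a": x1, "b": x2})
        out = compute_gvif(t, ["a", "b"])
        assert out["gvif"].to_numpy() == pytest.approx([1.0, 1.0], abs=1e-12)

    def test_duplicated_predictor_flagged_singular(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        t = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
        out = compute_gvif(t, ["a", "b", "c"])
        assert np.isinf(out.loc["a", "gvif"])
        assert out.loc["a", "flag_10"]

    def test_correlation_0_8_gives_known_vif(self):
        # force sample correlation to 0.8, then GVIF = 1/(1-r^2) = 2.7778
        rng = np.random.default_rng(2)
        x = rng.normal(size=5000)
        z = rng.normal(size=5000)
        r = 0.8
        y = r * x + np.sqrt(1 - r**2) * z
        # orthogonalize to the exact target correlation
        x = (x - x.mean()) / x.std()
        y = (y - y.mean()) / y.std()
        y = r * x + np.sqrt(1 - r**2) * _residualize(y, x)
        t = pd.DataFrame({"a": x, "b": y})
        out = compute_gvif(t, ["a", "b"])
        assert out.loc["a", "gvif"] == pytest.approx(1 / (1 - r**2), rel=1e-9)

    def test_single_df_squared_adj_equals_gvif(self, preprocessed):
        table, _ = preprocessed
        out = compute_gvif(table, ["n_total", "pesticides", "thz_class"])
        for pred in ("n_total", "pesticides"):
            assert out.loc[pred, "df"] == 1
            assert out.loc[pred, "gvif_adj_sq"] == pytest.approx(out.loc[pred, "gvif"])
        assert out.loc["thz_class", "df"] > 1

    def test_gvif_at_least_one(self, preprocessed):
        table, _ = preprocessed
        out = compute_gvif(
            table,
            ["n_total", "pesticides", "irrigation_tot", "mechanized",
             "thz_class", "mst_class", "soil_class"],
        )
        assert (out["gvif"] >= 1 - 1e-9).all()

    def test_constant_predictor_rejected(self):
        t = pd.DataFrame({"a": np.ones(10), "b": np.arange(10.0)})
        with pytest.raises(ValueError, match="constant"):
            compute_gvif(t, ["a", "b"])

    def test_matches_auxiliary_regression_oracle_on_random_designs(self):
        """All-continuous GVIF == 1/(1-R^2) from regressing each column
        on the others, over 50 random small designs, to 1e-8."""
        rng = np.random.default_rng(77)
        for _ in range(50):
            n = int(rng.integers(30, 80))
            p = int(rng.integers(2, 5))
            X = rng.normal(size=(n, p))
            # induce mild collinearity half the time
            if rng.random() < 0.5:
                X[:, 0] += 0.7 * X[:, 1]
            t = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
            out = compute_gvif(t, list(t.columns))
            for j, col in enumerate(t.columns):
                others = np.column_stack(
                    [np.ones(n), np.delete(X, j, axis=1)]
                )
                beta, *_ = np.linalg.lstsq(others, X[:, j], rcond=None)
                resid = X[:, j] - others @ beta
                ss_tot = ((X[:, j] - X[:, j].mean()) ** 2).sum()
                r2 = 1 - (resid**2).sum() / ss_tot
                assert out.loc[col, "gvif"] == pytest.approx(1 / (1 - r2), abs=1e-8, rel=1e-8)


def _residualize(y, x):
    b = np.dot(x, y) / np.dot(x, x)
    r = y - b * x
    return r / r.std()
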