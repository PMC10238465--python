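import numpy as np
import pandas as pd
import pytest

from forestcarbon import upscaling
from forestcarbon.errors import ConfigurationError, ValidationError


def make_pairs(n=200, seed=0, response=None):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "mat": rng.uniform(-8, 16, n),
        "map": rng.uniform(300, 1300, n),
        "stand_age": rng.uniform(5, 50, n),
        "lon": rng.uniform(107, 133, n),
        "lat": rng.uniform(34, 52, n),
        "species": rng.choice(["A", "B", "C"], n),
    })
    if response is None:
        response = 0.1 * df["stand_age"] + 0.002 * df["map"] - 0.05 * df["mat"]
    df["delta_biomass"] = response
    return df


class TestSplit:
    def test_eighty_twenty(self):
        train, val = upscaling.split_train_validation(10, 0.8, seed=0)
        assert len(train) == 8 and len(val) == 2
        assert len(np.intersect1d(train, val)) == 0
        assert sorted(np.concatenate([train, val]).tolist()) == list(range(10))

    def test_reproducible(self):
        a = upscaling.split_train_validation(50, 0.8, seed=7)
        b = upscaling.split_train_validation(50, 0.8, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_degenerate_fractions_rejected(self):
        with pytest.raises(ConfigurationError):
            upscaling.split_train_validation(20, 1.0, seed=0)
        with pytest.raises(ValidationError):
            upscaling.split_train_validation(5, 0.8, seed=0)


class TestModelTree:
    def test_constant_response_single_leaf(self):
        df = make_pairs(50, response=pd.Series(np.full(50, 3.0)))
        spec = upscaling.FeatureSpec(("A", "B", "C"))
        tree = upscaling.ModelTree.fit(spec.matrix(df), df["delta_biomass"].to_numpy(), spec)
        assert tree.first_split is None
        assert np.allclose(tree.predict(spec.matrix(df)), 3.0)

    def test_step_function_split_located(self):
        """A clean step in MAT at 4 deg C is found by the first split, and the
        chosen threshold matches an exhaustive single-split search."""
        mats = np.linspace(-8, 16, 200)
        df = pd.DataFrame({"mat": mats, "map": 500.0, "stand_age": 20.0,
                           "lon": 110.0, "lat": 40.0, "species": "A"})
        y = np.where(mats > 4.0, 5.0, 1.0)
        spec = upscaling.FeatureSpec(("A",))
        X = spec.matrix(df)
        tree = upscaling.ModelTree.fit(X, y, spec, min_leaf=10, max_depth=4)
        feat, thr = tree.first_split
        assert spec.names[feat] == "mat"
        grid_step = mats[1] - mats[0]
        assert abs(thr - 4.0) <= grid_step
        # exhaustive oracle: best single split on MAT by SSE reduction
        best_sse, best_thr = np.inf, None
        for k in range(1, len(mats)):
            t = (mats[k - 1] + mats[k]) / 2
            left, right = y[mats <= t], y[mats > t]
            sse = ((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum()
            if sse < best_sse - 1e-12:
                best_sse, best_thr = sse, t
        assert thr == pytest.approx(best_thr, abs=grid_step)
        from sklearn.metrics import r2_score
        assert r2_score(y, tree.predict(X)) >= 0.99

    def test_too_few_samples_single_leaf(self):
        df = make_pairs(15)
        spec = upscaling.FeatureSpec(("A", "B", "C"))
        tree = upscaling.ModelTree.fit(
            spec.matrix(df), df["delta_biomass"].to_numpy(), spec, min_leaf=10
        )
        assert tree.first_split is None


class TestEnsemble:
    def test_all_candidates_retained_when_counts_match(self):
        model = upscaling.train_ensemble(make_pairs(), n_candidates=20, n_keep=20, seed=0)
        assert len(model.members) == 20

    def test_noiseless_linear_response_recovered(self):
        model = upscaling.train_ensemble(make_pairs(500), n_candidates=40, seed=1)
        assert model.validation_r2 >= 0.95

    def test_same_seed_identical_scores(self):
        a = upscaling.train_ensemble(make_pairs(), n_candidates=25, seed=5)
        b = upscaling.train_ensemble(make_pairs(), n_candidates=25, seed=5)
        assert np.array_equal(a.member_scores, b.member_scores)
        assert np.array_equal(a.train_index, b.train_index)

    def test_too_few_candidates_rejected(self):
        with pytest.raises(ConfigurationError):
            upscaling.train_ensemble(make_pairs(), n_candidates=5, n_keep=20)

    def test_oob_selection_mode(self):
        model = upscaling.train_ensemble(
            make_pairs(300), n_candidates=25, seed=2, selection="oob"
        )
        assert len(model.members) == 20

    def test_median_robust_to_outlier_member(self):
        assert np.median([1.0, 2.0, 100.0]) == 2.0

    def test_member_permutation_invariance(self):
        model = upscaling.train_ensemble(make_pairs(300), n_candidates=25, seed=3)
        grid = make_pairs(40, seed=9).assign(mask=True)
        p1 = upscaling.predict_grid(model, grid)
        model.members = model.members[::-1]
        p2 = upscaling.predict_grid(model, grid)
        assert np.allclose(p1, p2, equal_nan=True)


class TestPredictGrid:
    def test_unmasked_cells_missing(self):
        model = upscaling.train_ensemble(make_pairs(300), n_candidates=25, seed=4)
        grid = make_pairs(30, seed=8)
        grid["mask"] = [True] * 15 + [False] * 15
        pred = upscaling.predict_grid(model, grid)
        assert pred.iloc[:15].notna().all()
        assert pred.iloc[15:].isna().all()

    def test_incomplete_predictor_cell_missing(self):
        model = upscaling.train_ensemble(make_pairs(300), n_candidates=25, seed=4)
        grid = make_pairs(10, seed=8).assign(mask=True)
        grid.loc[3, "mat"] = np.nan
        pred = upscaling.predict_grid(model, grid)
        assert np.isnan(pred.iloc[3]) and pred.drop(3).notna().all()

    def test_empty_mask_warns_and_returns_empty(self):
        model = upscaling.train_ensemble(make_pairs(300), n_candidates=25, seed=4)
        grid = make_pairs(10, seed=8).assign(mask=False)
        assert upscaling.predict_grid(model, grid).isna().all()


class TestAggregateTotals:
    def x_and_area(self):
        x = pd.DataFrame({
            "province": ["p1", "p1"], "species": ["A", "B"],
            "x_kg_m2": [2.0, 3.0], "n_cells": [5, 5],
        })
        area = pd.DataFrame({
            "province": ["p1", "p1"], "species": ["A", "B"],
            "area_km2": [1.0, 2.0],
        })
        return x, area

    def test_unit_conversion_oracle(self):
        # 2 kg/m2 * 1 km2 + 3 kg/m2 * 2 km2 = 8e6 kg = 0.008 Tg
        x, area = self.x_and_area()
        out = upscaling.aggregate_totals(x, area)
        total = out.loc[out["group"] == "Total", "biomass_total_tg"].iloc[0]
        assert total == pytest.approx(0.008)

    def test_linearity_in_area(self):
        x, area = self.x_and_area()
        t1 = upscaling.aggregate_totals(x, area)
        t2 = upscaling.aggregate_totals(x, area.assign(area_km2=area["area_km2"] * 2))
        assert (t2.loc[t2["group"] == "Total", "biomass_total_tg"].iloc[0]
                == pytest.approx(2 * t1.loc[t1["group"] == "Total", "biomass_total_tg"].iloc[0]))

    def test_other_group_takes_mean_of_majors(self):
        x = pd.DataFrame({
            "province": ["p1"] * 5,
            "species": list(upscaling.MAJOR_SPECIES),
            "x_kg_m2": [4.0] * 5,
            "n_cells": [1] * 5,
        })
        area = pd.DataFrame({
            "province": ["p1"] * 6,
            "species": list(upscaling.MAJOR_SPECIES) + ["other"],
            "area_km2": [10.0] * 6,
        })
        out = upscaling.aggregate_totals(x, area).set_index("group")
        assert out.loc["other", "delta_biomass_density"] == pytest.approx(4.0)

    def test_average_density_times_area_is_grand_total(self):
        x, area = self.x_and_area()
        out = upscaling.aggregate_totals(x, area).set_index("group")
        avg = out.loc["Average", "delta_biomass_density"]
        area_total = out.loc["Total", "area_km2"]
        assert avg * area_total * upscaling.KG_M2_KM2_TO_TG == pytest.approx(
            out.loc["Total", "biomass_total_tg"]
        )

    def test_negative_area_rejected(self):
        x, area = self.x_and_area()
        with pytest.raises(ValidationError):
            upscaling.aggregate_totals(x, area.assign(area_km2=[-1.0, 2.0]))


class TestUncertainty:
    def test_se_convention_hand_case(self):
        # totals {10, 12}: sample sd = sqrt(2), SE = sd/sqrt(2) = 1.0
        totals = np.array([10.0, 12.0])
        se = np.std(totals, ddof=1) / np.sqrt(len(totals))
        assert se == pytest.approx(1.0)

    def test_single_repeat_rejected(self):
        with pytest.raises(ValidationError):
            upscaling.ensemble_uncertainty(
                make_pairs(), make_pairs(10).assign(mask=True, province="p1"),
                pd.DataFrame({"province": ["p1"], "species": ["A"], "area_km2": [1.0]}),
                n_repeats=1,
            )

    def test_repeats_produce_finite_ses(self):
        pairs = make_pairs(200, seed=6)
        grid = make_pairs(60, seed=7).assign(mask=True)
        grid["province"] = np.where(grid["lon"] < 120, "p1", "p2")
        area = (
            grid.groupby(["province", "species"], as_index=False).size()
            .rename(columns={"size": "area_km2"})
        )
        out = upscaling.ensemble_uncertainty(
            pairs, grid, area, n_repeats=3, base_seed=0, n_candidates=22
        )
        total = out.set_index("group").loc["Total"]
        assert total["biomass_total_tg_se"] >= 0
        assert np.isfinite(total["biomass_total_tg"])


class TestReportHelpers:
    def test_headline_rates_arithmetic(self):
        rates = upscaling.headline_rates(900.0, 675.0, 30.0,
                                         {"sink": 0.3})
        assert rates["annual_rate_tg_yr"] == pytest.approx(30.0)
        assert rates["biomass_share_pct"] == pytest.approx(75.0)
        assert rates["pct_of_sink"] == pytest.approx(10.0)

    def test_implied_area_units(self):
        # 100 Tg at 2 kg/m2 -> 5e10 m2 = 50,000 km2
        assert upscaling.implied_area_km2(100.0, 2.0) == pytest.approx(50_000.0)
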