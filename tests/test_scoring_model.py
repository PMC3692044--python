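import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm_api

from mirtarget import DataError
from mirtarget import scoring_model as sm
from mirtarget.synthetic_fixtures import (
    demo_true_model,
    gen_repression_dataset,
    noise_sd_for_r2,
)


def fv(values, level="site"):
    return sm.FeatureVector(values=dict(values), level=level)


class TestAggregatePair:
    def test_single_site_is_identity_plus_count(self):
        site = fv({"dg_duplex": -8.0, "au_content": 0.5, "bls": 1.2})
        pair = sm.aggregate_pair([site], {"prob_exact": 0.2})
        assert pair.level == "pair"
        assert pair.values["dg_duplex"] == -8.0
        assert pair.values["site_count"] == 1.0
        assert pair.values["prob_exact"] == 0.2

    def test_two_identical_sites_double_energies(self):
        site = fv({"dg_duplex": -8.0, "dg_open": 2.0})
        pair = sm.aggregate_pair([site, site])
        assert pair.values["dg_duplex"] == -16.0
        assert pair.values["dg_open"] == 4.0
        assert pair.values["site_count"] == 2.0

    def test_mixed_availability_sums_available_values(self):
        with_cons = fv({"dg_duplex": -5.0, "bls": 1.0})
        without = fv({"dg_duplex": -3.0, "bls": float("nan")})
        pair = sm.aggregate_pair([with_cons, without])
        assert pair.values["dg_duplex"] == -8.0
        assert pair.values["bls"] == 1.0  # only the available value

    def test_empty_list_rejected(self):
        with pytest.raises(DataError):
            sm.aggregate_pair([])


class TestFit:
    def make_design(self, n, rng):
        return pd.DataFrame(
            {
                "dg_total": rng.uniform(-20, 0, n),
                "au_content": rng.uniform(0, 1, n),
                "bls": rng.uniform(0, 4, n),
            }
        )

    def test_exact_interpolation_with_zero_noise(self):
        rng = np.random.default_rng(0)
        X = self.make_design(50, rng)
        beta = {"dg_total": 0.03, "au_content": -0.5, "bls": -0.1}
        y = -0.2 + sum(X[k] * v for k, v in beta.items())
        model = sm.fit(X, y)
        assert model.intercept == pytest.approx(-0.2, abs=1e-9)
        for k, v in beta.items():
            assert model.coefficients[k] == pytest.approx(v, abs=1e-9)
        assert model.training_r2 == pytest.approx(1.0, abs=1e-12)

    def test_matches_independent_ols_implementation(self):
        rng = np.random.default_rng(1)
        X = self.make_design(200, rng)
        y = rng.normal(size=200)
        model = sm.fit(X, y)
        ref = sm_api.OLS(y, sm_api.add_constant(X.to_numpy())).fit()
        assert model.intercept == pytest.approx(ref.params[0], abs=1e-8)
        assert list(model.coefficients.values()) == pytest.approx(
            list(ref.params[1:]), abs=1e-8
        )
        assert model.training_r2 == pytest.approx(ref.rsquared, abs=1e-10)

    def test_orthogonal_response_has_near_zero_r2(self):
        rng = np.random.default_rng(2)
        X = self.make_design(2000, rng)
        y = rng.normal(size=2000)
        assert sm.fit(X, y).training_r2 < 0.01

    def test_constant_column_named_in_rank_error(self):
        rng = np.random.default_rng(3)
        X = self.make_design(50, rng)
        X["dead_feature"] = 1.0
        X = X.rename(columns={"dead_feature": "site_count"})
        with pytest.raises(DataError, match="site_count"):
            sm.fit(X, rng.normal(size=50))

    def test_residuals_orthogonal_to_features(self):
        rng = np.random.default_rng(4)
        X = self.make_design(300, rng)
        y = rng.normal(size=300)
        model = sm.fit(X, y)
        resid = y - np.array(
            [sm.predict(model, dict(row)) for _, row in X.iterrows()]
        )
        for col in X.columns:
            assert abs(np.dot(resid, X[col])) < 1e-8 * len(y)

    def test_coefficient_recovery_within_confidence_intervals(self):
        """With data generated at R^2 = 0.15, each true coefficient falls
        inside its 95% CI in at least 90% of seeded replicates."""
        true = demo_true_model()
        sigma = noise_sd_for_r2(true, 0.15)
        names = list(true.coefficients)
        hits = {k: 0 for k in names}
        n_rep = 60
        for rep in range(n_rep):
            X, y = gen_repression_dataset(true, 2000, sigma, seed=1000 + rep)
            ref = sm_api.OLS(y, sm_api.add_constant(X.to_numpy())).fit()
            lo, hi = ref.conf_int(alpha=0.05)[1:, 0], ref.conf_int(alpha=0.05)[1:, 1]
            for i, k in enumerate(X.columns):
                if lo[i] <= true.coefficients[k] <= hi[i]:
                    hits[k] += 1
        for k in names:
            assert hits[k] / n_rep >= 0.90, (k, hits[k] / n_rep)


class TestPredict:
    MODEL = sm.LinearModel(intercept=-0.3, coefficients={"dg_total": 0.02, "bls": -0.1})

    def test_all_zero_features_give_intercept(self):
        assert sm.predict(self.MODEL, {"dg_total": 0.0, "bls": 0.0}) == -0.3

    def test_exact_linearity(self):
        base = {"dg_total": -5.0, "bls": 2.0}
        s0 = sm.predict(self.MODEL, base)
        s1 = sm.predict(self.MODEL, {**base, "dg_total": -4.0})
        assert s1 - s0 == pytest.approx(0.02, abs=1e-12)

    def test_missing_feature_listed_in_error(self):
        with pytest.raises(DataError, match="bls"):
            sm.predict(self.MODEL, {"dg_total": 0.0})

    def test_training_round_trip_reproduces_rss(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"dg_total": rng.uniform(-20, 0, 100),
                          "bls": rng.uniform(0, 4, 100)})
        y = rng.normal(size=100)
        model = sm.fit(X, y)
        pred = np.array([sm.predict(model, dict(row)) for _, row in X.iterrows()])
        rss = np.sum((y - pred) ** 2)
        tss = np.sum((y - y.mean()) ** 2)
        assert 1 - rss / tss == pytest.approx(model.training_r2, abs=1e-10)


class TestPercentileTransform:
    BG = [-10.0, -5.0, -1.0]  # kcal/mol style background

    def test_worked_three_point_example(self):
        assert sm.percentile_transform(self.BG, -5.0, "dg_total") == 50.0

    def test_strongest_extreme_maps_to_100(self):
        assert sm.percentile_transform(self.BG, -10.0, "dg_total") == 100.0

    def test_weakest_extreme_maps_to_0(self):
        assert sm.percentile_transform(self.BG, -1.0, "dg_total") == 0.0

    def test_orientation_flips_for_higher_is_stronger(self):
        bg = [0.0, 1.0, 2.0]
        assert sm.percentile_transform(bg, 2.0, "bls") == 100.0
        assert sm.percentile_transform(bg, 0.0, "bls") == 0.0

    def test_ties_receive_averaged_rank(self):
        bg = [1.0, 2.0, 2.0, 3.0]
        # value 2 ties two background points: rank (1 + (2+1)/2) = 2.5
        assert sm.percentile_transform(bg, 2.0, "bls") == pytest.approx(50.0)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(7)
        bg = rng.normal(size=200)
        values = np.sort(rng.normal(size=50))
        pcts = [sm.percentile_transform(bg, v, "bls") for v in values]
        assert all(0 <= p <= 100 for p in pcts)
        assert all(a <= b + 1e-12 for a, b in zip(pcts, pcts[1:]))

    def test_unregistered_feature_rejected(self):
        with pytest.raises(DataError):
            sm.percentile_transform(self.BG, 0.0, "not_a_feature")

    def test_empty_background_rejected(self):
        with pytest.raises(DataError):
            sm.percentile_transform([], 0.0, "bls")


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path):
        model = sm.LinearModel(
            intercept=0.125, coefficients={"dg_total": 0.03, "bls": -0.5},
            training_r2=0.2, label="unit test",
        )
        path = tmp_path / "model.txt"
        sm.save_model(model, path)
        back = sm.load_model(path)
        assert back.intercept == model.intercept
        assert back.coefficients == model.coefficients
        assert back.training_r2 == model.training_r2

    def test_shipped_demo_models_load_and_are_labeled_synthetic(self):
        for name in ("full", "no_conservation"):
            model = sm.load_model(name=name)
            assert "synthetic" in model.label
            assert model.coefficients
            assert 0.0 <= model.training_r2 <= 1.0
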