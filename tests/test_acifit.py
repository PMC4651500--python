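"""A-Ci curve fitting: starting values, recovery, options, batch mode."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from leafgas import (BiochemParams, FvCBEstimator, coef_table, fit_aci,
                     fit_aci_fixed_transition, fit_acis_batch,
                     make_aci_curve)
from leafgas.acifit import FittingError, estimate_starting_values


@pytest.fixture
def clean_curve(fig_params):
    df, truth = make_aci_curve(fig_params)
    return df, truth


class TestStartingValues:
    def test_within_factor_two_of_truth(self):
        truth = BiochemParams(vcmax25=50.0, jmax25=100.0, rd25=1.5)
        df, _ = make_aci_curve(truth)
        v0, j0, r0 = estimate_starting_values(df)
        assert 25.0 < v0 < 100.0
        assert 50.0 < j0 < 200.0
        assert r0 > 0

    def test_insufficient_points_rejected(self):
        df = pd.DataFrame({"Photo": [1.0, 2.0], "Ci": [100.0, 300.0]})
        with pytest.raises(FittingError):
            estimate_starting_values(df)

    def test_inversion_scales_with_assimilation(self):
        truth = BiochemParams(vcmax25=50.0, jmax25=100.0, rd25=1.5)
        df, _ = make_aci_curve(truth)
        v0, j0, _ = estimate_starting_values(df)
        df2 = df.copy()
        df2["Photo"] = 2.0 * df2["Photo"]
        v2, j2, _ = estimate_starting_values(df2)
        assert v2 / v0 == pytest.approx(2.0, rel=0.3)
        assert j2 / j0 == pytest.approx(2.0, rel=0.3)


class TestFitAci:
    def test_noiseless_recovery(self, clean_curve):
        df, truth = clean_curve
        r = fit_aci(df)
        assert r.estimates["vcmax"] == pytest.approx(truth.vcmax25,
                                                     rel=1e-3)
        assert r.estimates["jmax"] == pytest.approx(truth.jmax25, rel=1e-3)
        assert r.estimates["rd"] == pytest.approx(truth.rd25, rel=1e-3)
        assert r.r_squared > 0.9999
        assert r.converged

    def test_fitted_values_reproduce_model(self, clean_curve):
        df, _ = clean_curve
        r = fit_aci(df)
        est = FvCBEstimator().fit(df, df["Photo"])
        np.testing.assert_allclose(est.predict(df), r.fitted_an, atol=1e-10)

    def test_fixed_rd_passthrough(self, clean_curve):
        df, truth = clean_curve
        r = fit_aci(df, rd_fixed=truth.rd25)
        assert r.estimates["rd"] == truth.rd25
        assert r.standard_errors["rd"] == 0.0
        assert r.estimates["vcmax"] == pytest.approx(truth.vcmax25,
                                                     rel=1e-3)
        assert r.estimates["jmax"] == pytest.approx(truth.jmax25, rel=1e-3)

    def test_negative_fixed_rd_rejected(self, clean_curve):
        df, _ = clean_curve
        with pytest.raises(Exception):
            fit_aci(df, rd_fixed=-1.0)

    def test_gm_aware_recovery(self):
        truth = BiochemParams(vcmax25=60.0, jmax25=120.0, rd25=1.2, gm=0.2)
        df, _ = make_aci_curve(truth)
        r = fit_aci(df, gm=0.2)
        assert r.estimates["vcmax"] == pytest.approx(60.0, rel=5e-3)
        assert r.estimates["jmax"] == pytest.approx(120.0, rel=5e-3)

    def test_transition_point_located(self, clean_curve):
        df, _ = clean_curve
        r = fit_aci(df)
        assert 300.0 < r.ci_transition < 1200.0

    def test_local_optimum_against_perturbations(self, clean_curve, rng):
        df, truth = clean_curve
        noisy = df.copy()
        noisy["Photo"] = noisy["Photo"] + rng.normal(0, 0.5, len(noisy))
        r = fit_aci(noisy)
        est = FvCBEstimator()
        _, y = noisy, noisy["Photo"].to_numpy()
        dfv, yv = est._validate(noisy, y)
        _, expand, resid = est._residual_fn(dfv, yv, est._base())
        theta_hat = np.array([r.estimates["vcmax"], r.estimates["jmax"],
                              r.estimates["rd"]])
        for _ in range(100):
            pert = theta_hat * (1.0 + rng.uniform(-0.1, 0.1, 3))
            ssr = float(np.sum(resid(pert) ** 2))
            assert r.ssr <= ssr + 1e-9

    def test_r_squared_is_squared_pearson(self, clean_curve, rng):
        df, _ = clean_curve
        noisy = df.copy()
        noisy["Photo"] = noisy["Photo"] + rng.normal(0, 0.4, len(noisy))
        r = fit_aci(noisy)
        expect = np.corrcoef(noisy["Photo"], r.fitted_an)[0, 1] ** 2
        assert r.r_squared == pytest.approx(expect, rel=1e-12)

    def test_too_few_observations(self):
        df = pd.DataFrame({"Photo": [1.0, 5.0, 8.0],
                           "Ci": [100.0, 400.0, 900.0]})
        with pytest.raises(FittingError):
            fit_aci(df)

    def test_degenerate_ci_rejected(self):
        df = pd.DataFrame({"Photo": np.arange(6.0),
                           "Ci": np.full(6, 300.0)})
        with pytest.raises(FittingError):
            fit_aci(df)


class TestSklearnProtocol:
    def test_get_set_params_and_clone(self):
        est = FvCBEstimator(rd_fixed=1.0, gm=0.3)
        assert est.get_params()["gm"] == 0.3
        est2 = clone(est).set_params(gm=0.5)
        assert est2.gm == 0.5 and est2.rd_fixed == 1.0

    def test_fit_predict_shapes(self, clean_curve):
        df, _ = clean_curve
        est = FvCBEstimator().fit(df, df["Photo"])
        assert est.vcmax_ > 0 and est.jmax_ > 0
        pred = est.predict(df)
        assert pred.shape == (len(df),)
        assert est.score(df, df["Photo"]) > 0.999


class TestFixedTransition:
    def test_consistency_with_free_fit(self, clean_curve):
        df, _ = clean_curve
        free = fit_aci(df)
        fixed = fit_aci_fixed_transition(df, free.ci_transition)
        assert fixed.estimates["vcmax"] == \
            pytest.approx(free.estimates["vcmax"], rel=0.01)
        assert fixed.estimates["jmax"] == \
            pytest.approx(free.estimates["jmax"], rel=0.01)
        # the hard limb split absorbs the smooth-minimum blending near the
        # transition into the (small) rd term
        assert fixed.estimates["rd"] == pytest.approx(free.estimates["rd"],
                                                      abs=0.2)

    def test_ssr_minimal_near_optimal_transition(self, clean_curve):
        df, _ = clean_curve
        free = fit_aci(df)
        ssr_opt = fit_aci_fixed_transition(df, free.ci_transition).ssr
        for ct in (250.0, 400.0, 900.0, 1050.0):
            assert ssr_opt <= fit_aci_fixed_transition(df, ct).ssr + 1e-9

    def test_empty_limb_rejected(self, clean_curve):
        df, _ = clean_curve
        with pytest.raises(FittingError):
            fit_aci_fixed_transition(df, float(df["Ci"].max()))

    def test_out_of_range_transition_rejected(self, clean_curve):
        df, _ = clean_curve
        with pytest.raises(FittingError):
            fit_aci_fixed_transition(df, 5000.0)


class TestBatch:
    def _table(self):
        truths = {"a": BiochemParams(vcmax25=40.0, jmax25=80.0, rd25=1.0),
                  "b": BiochemParams(vcmax25=70.0, jmax25=140.0, rd25=2.0),
                  "c": BiochemParams(vcmax25=110.0, jmax25=180.0, rd25=0.8)}
        from leafgas import make_aci_batch
        return make_aci_batch(truths, seed=3), truths

    def test_each_group_recovers_its_truth(self):
        table, truths = self._table()
        res = fit_acis_batch(table, "Curve")
        for key, truth in truths.items():
            assert res[key].estimates["vcmax"] == \
                pytest.approx(truth.vcmax25, rel=1e-3)

    def test_degenerate_group_isolated(self):
        table, _ = self._table()
        bad = pd.DataFrame({"Curve": "zz", "Photo": np.arange(6.0),
                            "Ci": np.full(6, 250.0), "Tleaf": 25.0,
                            "PARi": 1800.0, "An_true": np.arange(6.0)})
        res = fit_acis_batch(pd.concat([table, bad], ignore_index=True),
                             "Curve")
        assert isinstance(res["zz"], FittingError)
        assert sum(not isinstance(v, FittingError)
                   for v in res.values()) == 3
        tab = coef_table(res)
        assert len(tab) == 4 and not tab.loc[
            tab.curve_id == "zz", "converged"].iloc[0]

    def test_missing_group_key(self):
        table, _ = self._table()
        with pytest.raises(FittingError):
            fit_acis_batch(table, "nope")

    def test_empty_table(self):
        with pytest.raises(FittingError):
            fit_acis_batch(pd.DataFrame(), "Curve")
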