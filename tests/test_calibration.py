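"""OLS calibration model, published fixtures, and leave-one-participant-out CV."""

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from paeecal.calibration import (
    PRINTED_BILATERAL,
    PRINTED_UNILATERAL,
    PaeeRegressor,
    SingularFitError,
    fit_paee_model,
    loocv_predict,
    bootstrap_models,
    predict_paee,
)

from conftest import normal_equations


class TestPaeeRegressor:
    def test_recovers_printed_equation_from_noiseless_records(self):
        rng = np.random.default_rng(0)
        pac = rng.uniform(0, 6000, 40)
        hr = rng.uniform(60, 150, 40)
        y = predict_paee(PRINTED_UNILATERAL, pac, hr)
        est = PaeeRegressor().fit(np.column_stack([pac, hr]), y)
        assert est.beta_pac_ == pytest.approx(PRINTED_UNILATERAL.beta_pac, rel=1e-9)
        assert est.beta_hr_ == pytest.approx(PRINTED_UNILATERAL.beta_hr, rel=1e-9)
        assert est.intercept_ == pytest.approx(PRINTED_UNILATERAL.intercept, rel=1e-9)
        assert est.see_ == pytest.approx(0.0, abs=1e-9)

    def test_four_point_toy_matches_normal_equations(self, toy_records):
        beta = normal_equations(toy_records["pac"], toy_records["hr"],
                                toy_records["criterion_paee"])
        m = fit_paee_model(toy_records)
        assert m.intercept == pytest.approx(beta[0], rel=1e-9)
        assert m.beta_pac == pytest.approx(beta[1], rel=1e-9)
        assert m.beta_hr == pytest.approx(beta[2], rel=1e-9)

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_normal_equations_on_random_instances(self, trial):
        rng = np.random.default_rng(100 + trial)
        pac = rng.uniform(0, 7000, 10)
        hr = rng.uniform(50, 160, 10)
        y = -2 + 4e-4 * pac + 0.04 * hr + rng.normal(0, 0.8, 10)
        oracle = normal_equations(pac, hr, y)
        est = PaeeRegressor().fit(np.column_stack([pac, hr]), y)
        assert np.allclose([est.intercept_, *est.coef_], oracle, rtol=1e-9, atol=1e-12)

    def test_residuals_sum_to_zero_in_sample(self, toy_records):
        est = PaeeRegressor().fit(
            toy_records[["pac", "hr"]].to_numpy(), toy_records["criterion_paee"]
        )
        pred = est.predict(toy_records[["pac", "hr"]].to_numpy())
        assert pred.mean() == pytest.approx(toy_records["criterion_paee"].mean(),
                                            rel=1e-12)

    def test_constant_hr_raises_named_singular_error(self):
        X = np.column_stack([np.linspace(0, 5000, 6), np.full(6, 90.0)])
        with pytest.raises(SingularFitError, match="hr"):
            PaeeRegressor().fit(X, np.linspace(0, 5, 6))

    def test_too_few_records_raise(self):
        X = np.array([[0, 60], [100, 70], [200, 80.0]])
        with pytest.raises(ValueError):
            PaeeRegressor().fit(X, [0.0, 1.0, 2.0])

    def test_hr_only_mode_ignores_pac(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([rng.uniform(0, 5000, 20), rng.uniform(60, 150, 20)])
        y = -1 + 0.03 * X[:, 1] + rng.normal(0, 0.1, 20)
        est = PaeeRegressor(use_pac=False).fit(X, y)
        assert est.beta_pac_ == 0.0
        X2 = X.copy()
        X2[:, 0] = 0.0
        assert np.allclose(est.predict(X), est.predict(X2))

    def test_clamp_zero_flag(self):
        est = PaeeRegressor(clamp_zero=True).fit(
            np.array([[0, 60], [1000, 95], [2000, 100], [3000, 120.0]]),
            [0.0, 1.0, 2.0, 3.0],
        )
        assert est.predict(np.array([[0.0, 1.0]])).min() >= 0.0

    def test_sklearn_contract_params_and_clone(self):
        est = PaeeRegressor(use_pac=False, clamp_zero=True)
        assert est.get_params() == {"use_pac": False, "clamp_zero": True}
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est.set_params(use_pac=True)
        assert est.use_pac is True


class TestPredictPaee:
    def test_intercept_read_off(self):
        assert predict_paee(PRINTED_UNILATERAL, 0.0, 1e-12) == pytest.approx(
            PRINTED_UNILATERAL.intercept, rel=1e-6
        )

    @pytest.mark.parametrize(
        "model, pac, hr, expected",
        [
            (PRINTED_UNILATERAL, 3353.0, 106.0, 3.627),
            (PRINTED_BILATERAL, 5235.0, 142.0, 5.243),
        ],
    )
    def test_group_mean_hand_arithmetic(self, model, pac, hr, expected):
        assert predict_paee(model, pac, hr) == pytest.approx(expected, abs=5e-4)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            predict_paee(PRINTED_UNILATERAL, -1.0, 80.0)
        with pytest.raises(ValueError):
            predict_paee(PRINTED_UNILATERAL, 100.0, 0.0)


class TestLoocv:
    def _records(self, n_participants=3, noise=0.0, seed=5):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(n_participants):
            for t in range(4):
                pac = rng.uniform(0, 6000)
                hr = rng.uniform(60, 150)
                rows.append(
                    {"participant": f"p{i}", "task": f"t{t}", "pac": pac, "hr": hr,
                     "criterion_paee": -2 + 5e-4 * pac + 0.04 * hr
                     + rng.normal(0, noise)}
                )
        return pd.DataFrame(rows)

    def test_every_prediction_is_out_of_sample_and_fold_count(self):
        rec = self._records(n_participants=5, noise=0.5)
        out = loocv_predict(rec)
        assert out["fold"].nunique() == 5
        # each participant maps to exactly one fold
        assert (out.groupby("participant")["fold"].nunique() == 1).all()

    def test_matches_per_fold_normal_equations_oracle(self):
        rec = self._records(n_participants=3, noise=0.7)
        out = loocv_predict(rec)
        for pid in rec["participant"].unique():
            train = rec[rec["participant"] != pid]
            test = out[out["participant"] == pid]
            beta = normal_equations(train["pac"], train["hr"],
                                    train["criterion_paee"])
            expected = beta[0] + beta[1] * test["pac"] + beta[2] * test["hr"]
            assert np.allclose(test["predicted_paee"], expected, rtol=1e-9)

    def test_noiseless_records_predicted_exactly(self):
        rec = self._records(n_participants=4, noise=0.0)
        out = loocv_predict(rec)
        assert np.allclose(out["predicted_paee"], out["criterion_paee"], atol=1e-9)

    def test_loocv_error_not_below_in_sample_error(self):
        rec = self._records(n_participants=8, noise=1.0, seed=9)
        m = fit_paee_model(rec)
        in_sample = rec["criterion_paee"] - predict_paee(m, rec["pac"], rec["hr"])
        out = loocv_predict(rec)
        oos = out["criterion_paee"] - out["predicted_paee"]
        assert np.mean(oos**2) >= np.mean(in_sample**2)

    def test_requires_three_participants(self):
        rec = self._records(n_participants=2)
        with pytest.raises(ValueError):
            loocv_predict(rec)

    def test_singular_fold_is_skipped_with_warning(self):
        rec = self._records(n_participants=3, noise=0.3)
        # removing p0 leaves constant HR in the training set
        rec.loc[rec["participant"] != "p0", "hr"] = 95.0
        with pytest.warns(UserWarning, match="skipped"):
            out = loocv_predict(rec)
        assert out.loc[out["participant"] == "p0", "predicted_paee"].isna().all()


def test_bootstrap_models_shapes_and_determinism():
    rng = np.random.default_rng(3)
    rows = []
    for i in range(6):
        for t in range(4):
            pac, hr = rng.uniform(0, 6000), rng.uniform(60, 150)
            rows.append({"participant": f"p{i}", "pac": pac, "hr": hr,
                         "criterion_paee": -2 + 5e-4 * pac + 0.04 * hr
                         + rng.normal(0, 0.5)})
    rec = pd.DataFrame(rows)
    a = bootstrap_models(rec, n_boot=25, seed=1)
    b = bootstrap_models(rec, n_boot=25, seed=1)
    pd.testing.assert_frame_equal(a, b)
    assert {"beta_pac", "beta_hr", "intercept"} <= set(a.columns)
    assert len(a) <= 25
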