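"""Outcome model: grouped stratified folds, L1 logistic fitting, patient
aggregation, metrics and the cross-validated results object."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from msipredict.core import NED, RECPRO, ParameterError
from msipredict.model import (
    ModelConfig,
    OutcomeModel,
    aggregate_patient,
    compute_metrics,
    fit_l1_logistic,
    l1_objective,
    make_grouped_stratified_folds,
    predict_spectra,
)


def _patient_table(n_rec=20, n_ned=11):
    ids = [f"P{i:03d}" for i in range(n_rec + n_ned)]
    return pd.DataFrame(
        {
            "patient_id": ids,
            "outcome": [RECPRO] * n_rec + [NED] * n_ned,
            "cohort": "CDDP",
            "slide": "S1",
        }
    )


class TestFolds:
    def test_31_patients_give_fold_sizes_7_6_6_6_6(self):
        plan = make_grouped_stratified_folds(_patient_table(), n_folds=5, seed=0)
        sizes = sorted(plan.assignments.value_counts().tolist(), reverse=True)
        assert sizes == [7, 6, 6, 6, 6]

    def test_train_test_patient_sets_disjoint(self):
        plan = make_grouped_stratified_folds(_patient_table(), seed=1)
        for k in range(plan.n_folds):
            assert not set(plan.test_patients(k)) & set(plan.train_patients(k))

    def test_each_fold_has_at_least_two_ned_patients(self):
        table = _patient_table()
        outcome = table.set_index("patient_id")["outcome"]
        for seed in range(10):
            plan = make_grouped_stratified_folds(table, seed=seed)
            for k in range(5):
                ned = sum(outcome[p] == NED for p in plan.test_patients(k))
                assert ned >= 2

    def test_deterministic_given_seed(self):
        a = make_grouped_stratified_folds(_patient_table(), seed=5)
        b = make_grouped_stratified_folds(_patient_table(), seed=5)
        assert a.assignments.equals(b.assignments)

    def test_fewer_patients_than_folds_rejected(self):
        with pytest.raises(ParameterError):
            make_grouped_stratified_folds(_patient_table(2, 1), n_folds=5)


class TestFitL1Logistic:
    def test_huge_lambda_shrinks_all_coefficients_to_zero(self, rng):
        X = rng.normal(size=(60, 5))
        y = (X[:, 0] + 0.5 * rng.normal(size=60) > 0).astype(int)
        coef, intercept, _ = fit_l1_logistic(X, y, l1_strength=100.0)
        assert np.all(coef == 0.0)

    def test_sign_matches_separation_direction(self, rng):
        x = np.concatenate([rng.normal(-2, 0.5, 40), rng.normal(2, 0.5, 40)])
        y = np.repeat([0, 1], 40)
        coef, _, _ = fit_l1_logistic(x[:, None], y, l1_strength=0.01)
        assert coef[0] > 0

    def test_objective_matches_grid_search_oracle(self, rng):
        x = np.concatenate([rng.normal(-1, 1, 30), rng.normal(1, 1, 20)])
        y = np.repeat([0, 1], [30, 20])
        lam = 0.5
        coef, intercept, ok = fit_l1_logistic(
            x[:, None], y, l1_strength=lam, tol=1e-8, max_iter=20000
        )
        assert ok
        fitted = l1_objective(x[:, None], y, coef, intercept, lam)
        grid_c = np.arange(-3, 3, 0.01)
        grid_b = np.arange(-3, 3, 0.01)
        best = min(
            l1_objective(x[:, None], y, np.array([c]), b, lam)
            for c in grid_c
            for b in grid_b
        )
        assert fitted <= best + 1e-3

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(10, 2))
        with pytest.raises(ParameterError):
            fit_l1_logistic(X, np.zeros(10), l1_strength=0.1)

    def test_sparsity_monotone_in_lambda(self, rng):
        X = rng.normal(size=(120, 30))
        beta = np.zeros(30)
        beta[:5] = [1.5, -1.0, 0.8, -0.6, 0.5]
        y = (X @ beta + rng.normal(0, 1, 120) > 0).astype(int)
        nnz = []
        for lam in [0.001, 0.003, 0.01, 0.03, 0.1, 0.3]:
            coef, _, _ = fit_l1_logistic(X, y, l1_strength=lam)
            nnz.append(int((coef != 0).sum()))
        assert all(a >= b for a, b in zip(nnz, nnz[1:]))


class TestPredictSpectra:
    def test_null_model_gives_half(self):
        p = predict_spectra(np.zeros(3), 0.0, np.ones((4, 3)))
        assert np.allclose(p, 0.5)

    def test_decision_boundary_gives_half(self):
        p = predict_spectra(np.array([1.0, -1.0]), 0.0, np.array([[2.0, 2.0]]))
        assert p[0] == pytest.approx(0.5)

    def test_hand_computed_two_feature_example(self):
        # z = 0.1 + 1*0.5 + 2*(-0.25) = 0.1
        p = predict_spectra(np.array([0.5, -0.25]), 0.1, np.array([[1.0, 2.0]]))
        assert p[0] == pytest.approx(1.0 / (1.0 + np.exp(-0.1)))

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            predict_spectra(np.zeros(3), 0.0, np.ones((2, 4)))


class TestAggregatePatient:
    def test_single_spectrum_high_p_ned(self):
        out = aggregate_patient([0.9], ["P1"], [NED])
        assert out.loc[0, "predicted"] == NED and out.loc[0, "majority_correct"]

    def test_probability_sums_drive_the_call(self):
        out = aggregate_patient([0.6, 0.6, 0.1], ["P1"] * 3)
        # sums: NED 1.3 vs RecPro 1.7
        assert out.loc[0, "predicted"] == RECPRO

    def test_exact_tie_falls_to_recpro(self):
        out = aggregate_patient([0.5, 0.5], ["P1"] * 2)
        assert out.loc[0, "predicted"] == RECPRO

    def test_majority_requires_strictly_more_than_half(self):
        out = aggregate_patient([0.9, 0.1], ["P1"] * 2, [NED, NED])
        assert out.loc[0, "fraction_correct"] == 0.5
        assert not out.loc[0, "majority_correct"]


class TestComputeMetrics:
    @pytest.mark.parametrize(
        "sens,spec,bacc",
        [(0.750, 0.660, 0.705), (0.517, 0.917, 0.717)],
    )
    def test_balanced_accuracy_is_mean_of_sens_spec(self, sens, spec, bacc):
        n = 1000
        y = np.array([1] * n + [0] * n)
        yhat = np.concatenate(
            [
                np.repeat([1, 0], [int(round(sens * n)), n - int(round(sens * n))]),
                np.repeat([0, 1], [int(round(spec * n)), n - int(round(spec * n))]),
            ]
        )
        m = compute_metrics(y, yhat)
        assert m["sensitivity"] == pytest.approx(sens, abs=1e-9)
        assert m["specificity"] == pytest.approx(spec, abs=1e-9)
        assert m["b.acc"] == pytest.approx(bacc, abs=5e-4)

    def test_perfect_prediction(self):
        y = np.array([1, 0, 1, 0])
        m = compute_metrics(y, y, y.astype(float))
        assert m["sensitivity"] == m["specificity"] == m["b.acc"] == m["AUC"] == 1.0

    def test_absent_class_flagged_undefined(self):
        m = compute_metrics(np.ones(4), np.ones(4))
        assert m["undefined"] and np.isnan(m["specificity"])


@pytest.fixture(scope="module")
def mini_fit(mini_features):
    model = OutcomeModel(mini_features, config=ModelConfig(n_folds=3, seed=0))
    return model.fit()


class TestOutcomeModelFit:
    def test_mean_column_is_arithmetic_mean_of_splits(self, mini_fit):
        splits = mini_fit.metrics[[c for c in mini_fit.metrics if c.startswith("split")]]
        assert np.allclose(
            mini_fit.metrics["mean"], splits.mean(axis=1), equal_nan=True
        )

    def test_balanced_accuracy_identity_on_all_rows(self, mini_fit):
        m = mini_fit.metrics
        for col in m.columns:
            for level in ("spectra", "patient"):
                sens = m.loc[(level, "sensitivity"), col]
                spec = m.loc[(level, "specificity"), col]
                assert m.loc[(level, "b.acc"), col] == pytest.approx((sens + spec) / 2)

    def test_probabilities_in_unit_interval(self, mini_fit):
        p = mini_fit.spectrum_probabilities["p_ned"]
        assert p.between(0, 1).all()

    def test_every_roi_spectrum_predicted_exactly_once(self, mini_fit, mini_features):
        n_roi = int(mini_features.obs["roi_flag"].sum())
        assert len(mini_fit.spectrum_probabilities) == n_roi

    def test_prediction_invariant_to_patient_relabeling(self, mini_features):
        res_a = OutcomeModel(mini_features, config=ModelConfig(n_folds=3, seed=0)).fit()
        renamed = dataclasses.replace(
            mini_features,
            obs=mini_features.obs.assign(
                patient_id="X" + mini_features.obs["patient_id"]
            ),
            patients=mini_features.patients.assign(
                patient_id="X" + mini_features.patients["patient_id"]
            ),
        )
        res_b = OutcomeModel(renamed, config=ModelConfig(n_folds=3, seed=0)).fit()
        assert np.allclose(
            res_a.spectrum_probabilities["p_ned"],
            res_b.spectrum_probabilities["p_ned"],
        )

    def test_restricted_mode_uses_exactly_the_requested_features(self, mini_features):
        idx = np.array([2, 5, 11, 17])
        model = OutcomeModel(
            mini_features,
            config=ModelConfig(
                feature_mode="restricted", restricted_indices=idx, n_folds=3
            ),
        )
        assert np.allclose(model.features.feature_mz, mini_features.feature_mz[idx])


class TestCoefficientStability:
    def _with_coefs(self, mini_fit, coefs):
        return dataclasses.replace(mini_fit, coefs=np.asarray(coefs, float))

    def test_feature_nonzero_in_single_split_excluded(self, mini_fit):
        coefs = np.zeros((3, mini_fit.feature_mz.size))
        coefs[0, 0] = 1.0  # one split only
        coefs[:, 1] = [0.5, 0.7, 0.0]  # two splits
        report = self._with_coefs(mini_fit, coefs).coefficient_stability(min_splits=2)
        assert list(report["feature_index"]) == [1]

    def test_mixed_signs_flagged_inconsistent(self, mini_fit):
        coefs = np.zeros((3, mini_fit.feature_mz.size))
        coefs[:, 3] = [1.0, -1.0, 0.0]
        coefs[:, 4] = [-0.2, -0.4, -0.1]
        report = self._with_coefs(mini_fit, coefs).coefficient_stability()
        by_idx = report.set_index("feature_index")
        assert not by_idx.loc[3, "sign_consistent"]
        assert by_idx.loc[4, "sign_consistent"]
        assert by_idx.loc[4, "mean_coef"] == pytest.approx(-0.7 / 3)


class TestTransferEvaluation:
    def test_self_transfer_matches_direct_prediction(self, mini_features, mini_fit):
        transfer = mini_fit.evaluate_transfer(mini_features)
        fm = transfer.model.features
        y = (fm.outcome_per_spectrum() == NED).to_numpy().astype(int)
        for k in range(mini_fit.coefs.shape[0]):
            p = predict_spectra(mini_fit.coefs[k], mini_fit.intercepts[k], fm.values)
            expected = compute_metrics(y, (p > 0.5).astype(int), p)
            got = transfer.metrics[f"split_{k + 1}"]
            assert got[("spectra", "b.acc")] == pytest.approx(expected["b.acc"])
            assert got[("spectra", "AUC")] == pytest.approx(expected["AUC"])

    def test_feature_space_mismatch_rejected(self, mini_features):
        res = OutcomeModel(mini_features, config=ModelConfig(n_folds=3)).fit()
        other = mini_features.subset_features(np.arange(10))
        with pytest.raises(ParameterError, match="feature space"):
            res.evaluate_transfer(other)
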