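"""Super Learner: out-of-fold honesty, weight fitting, stacked prediction."""

import numpy as np
import pytest
from sklearn.base import clone

from survstack import (
    LearnerSpec,
    SimulationConfig,
    SuperLearner,
    cv_risk_matrix,
    fit_sl_weights,
    fit_super_learner,
    generate_cohort,
    harrell_cindex,
    predict_stacked,
)


@pytest.fixture(scope="module")
def cohort():
    cfg = SimulationConfig(n_patients=400, n_covariates=3,
                           linear_effects=(1.0, -0.5, 0.0),
                           censoring_rate_target=0.3, seed=31)
    return generate_cohort(cfg)


def pretrained(coef):
    return LearnerSpec("pretrained_linear", {"coef": tuple(coef)})


class TestRiskMatrix:
    def test_no_fit_learner_is_fold_independent(self, cohort):
        ds, _ = cohort
        spec = pretrained((1.0, -0.5, 0.0))
        rm = cv_risk_matrix([spec], ds, V=5, seed=0)
        raw = ds.covariates @ np.array([1.0, -0.5, 0.0])
        expected = (raw - raw.mean()) / raw.std()
        np.testing.assert_allclose(rm.values[:, 0], expected, atol=1e-10)

    def test_leave_one_out_boundary_fills_all_cells(self, cohort):
        ds, _ = cohort
        tiny = ds.subset(np.arange(10))
        # a touch of ridge keeps the nine-patient Cox fits away from separation
        rm = cv_risk_matrix([LearnerSpec("cox", {"penalty": 5.0})], tiny, V=10, seed=1)
        assert not np.isnan(rm.values).any()

    def test_fold_sizes_balanced(self, cohort):
        ds, _ = cohort
        rm = cv_risk_matrix([pretrained((1.0, 0.0, 0.0))], ds, V=7, seed=2)
        sizes = np.bincount(rm.fold_assignment, minlength=7)
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == ds.n_patients

    def test_every_patient_predicted_once_per_learner(self, cohort):
        ds, _ = cohort
        specs = [LearnerSpec("cox", {}), pretrained((1.0, 0.0, 0.0))]
        rm = cv_risk_matrix(specs, ds, V=4, seed=3)
        assert rm.values.shape == (ds.n_patients, 2)
        assert np.isfinite(rm.values).all()
        assert set(rm.fold_assignment) == set(range(4))

    def test_columns_standardized(self, cohort):
        ds, _ = cohort
        rm = cv_risk_matrix([LearnerSpec("cox", {})], ds, V=5, seed=4)
        assert rm.values[:, 0].mean() == pytest.approx(0.0, abs=1e-9)
        assert rm.values[:, 0].std() == pytest.approx(1.0, abs=1e-9)

    def test_failing_learner_names_learner_and_fold(self, cohort):
        ds, _ = cohort
        bad = LearnerSpec("pretrained_linear", {"coef": (1.0,)})  # wrong length
        with pytest.raises(RuntimeError, match="fold 0"):
            cv_risk_matrix([bad], ds, V=3, seed=5)


class TestWeights:
    def test_single_column_gets_unit_weight(self, cohort):
        ds, _ = cohort
        alpha = fit_sl_weights(np.random.default_rng(0).standard_normal((400, 1)),
                               ds.times, ds.events, n_restarts=1, seed=0)
        np.testing.assert_array_equal(alpha, [1.0])

    def test_oracle_column_dominates_noise(self):
        cfg = SimulationConfig(n_patients=1500, n_covariates=2,
                               linear_effects=(1.5, 0.8), seed=40)
        ds, r = generate_cohort(cfg)
        rng = np.random.default_rng(1)
        H = np.column_stack([(r - r.mean()) / r.std(), rng.standard_normal(1500)])
        alpha = fit_sl_weights(H, ds.times, ds.events, n_restarts=5, seed=1)
        assert alpha[0] >= 0.9
        c_combined = harrell_cindex(H @ alpha, ds.times, ds.events)
        c_truth = harrell_cindex(H[:, 0], ds.times, ds.events)
        assert abs(c_combined - c_truth) < 0.005

    def test_weights_live_on_the_simplex(self, cohort):
        ds, _ = cohort
        rng = np.random.default_rng(2)
        H = rng.standard_normal((400, 4))
        alpha = fit_sl_weights(H, ds.times, ds.events, n_restarts=3, seed=2)
        assert np.all(alpha >= 0.0)
        assert alpha.sum() == pytest.approx(1.0, abs=1e-12)

    def test_duplicated_column_degeneracy(self, cohort):
        ds, r = cohort
        h = (r - r.mean()) / r.std()
        H = np.column_stack([h, h])
        alpha = fit_sl_weights(H, ds.times, ds.events, n_restarts=3, seed=3)
        c = harrell_cindex(H @ alpha, ds.times, ds.events)
        assert c == pytest.approx(harrell_cindex(h, ds.times, ds.events), abs=1e-12)

    def test_pure_noise_column_does_not_harm(self):
        cfg = SimulationConfig(n_patients=1500, n_covariates=2,
                               linear_effects=(1.5, 0.8), seed=41)
        ds, r = generate_cohort(cfg)
        rng = np.random.default_rng(4)
        h = (r - r.mean()) / r.std()
        a1 = fit_sl_weights(h[:, None], ds.times, ds.events, n_restarts=3, seed=4)
        c1 = harrell_cindex(h[:, None] @ a1, ds.times, ds.events)
        H = np.column_stack([h, rng.standard_normal(1500)])
        a2 = fit_sl_weights(H, ds.times, ds.events, n_restarts=3, seed=4)
        c2 = harrell_cindex(H @ a2, ds.times, ds.events)
        assert c2 >= c1 - 0.005

    def test_zero_columns_rejected(self, cohort):
        ds, _ = cohort
        with pytest.raises(ValueError):
            fit_sl_weights(np.empty((400, 0)), ds.times, ds.events)


class TestStackedModel:
    def test_single_cox_library_matches_plain_cox_ranking(self, cohort):
        ds, _ = cohort
        sm = fit_super_learner([LearnerSpec("cox", {})], ds, V=5, seed=0, n_restarts=2)
        np.testing.assert_array_equal(sm.weights, [1.0])
        from survstack import CoxPHLearner

        cox = CoxPHLearner().fit(ds.covariates, ds.y)
        r_stack = predict_stacked(sm, ds.covariates)
        r_cox = cox.predict(ds.covariates)
        assert np.array_equal(np.argsort(r_stack), np.argsort(r_cox))

    def test_scaling_a_base_learner_leaves_ranking_unchanged(self, cohort):
        """Column standardisation absorbs any rescaling of raw base risks."""
        ds, _ = cohort
        sm1 = fit_super_learner([pretrained((1.0, -0.5, 0.0)),
                                 pretrained((0.0, 0.0, 1.0))],
                                ds, V=4, seed=5, n_restarts=2)
        sm2 = fit_super_learner([pretrained((10.0, -5.0, 0.0)),
                                 pretrained((0.0, 0.0, 1.0))],
                                ds, V=4, seed=5, n_restarts=2)
        r1 = predict_stacked(sm1, ds.covariates)
        r2 = predict_stacked(sm2, ds.covariates)
        assert np.array_equal(np.argsort(r1), np.argsort(r2))

    def test_unit_weight_reproduces_base_ranking(self, cohort):
        ds, r = cohort
        sm = fit_super_learner([pretrained((1.0, -0.5, 0.0)),
                                pretrained((0.0, 0.0, 1.0))],
                               ds, V=4, seed=6, n_restarts=3)
        if sm.weights[0] == 1.0:
            base = sm.base_learners[0].predict(ds.covariates)
            stacked = predict_stacked(sm, ds.covariates)
            assert np.array_equal(np.argsort(stacked), np.argsort(base))


class TestSuperLearnerEstimator:
    def test_sklearn_contract_and_fit_predict(self, cohort):
        ds, _ = cohort
        specs = [LearnerSpec("cox", {}), LearnerSpec("coxnet", {"alpha": 0.5, "lam": 0.01})]
        sl = SuperLearner(specs=specs, V=3, n_restarts=2, random_state=0)
        cloned = clone(sl)
        assert cloned.get_params()["V"] == 3
        sl.fit(ds.covariates, ds.y)
        assert sl.weights_.sum() == pytest.approx(1.0)
        r = sl.predict(ds.covariates)
        assert len(r) == ds.n_patients
        assert harrell_cindex(r, ds.times, ds.events) > 0.6
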