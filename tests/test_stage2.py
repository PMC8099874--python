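from itertools import product

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from tremordx.data import AXES, INCLUDED_TASKS, TRIALS, Axis, Group, TaskLabel
from tremordx.stage2 import (
    FEATURE_DIM,
    AssessmentDecision,
    FeatureVector,
    all_feature_labels,
    assemble_features,
    classify_assessment,
    decide_patient,
    feature_index,
    feature_label,
    features_from_dataset,
    fit_naive_bayes,
    fit_qda,
    patient_prediction,
    qda_likelihood_ratio,
    qda_log_likelihood_ratio,
)


class TestFeatureIndex:
    def test_specific_example(self):
        # (trial 2, Posture1, z) -> (2-1)*18 + 2*3 + 2 = 26
        assert feature_index(2, TaskLabel.POSTURE1, Axis.Z) == 26

    def test_enumeration_oracle_covers_0_to_53(self):
        # oracle: enumerate tuples in trial-major, task, axis order
        expected = {}
        for i, (trial, task, axis) in enumerate(product(TRIALS, INCLUDED_TASKS, AXES)):
            expected[(trial, task, axis)] = i
        for key, idx in expected.items():
            assert feature_index(*key) == idx
        assert sorted(expected.values()) == list(range(FEATURE_DIM))

    def test_label_format(self):
        assert feature_label(2, TaskLabel.POSTURE1, Axis.Z) == "2-Posture1-z"
        labels = all_feature_labels()
        assert len(labels) == FEATURE_DIM
        assert labels[0] == "1-Rest1-x"
        assert labels[-1] == "3-Load2-z"

    def test_invalid_trial(self):
        with pytest.raises(ValueError):
            feature_index(4, TaskLabel.REST1, Axis.X)


class _ConstantModel:
    """Stage-1 stand-in emitting a fixed probability pair."""

    def __init__(self, p_pd=0.5):
        self.p_pd = p_pd

    def forward_batch(self, X, hints):
        out = np.empty((len(X), 2))
        out[:, 0] = self.p_pd
        out[:, 1] = 1 - self.p_pd
        return out

    def predict_proba_pd(self, X, hints):
        return np.full(len(X), self.p_pd)


class TestAssembleFeatures:
    def test_constant_model_gives_constant_features(self, easy_assessments):
        fv = assemble_features(easy_assessments[0], _ConstantModel(0.5))
        assert fv.values.shape == (FEATURE_DIM,)
        np.testing.assert_array_equal(fv.values, 0.5)

    def test_tie_rule_binary_mode(self, easy_assessments):
        fv = assemble_features(easy_assessments[0], _ConstantModel(0.5), mode="binary")
        np.testing.assert_array_equal(fv.values, 0.0)  # p == 0.5 -> 0

    def test_binary_above_half_is_one(self, easy_assessments):
        fv = assemble_features(easy_assessments[0], _ConstantModel(0.7), mode="binary")
        np.testing.assert_array_equal(fv.values, 1.0)

    def test_probabilistic_in_unit_interval(self, easy_assessments, trained_tiny_model):
        fv = assemble_features(easy_assessments[0], trained_tiny_model)
        assert ((fv.values >= 0) & (fv.values <= 1)).all()

    def test_matches_features_from_dataset(
        self, easy_assessments, easy_dataset, trained_tiny_model
    ):
        direct = assemble_features(easy_assessments[0], trained_tiny_model)
        batch = features_from_dataset(easy_dataset, trained_tiny_model)
        match = [f for f in batch if f.key == direct.key]
        assert len(match) == 1
        np.testing.assert_allclose(match[0].values, direct.values, atol=1e-12)

    def test_unknown_mode_rejected(self, easy_assessments):
        with pytest.raises(ValueError):
            assemble_features(easy_assessments[0], _ConstantModel(), mode="fuzzy")


def _random_features(rng, n_per_class=10, dim=FEATURE_DIM, shift=1.0):
    pd_rows = rng.normal(loc=shift, size=(n_per_class, dim))
    et_rows = rng.normal(loc=-shift, size=(n_per_class, dim))
    mat = np.vstack([pd_rows, et_rows])
    labels = np.array([0] * n_per_class + [1] * n_per_class)
    return mat, labels


class TestFitQda:
    def test_means_are_class_sample_means(self):
        mat, labels = _random_features(np.random.default_rng(0))
        model = fit_qda(mat, labels, shrinkage=0.1)
        np.testing.assert_allclose(model.mu_pd, mat[labels == 0].mean(axis=0))
        np.testing.assert_allclose(model.mu_et, mat[labels == 1].mean(axis=0))

    def test_shrinkage_zero_recovers_sample_covariance(self):
        # textbook covariance oracle (+ the documented eps*I ridge)
        rng = np.random.default_rng(1)
        mat, labels = _random_features(rng, n_per_class=100, dim=5)
        model = fit_qda(mat, labels, shrinkage=0.0)
        s = np.cov(mat[labels == 0], rowvar=False, ddof=1)
        eps = 1e-6 * np.diag(s).mean()
        np.testing.assert_allclose(model.sigma_pd, s + eps * np.eye(5), atol=1e-10)

    def test_identical_vectors_full_shrinkage_gives_diagonal(self):
        row = np.arange(FEATURE_DIM, dtype=float)
        mat = np.vstack([row, row, -row, -row])
        labels = np.array([0, 0, 1, 1])
        model = fit_qda(mat, labels, shrinkage=1.0)
        np.testing.assert_allclose(model.mu_pd, row)
        assert np.allclose(model.sigma_pd, np.diag(np.diag(model.sigma_pd)))
        assert np.linalg.eigvalsh(model.sigma_pd).min() > 0

    def test_positive_definite_even_underdetermined(self):
        rng = np.random.default_rng(2)
        mat, labels = _random_features(rng, n_per_class=3)  # 3 samples, 54 dims
        model = fit_qda(mat, labels, shrinkage=0.1)
        np.linalg.cholesky(model.sigma_pd)
        np.linalg.cholesky(model.sigma_et)

    def test_small_class_rejected(self):
        mat = np.zeros((3, FEATURE_DIM))
        with pytest.raises(ValueError):
            fit_qda(mat, np.array([0, 1, 1]))

    def test_easy_cohort_rest_means_separate(self, easy_dataset, trained_tiny_model):
        feats = features_from_dataset(easy_dataset, trained_tiny_model)
        model = fit_qda(feats, shrinkage=0.5)
        rest_idx = [
            feature_index(t, task, a)
            for t in TRIALS
            for task in (TaskLabel.REST1, TaskLabel.REST2)
            for a in AXES
        ]
        assert (model.mu_pd[rest_idx] > model.mu_et[rest_idx]).all()


class TestLikelihoodRatio:
    def _toy_model(self, dim=2):
        return fit_qda(
            np.vstack(
                [
                    np.eye(dim)[0] + np.random.default_rng(0).normal(0, 1e-9, (2, dim)),
                    np.random.default_rng(1).normal(0, 1e-9, (2, dim)),
                ]
            ),
            np.array([0, 0, 1, 1]),
        )

    def test_identical_densities_give_ratio_one(self):
        from tremordx.stage2 import QdaModel

        mu = np.zeros(3)
        sigma = np.eye(3)
        model = QdaModel(mu, mu.copy(), sigma, sigma.copy(), shrinkage=0.0)
        for f in np.random.default_rng(0).normal(size=(5, 3)):
            assert qda_likelihood_ratio(model, f) == pytest.approx(1.0)

    def test_closed_form_two_dim_case(self):
        # mu_PD=(1,0), mu_ET=(0,0), identity covariances, f=(1,0) -> exp(0.5)
        from tremordx.stage2 import QdaModel

        model = QdaModel(
            np.array([1.0, 0.0]),
            np.array([0.0, 0.0]),
            np.eye(2),
            np.eye(2),
            shrinkage=0.0,
        )
        assert qda_likelihood_ratio(model, np.array([1.0, 0.0])) == pytest.approx(
            np.exp(0.5), rel=1e-10
        )

    @pytest.mark.parametrize("dim", [2, 54])
    def test_density_ratio_identity_oracle(self, dim):
        rng = np.random.default_rng(7)
        n = max(60, dim + 10)
        mat = np.vstack(
            [rng.normal(0.5, 1.0, (n, dim)), rng.normal(-0.5, 1.2, (n, dim))]
        )
        labels = np.array([0] * n + [1] * n)
        model = fit_qda(mat, labels, shrinkage=0.2)
        pd_oracle = multivariate_normal(model.mu_pd, model.sigma_pd)
        et_oracle = multivariate_normal(model.mu_et, model.sigma_et)
        for f in rng.normal(size=(100, dim)):
            log_ratio = qda_log_likelihood_ratio(model, f)
            expected = pd_oracle.logpdf(f) - et_oracle.logpdf(f)
            assert log_ratio == pytest.approx(expected, rel=1e-8, abs=1e-8)

    def test_log_ratio_is_quadratic_in_f(self):
        rng = np.random.default_rng(8)
        dim = 3
        mat, labels = _random_features(rng, n_per_class=50, dim=dim)
        model = fit_qda(mat, labels, shrinkage=0.0)
        pts = rng.normal(size=(40, dim))
        vals = np.array([qda_log_likelihood_ratio(model, p) for p in pts])
        # design matrix of a full quadratic polynomial in 3 variables
        cols = [np.ones(len(pts))]
        cols += [pts[:, i] for i in range(dim)]
        cols += [pts[:, i] * pts[:, j] for i in range(dim) for j in range(i, dim)]
        design = np.column_stack(cols)
        residual = vals - design @ np.linalg.lstsq(design, vals, rcond=None)[0]
        assert np.abs(residual).max() < 1e-8

    def test_swapping_classes_inverts_ratio(self):
        rng = np.random.default_rng(9)
        mat, labels = _random_features(rng, n_per_class=30, dim=4)
        model = fit_qda(mat, labels, shrinkage=0.1)
        swapped = model.swapped()
        for f in rng.normal(size=(20, 4)):
            assert qda_log_likelihood_ratio(swapped, f) == pytest.approx(
                -qda_log_likelihood_ratio(model, f), abs=1e-9
            )

    def test_dimension_mismatch_rejected(self):
        mat, labels = _random_features(np.random.default_rng(0), dim=4)
        model = fit_qda(mat, labels)
        with pytest.raises(ValueError):
            qda_log_likelihood_ratio(model, np.zeros(5))


class TestClassifyAssessment:
    def _model(self):
        mat, labels = _random_features(np.random.default_rng(0), dim=3)
        return fit_qda(mat, labels, shrinkage=0.1)

    def test_tie_goes_to_et(self):
        from tremordx.stage2 import QdaModel

        mu = np.zeros(2)
        model = QdaModel(mu, mu.copy(), np.eye(2), np.eye(2), shrinkage=0.0)
        decision = classify_assessment(model, np.array([0.3, -0.3]), threshold=1.0)
        assert decision.log_likelihood_ratio == pytest.approx(0.0, abs=1e-12)
        assert decision.predicted is Group.ET

    def test_threshold_limits(self):
        model = self._model()
        f = np.random.default_rng(1).normal(size=3)
        assert classify_assessment(model, f, threshold=1e-300).predicted is Group.PD
        assert classify_assessment(model, f, threshold=1e300).predicted is Group.ET

    def test_predicted_matches_log_ratio_sign(self):
        model = self._model()
        for f in np.random.default_rng(2).normal(size=(20, 3)):
            d = classify_assessment(model, f)
            assert d.predicted is (Group.PD if d.log_likelihood_ratio > 0 else Group.ET)


class TestDecidePatient:
    def _decision(self, predicted):
        return AssessmentDecision(
            predicted=predicted, log_likelihood_ratio=0.0, threshold_used=1.0
        )

    def test_bilateral_both_correct(self):
        ds = [self._decision(Group.PD), self._decision(Group.PD)]
        assert decide_patient(ds, Group.PD) is True

    def test_bilateral_one_wrong(self):
        ds = [self._decision(Group.PD), self._decision(Group.ET)]
        assert decide_patient(ds, Group.PD) is False

    def test_unilateral_single_correct(self):
        assert decide_patient([self._decision(Group.ET)], Group.ET) is True

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            decide_patient([], Group.PD)

    def test_monotone_adding_wrong_never_fixes(self):
        correct = [self._decision(Group.PD)]
        assert decide_patient(correct, Group.PD)
        assert not decide_patient(correct + [self._decision(Group.ET)], Group.PD)

    def test_prediction_majority_and_tie_break(self):
        correct, pred = patient_prediction(
            [self._decision(Group.ET), self._decision(Group.ET), self._decision(Group.PD)],
            Group.ET,
        )
        assert not correct and pred is Group.ET
        correct, pred = patient_prediction(
            [self._decision(Group.PD), self._decision(Group.ET)], Group.PD
        )
        assert not correct and pred is Group.ET  # tie broken against truth


class TestNaiveBayes:
    def test_matches_full_shrinkage_qda_decisions(self):
        rng = np.random.default_rng(3)
        mat, labels = _random_features(rng, n_per_class=30, dim=6)
        nb = fit_naive_bayes(mat, labels)
        qda_diag = fit_qda(mat, labels, shrinkage=1.0)
        for f in rng.normal(size=(100, 6)):
            assert classify_assessment(nb, f).predicted is classify_assessment(
                qda_diag, f
            ).predicted
            assert qda_log_likelihood_ratio(nb, f) == pytest.approx(
                qda_log_likelihood_ratio(qda_diag, f), rel=1e-10
            )

    def test_single_feature_equals_univariate_ratio(self):
        rng = np.random.default_rng(4)
        a = rng.normal(1.0, 0.5, 50)
        b = rng.normal(-1.0, 2.0, 50)
        mat = np.r_[a, b][:, None]
        labels = np.array([0] * 50 + [1] * 50)
        nb = fit_naive_bayes(mat, labels)
        from scipy.stats import norm

        eps_a = 1e-6 * a.var(ddof=1)
        eps_b = 1e-6 * b.var(ddof=1)
        for f in rng.normal(size=5):
            expected = norm.logpdf(
                f, a.mean(), np.sqrt(a.var(ddof=1) + eps_a)
            ) - norm.logpdf(f, b.mean(), np.sqrt(b.var(ddof=1) + eps_b))
            assert qda_log_likelihood_ratio(nb, np.array([f])) == pytest.approx(
                expected, rel=1e-8
            )

    def test_identical_classes_give_ratio_one(self):
        rng = np.random.default_rng(5)
        rows = rng.normal(size=(20, 4))
        mat = np.vstack([rows, rows])
        labels = np.array([0] * 20 + [1] * 20)
        nb = fit_naive_bayes(mat, labels)
        for f in rng.normal(size=(10, 4)):
            assert qda_likelihood_ratio(nb, f) == pytest.approx(1.0, abs=1e-9)
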