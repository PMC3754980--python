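"""OPLS-DA fitting, loading-based selection, LDA, and the CV engine."""

import math

import numpy as np
import pandas as pd
import pytest

from mzmwas.containers import ValidationError
from mzmwas.panel import (
    PanelClassifier,
    PanelConfig,
    cross_validate,
    fit_lda,
    fit_opls,
    fit_pls,
    predict_lda,
    run_panel,
    scale_matrix,
    select_top_loadings,
)


def two_class_data(n_per=24, p=30, sep=3.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, size=(2 * n_per, p))
    X[:n_per, 0] += sep
    y = np.array(["case"] * n_per + ["control"] * n_per)
    return X, y


class TestOpls:
    def test_zero_orthogonal_equals_plain_pls(self):
        X, y = two_class_data(seed=1)
        cfg = PanelConfig(n_orthogonal=0, n_predictive=2)
        model = fit_opls(X, y, cfg)
        W, T, P, var = fit_pls(X, y, n_components=2)
        np.testing.assert_allclose(model.t_pred, T, atol=1e-10)
        np.testing.assert_allclose(model.p_pred, P, atol=1e-10)

    def test_scores_mutually_orthogonal(self):
        X, y = two_class_data(seed=2)
        model = fit_opls(X, y, PanelConfig(n_orthogonal=2, n_predictive=2))
        scores = np.hstack([model.t_orth, model.t_pred])
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) / np.max(np.diag(gram)) < 1e-8

    def test_variance_fractions_bounded(self):
        X, y = two_class_data(seed=3)
        model = fit_opls(X, y, PanelConfig(n_orthogonal=1, n_predictive=2))
        fractions = np.concatenate(
            [model.variance_explained_orth, model.variance_explained_pred]
        )
        assert (fractions >= 0).all()
        assert fractions.sum() <= 1 + 1e-8

    def test_recovers_planted_discriminant_direction(self):
        rng = np.random.default_rng(7)
        n, p = 60, 20
        X = rng.normal(0, 0.1, size=(n, p))
        y = np.array(["case"] * 30 + ["control"] * 30)
        X[:30, 0] += 2.0  # class difference along e1
        # strong variance along e2, centred within each class so it is
        # genuinely orthogonal to the contrast
        orth = rng.normal(0, 4.0, n)
        orth[:30] -= orth[:30].mean()
        orth[30:] -= orth[30:].mean()
        X[:, 1] += orth
        cfg = PanelConfig(n_orthogonal=1, n_predictive=1, scaling="mean_center")
        model = fit_opls(X, y, cfg)
        w = model.w_pred[:, 0]
        cos = abs(w[0]) / np.linalg.norm(w)
        assert cos >= 0.99
        # and the orthogonal component captured the planted e2 variance
        assert abs(model.w_orth[1, 0]) > 0.99

    def test_constant_feature_under_autoscale_rejected(self):
        X, y = two_class_data(seed=4)
        X[:, 5] = 2.0
        with pytest.raises(ValidationError, match="column 5"):
            fit_opls(X, y, PanelConfig())

    def test_missing_values_rejected(self):
        X, y = two_class_data(seed=5)
        X[0, 0] = np.nan
        with pytest.raises(ValidationError, match="missing"):
            fit_opls(X, y)

    def test_cross_check_against_sklearn_pls(self):
        # independent oracle: sklearn NIPALS PLS scores match up to sign
        from sklearn.cross_decomposition import PLSRegression

        X, y = two_class_data(seed=8)
        Xs, _, _ = scale_matrix(X, "autoscale")
        ycode = np.where(y == "case", 1.0, -1.0)
        W, T, P, _ = fit_pls(X, y, n_components=2)
        ref = PLSRegression(n_components=2, scale=False).fit(Xs, ycode - ycode.mean())
        for a in range(2):
            c = np.corrcoef(T[:, a], ref.x_scores_[:, a])[0, 1]
            assert abs(c) > 1 - 1e-6


class TestSelection:
    def test_fraction_one_returns_all_ranked(self):
        X, y = two_class_data(seed=9)
        model = fit_opls(X, y, PanelConfig())
        sel = select_top_loadings(model, 1.0)
        assert sorted(sel) == sorted(model.feature_names)

    def test_dominant_feature_ranks_first(self):
        X, y = two_class_data(n_per=30, p=25, sep=0.0, seed=10)
        X[:30, 7] += 5.0  # only informative feature
        y = np.array(["case"] * 30 + ["control"] * 30)
        model = fit_opls(X, y, PanelConfig(n_orthogonal=0))
        sel = select_top_loadings(model, 0.04)
        assert sel[0] == "f7"

    def test_selected_count_is_ceiling(self):
        X, y = two_class_data(n_per=10, p=1168, sep=1.0, seed=11)
        model = fit_opls(X, y, PanelConfig(n_orthogonal=0, n_predictive=1))
        sel = select_top_loadings(model, 0.05)
        assert len(sel) == math.ceil(0.05 * 1168) == 59

    def test_invalid_fraction_rejected(self):
        X, y = two_class_data(seed=12)
        model = fit_opls(X, y, PanelConfig())
        with pytest.raises(ValidationError):
            select_top_loadings(model, 1.5)


class TestLda:
    def test_well_separated_classes_near_perfect(self):
        X, y = two_class_data(n_per=40, p=5, sep=6.0, seed=13)
        model = fit_lda(X, y, shrinkage=0)
        assert np.mean(predict_lda(model, X) == y) == 1.0

    def test_single_feature_boundary_at_midpoint(self):
        rng = np.random.default_rng(14)
        x0 = rng.normal(0, 1, 200)
        x1 = rng.normal(4, 1, 200)
        X = np.concatenate([x0, x1]).reshape(-1, 1)
        y = np.array(["a"] * 200 + ["b"] * 200)
        model = fit_lda(X, y, shrinkage=0)
        mid = (x0.mean() + x1.mean()) / 2
        eps = 0.05
        assert predict_lda(model, [[mid - eps]])[0] == "a"
        assert predict_lda(model, [[mid + eps]])[0] == "b"

    def test_singular_covariance_requires_shrinkage(self):
        X, y = two_class_data(n_per=5, p=50, seed=15)
        with pytest.raises(ValidationError, match="shrinkage"):
            fit_lda(X, y, shrinkage=0)
        model = fit_lda(X, y, shrinkage="auto")  # regularized fit succeeds
        assert len(predict_lda(model, X)) == len(y)

    def test_identical_distributions_cv_near_half(self):
        X, y = two_class_data(n_per=30, p=10, sep=0.0, seed=16)
        res = cross_validate(
            X, y, lambda: PanelClassifier(PanelConfig(loading_fraction=0.5)),
            scheme="kfold10_stratified", seed=0,
        )
        # null accuracy within 3 binomial SDs of 0.5
        n = res["n_predictions"]
        assert abs(res["pooled_accuracy"] - 0.5) < 3 * math.sqrt(0.25 / n)


class TestCrossValidate:
    def test_loo_yields_n_predictions(self):
        X, y = two_class_data(n_per=23, p=8, sep=2.0, seed=17)
        y = y[:45]
        X = X[:45]
        res = cross_validate(
            X, y, lambda: PanelClassifier(PanelConfig()), scheme="loo", seed=0
        )
        assert res["n_predictions"] == 45

    def test_perfect_oracle_scores_one(self):
        class Oracle:
            def fit(self, X, y):
                self.key = {tuple(row): lab for row, lab in zip(X, y)}
                return self

            def predict(self, X):
                # class is encoded in the sign of column 0 (sep large)
                return np.where(np.asarray(X)[:, 0] > 3, "case", "control")

        X, y = two_class_data(n_per=20, p=4, sep=6.0, seed=18)
        for scheme in ("kfold10_stratified", "loo"):
            res = cross_validate(X, y, Oracle, scheme=scheme, seed=1)
            assert res["pooled_accuracy"] == 1.0

    def test_cv_accuracy_below_resubstitution_on_average(self):
        gaps = []
        for seed in range(6):
            X, y = two_class_data(n_per=12, p=40, sep=0.8, seed=seed)
            clf = PanelClassifier(PanelConfig(loading_fraction=0.2))
            clf.fit(X, y)
            resub = np.mean(clf.predict(X) == y)
            res = cross_validate(
                X, y, lambda: PanelClassifier(PanelConfig(loading_fraction=0.2)),
                scheme="kfold10_stratified", seed=seed,
            )
            gaps.append(resub - res["pooled_accuracy"])
        assert np.mean(gaps) >= 0  # optimism of training-set accuracy

    def test_feature_permutation_invariance(self):
        X, y = two_class_data(n_per=15, p=20, sep=2.0, seed=19)
        rng = np.random.default_rng(3)
        perm = rng.permutation(20)
        r1 = cross_validate(
            X, y, lambda: PanelClassifier(PanelConfig()), "kfold10_stratified", 7
        )
        r2 = cross_validate(
            X[:, perm], y, lambda: PanelClassifier(PanelConfig()),
            "kfold10_stratified", 7,
        )
        assert r1["pooled_accuracy"] == pytest.approx(r2["pooled_accuracy"])

    def test_unknown_scheme_rejected(self):
        X, y = two_class_data(seed=20)
        with pytest.raises(ValidationError):
            cross_validate(X, y, lambda: None, scheme="bootstrap", seed=0)


class TestRunPanel:
    def test_end_to_end_on_simulated_cohort(self, simulated):
        from mzmwas.mwas import presence_filter

        _, table, samples, _ = simulated
        filt = presence_filter(table, 0.5)
        cfg = PanelConfig(cv_schemes=("kfold10_stratified",), seed=0)
        rep = run_panel(filt, samples, cfg)
        assert len(rep.selected_features) == math.ceil(0.05 * filt.n_features)
        assert set(rep.selected_features) <= set(filt.feature_ids)
        assert 0 <= rep.cv_accuracy["kfold10_stratified"] <= 1
        assert rep.resubstitution_accuracy >= rep.cv_accuracy["kfold10_stratified"] - 0.1
        assert rep.scores.shape[0] == filt.n_samples
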