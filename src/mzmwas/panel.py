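"""Multivariate group separation: OPLS-DA, loading-based feature selection,
regularized LDA, and an honest cross-validation engine.

OPLS-DA first strips variation orthogonal to the class contrast
(Trygg-Wold orthogonal signal correction), then fits NIPALS PLS
components on the deflated matrix; the orthogonal/predictive variance
split is bookkept as fractions of the scaled total sum of squares.
Features are ranked by variance-weighted squared predictive loadings and
the top fraction (default 5%) forms the candidate panel, which is scored
by linear discriminant analysis with shrinkage-regularized covariance
(necessary when features outnumber samples).  Cross-validation refits
imputation, scaling, the OPLS model, the feature selection and the
classifier inside every training fold, so reported accuracies are free of
selection leakage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .containers import FeatureTable, ValidationError, group_masks, validate_samples


@dataclass
class PanelConfig:
    n_orthogonal: int = 1
    n_predictive: int = 2
    scaling: str = "autoscale"  # or "mean_center"
    loading_fraction: float = 0.05
    cv_schemes: tuple[str, ...] = ("kfold10_stratified", "loo")
    shrinkage: Union[str, float] = "auto"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_orthogonal < 0 or self.n_predictive < 1:
            raise ValidationError("need n_orthogonal >= 0 and n_predictive >= 1")
        if not (0 < self.loading_fraction <= 1):
            raise ValidationError("loading_fraction must be in (0, 1]")
        if self.scaling not in ("autoscale", "mean_center"):
            raise ValidationError(f"unknown scaling {self.scaling!r}")


@dataclass
class OplsModel:
    """Fitted OPLS-DA model on the scaled matrix."""

    center: np.ndarray
    scale: np.ndarray
    w_orth: np.ndarray  # features x n_orthogonal
    t_orth: np.ndarray  # samples x n_orthogonal
    p_orth: np.ndarray
    w_pred: np.ndarray  # features x n_predictive
    t_pred: np.ndarray
    p_pred: np.ndarray
    variance_explained_orth: np.ndarray  # fractions of scaled total SS
    variance_explained_pred: np.ndarray
    feature_names: list[str]


def scale_matrix(
    X: np.ndarray, scaling: str = "autoscale"
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-center (and unit-variance scale) a samples x features matrix."""
    center = X.mean(axis=0)
    if scaling == "autoscale":
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            j = int(np.nonzero(sd == 0)[0][0])
            raise ValidationError(
                f"feature column {j} is constant; autoscaling would divide by zero"
            )
        scale = sd
    else:
        scale = np.ones(X.shape[1])
    return (X - center) / scale, center, scale


def _nipals_pls(Xd: np.ndarray, yc: np.ndarray, n_components: int, ss_total: float):
    """PLS1 NIPALS components on an (already deflated) matrix."""
    n, p = Xd.shape
    W = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    P = np.zeros((p, n_components))
    var = np.zeros(n_components)
    X = Xd.copy()
    for a in range(n_components):
        w = X.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        t = X @ w
        tt = t @ t
        if tt == 0:
            break
        pl = X.T @ t / tt
        X -= np.outer(t, pl)
        W[:, a], T[:, a], P[:, a] = w, t, pl
        var[a] = tt * (pl @ pl) / ss_total
    return W, T, P, var, X


def fit_opls(
    X: np.ndarray,
    y: Sequence,
    config: Optional[PanelConfig] = None,
    feature_names: Optional[Sequence[str]] = None,
) -> OplsModel:
    """Fit OPLS-DA: orthogonal signal correction then NIPALS PLS.

    ``X`` is samples x features with no missing values; ``y`` is a two-level
    class code (internally centred +/-1 contrast).  With
    ``n_orthogonal = 0`` the predictive components equal plain PLS-DA on
    the scaled matrix.
    """
    config = config or PanelConfig()
    X = np.asarray(X, float)
    if np.isnan(X).any():
        raise ValidationError("X contains missing values; impute upstream")
    yv = np.asarray(y)
    classes = np.unique(yv)
    if len(classes) != 2 or min(np.sum(yv == c) for c in classes) < 2:
        raise ValidationError("need exactly two classes with >= 2 samples each")
    ycode = np.where(yv == classes[1], 1.0, -1.0)
    yc = ycode - ycode.mean()

    Xs, center, scale = scale_matrix(X, config.scaling)
    ss_total = float((Xs**2).sum())
    n, p = Xs.shape

    Wo = np.zeros((p, config.n_orthogonal))
    To = np.zeros((n, config.n_orthogonal))
    Po = np.zeros((p, config.n_orthogonal))
    var_o = np.zeros(config.n_orthogonal)
    Xd = Xs.copy()
    for a in range(config.n_orthogonal):
        w = Xd.T @ yc
        w /= np.linalg.norm(w)
        t = Xd @ w
        pl = Xd.T @ t / (t @ t)
        w_o = pl - (w @ pl) * w
        nw = np.linalg.norm(w_o)
        if nw == 0:  # no orthogonal variation left
            Wo, To, Po, var_o = Wo[:, :a], To[:, :a], Po[:, :a], var_o[:a]
            break
        w_o /= nw
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd -= np.outer(t_o, p_o)
        Wo[:, a], To[:, a], Po[:, a] = w_o, t_o, p_o
        var_o[a] = (t_o @ t_o) * (p_o @ p_o) / ss_total

    W, T, P, var_p, _ = _nipals_pls(Xd, yc, config.n_predictive, ss_total)
    return OplsModel(
        center=center,
        scale=scale,
        w_orth=Wo,
        t_orth=To,
        p_orth=Po,
        w_pred=W,
        t_pred=T,
        p_pred=P,
        variance_explained_orth=var_o,
        variance_explained_pred=var_p,
        feature_names=list(feature_names) if feature_names is not None else
        [f"f{j}" for j in range(p)],
    )


def fit_pls(
    X: np.ndarray, y: Sequence, n_components: int = 2, scaling: str = "autoscale"
):
    """Plain PLS-DA (no orthogonal correction); returns (W, T, P, var)."""
    cfg = PanelConfig(n_orthogonal=0, n_predictive=n_components, scaling=scaling)
    m = fit_opls(X, y, cfg)
    return m.w_pred, m.t_pred, m.p_pred, m.variance_explained_pred


def select_top_loadings(
    model: OplsModel,
    fraction: float = 0.05,
    mz: Optional[pd.Series] = None,
) -> list[str]:
    """Top features by variance-weighted squared predictive loading.

    Rank score for feature j is sum_a loading[j,a]^2 * variance_explained[a]
    over predictive components; ties break by m/z ascending (when given)
    then by feature name.  Returns ceil(fraction * p) features.
    """
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must be in (0, 1]")
    score = (model.p_pred**2 @ model.variance_explained_pred)
    names = model.feature_names
    if mz is not None:
        tie = [float(mz[f]) for f in names]
    else:
        tie = list(range(len(names)))
    order = sorted(
        range(len(names)), key=lambda j: (-score[j], tie[j], names[j])
    )
    n_sel = math.ceil(fraction * len(names))
    return [names[j] for j in order[:n_sel]]


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

def fit_lda(X: np.ndarray, y: Sequence, shrinkage: Union[str, float] = "auto"):
    """Two-class LDA with shrinkage-regularized pooled covariance.

    ``shrinkage`` is 'auto' (Ledoit-Wolf) or a value in [0, 1]; 0 requires
    more samples than features.
    """
    X = np.asarray(X, float)
    yv = np.asarray(y)
    classes = np.unique(yv)
    if len(classes) != 2 or min(np.sum(yv == c) for c in classes) < 2:
        raise ValidationError("need two classes with >= 2 samples each")
    if shrinkage == 0 or shrinkage == 0.0:
        if X.shape[1] >= X.shape[0]:
            raise ValidationError(
                "covariance is singular with features >= samples; "
                "use shrinkage > 0 or 'auto'"
            )
        model = LinearDiscriminantAnalysis(solver="svd")
    else:
        model = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
    model.fit(X, yv)
    return model


def predict_lda(model, X: np.ndarray) -> np.ndarray:
    return model.predict(np.asarray(X, float))


# ---------------------------------------------------------------------------
# Cross-validation engine
# ---------------------------------------------------------------------------

def _folds(scheme: str, y: np.ndarray, seed: int):
    if scheme == "loo":
        return list(LeaveOneOut().split(np.zeros_like(y), y))
    if scheme == "kfold10_stratified":
        k = min(10, int(np.min(np.bincount(pd.factorize(y)[0]))))
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        return list(cv.split(np.zeros_like(y), y))
    raise ValidationError(f"unknown CV scheme {scheme!r}")


def cross_validate(
    X: np.ndarray,
    y: Sequence,
    make_classifier: Callable[[], object],
    scheme: str = "kfold10_stratified",
    seed: int = 0,
) -> dict:
    """Per-fold and pooled accuracy of any fit/predict classifier.

    ``make_classifier()`` must return a fresh object with ``fit(X, y)`` and
    ``predict(X)``; everything the classifier learns (scaling, feature
    selection, model) must happen inside ``fit`` so no information leaks
    from test folds.  Folds whose training part lacks a class are flagged
    invalid and skipped.
    """
    X = np.asarray(X, float)
    yv = np.asarray(y)
    folds = _folds(scheme, yv, seed)
    fold_acc: list[float] = []
    invalid = 0
    predictions = np.empty(len(yv), dtype=object)
    predicted = np.zeros(len(yv), bool)
    for train, test in folds:
        if len(np.unique(yv[train])) < 2:
            invalid += 1
            continue
        clf = make_classifier()
        clf.fit(X[train], yv[train])
        pred = clf.predict(X[test])
        predictions[test] = pred
        predicted[test] = True
        fold_acc.append(float(np.mean(pred == yv[test])))
    pooled = float(np.mean(predictions[predicted] == yv[predicted])) if predicted.any() else float("nan")
    return {
        "scheme": scheme,
        "fold_accuracies": fold_acc,
        "pooled_accuracy": pooled,
        "n_predictions": int(predicted.sum()),
        "invalid_folds": invalid,
        "predictions": predictions,
    }


class PanelClassifier:
    """Self-contained pipeline: impute -> scale -> OPLS -> select -> LDA.

    All statistics (medians, centring, loadings, selection) come from the
    training data passed to ``fit``, so the object is safe to use inside
    cross-validation.
    """

    def __init__(
        self,
        config: Optional[PanelConfig] = None,
        feature_names: Optional[Sequence[str]] = None,
    ):
        self.config = config or PanelConfig()
        self.feature_names = list(feature_names) if feature_names is not None else None

    def fit(self, X: np.ndarray, y: Sequence):
        X = np.asarray(X, float)
        med = np.nanmedian(X, axis=0)
        med = np.where(np.isnan(med), 0.0, med)
        self.medians_ = med
        Xi = np.where(np.isnan(X), med, X)
        # constant columns cannot be autoscaled; drop them for this fit
        sd = Xi.std(axis=0, ddof=1)
        self.keep_ = sd > 0
        Xi = Xi[:, self.keep_]
        kept_names = (
            [n for n, k in zip(self.feature_names, self.keep_) if k]
            if self.feature_names is not None
            else None
        )
        self.model_ = fit_opls(Xi, y, self.config, feature_names=kept_names)
        names = self.model_.feature_names
        sel = select_top_loadings(self.model_, self.config.loading_fraction)
        self.sel_idx_ = np.array([names.index(s) for s in sel])
        Xsel = (Xi - self.model_.center) / self.model_.scale
        self.lda_ = fit_lda(
            Xsel[:, self.sel_idx_], y, shrinkage=self.config.shrinkage
        )
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, float)
        Xi = np.where(np.isnan(X), self.medians_, X)[:, self.keep_]
        Xsel = (Xi - self.model_.center) / self.model_.scale
        return predict_lda(self.lda_, Xsel[:, self.sel_idx_])


@dataclass
class PanelReport:
    selected_features: list[str]
    variance_explained_orth: list[float]
    variance_explained_pred: list[float]
    resubstitution_accuracy: float
    cv_accuracy: dict[str, float]
    predictions: pd.DataFrame
    scores: pd.DataFrame


def run_panel(
    table: FeatureTable, samples: pd.DataFrame, config: Optional[PanelConfig] = None
) -> PanelReport:
    """Fit the full panel-selection stage on a feature table.

    Missing intensities are median-imputed per feature (multivariate
    models need complete matrices; the univariate screen never imputes).
    """
    config = config or PanelConfig()
    validate_samples(samples)
    X = table.data.T.to_numpy(float)  # samples x features
    y = samples.loc[table.sample_ids, "group"].to_numpy()

    full = PanelClassifier(config, feature_names=table.feature_ids).fit(X, y)
    names = full.model_.feature_names
    selected = [names[j] for j in full.sel_idx_]
    resub = float(np.mean(full.predict(X) == y))

    cv_acc: dict[str, float] = {}
    preds = {}
    for scheme in config.cv_schemes:
        res = cross_validate(
            X, y, lambda: PanelClassifier(config), scheme=scheme, seed=config.seed
        )
        cv_acc[scheme] = res["pooled_accuracy"]
        preds[scheme] = res["predictions"]
    model = full.model_
    scores = pd.DataFrame(
        {
            **{
                f"t_pred{a + 1}": model.t_pred[:, a]
                for a in range(model.t_pred.shape[1])
            },
            **{
                f"t_orth{a + 1}": model.t_orth[:, a]
                for a in range(model.t_orth.shape[1])
            },
            "group": y,
        },
        index=table.sample_ids,
    )
    pred_df = pd.DataFrame(preds, index=table.sample_ids)
    return PanelReport(
        selected_features=selected,
        variance_explained_orth=[float(v) for v in model.variance_explained_orth],
        variance_explained_pred=[float(v) for v in model.variance_explained_pred],
        resubstitution_accuracy=resub,
        cv_accuracy=cv_acc,
        predictions=pred_df,
        scores=scores,
    )
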