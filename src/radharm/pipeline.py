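"""Malignancy prediction: LASSO feature selection, then a linear SVM.

Features (already restricted to the acquisition-independent set by the
caller) are z-scored with training statistics, an L1-penalized least-squares
regression of the 0/1 malignancy label (penalty ``alpha`` in the
(1/2n)·RSS + alpha·||w||_1 parameterization) selects the features with
nonzero coefficients, and a soft-margin linear SVM (hinge loss, C = 1) is
trained on the selection.  When the LASSO selects nothing the model degrades
to a constant all-benign predictor — the honest behaviour when harmonization
leaves no predictive acquisition-independent features.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import Lasso, LogisticRegression
from sklearn.svm import SVC

from .schema import SchemaError

__all__ = ["LassoSvmClassifier", "lasso_select", "train_classifier", "predict_scores"]

FALLBACK_SCORE = -1.0  # constant decision value of the all-benign fallback


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("feature matrix must be 2-D")
    return X, list(range(X.shape[1]))


class LassoSvmClassifier(BaseEstimator, ClassifierMixin):
    """LASSO-selected linear SVM for benign/malignant classification.

    Parameters
    ----------
    lasso_alpha : float, default 0.05
        L1 penalty weight of the selection regression.
    C : float, default 1.0
        SVM regularization.
    logistic_lasso : bool, default False
        Use L1-penalized logistic regression for selection instead of the
        least-squares LASSO (offered for sensitivity analyses; the default
        matches the least-squares form of the selection operator).

    Attributes
    ----------
    selected_features_ : list of column names with nonzero LASSO coefficients
    center_, scale_ : training z-scoring statistics (all input features)
    weights_, bias_ : SVM hyperplane in the standardized selected space
    fallback_ : True when nothing was selected; the decision score is then
        the constant ``FALLBACK_SCORE`` and every prediction is benign.
    """

    def __init__(self, lasso_alpha=0.05, C=1.0, logistic_lasso=False):
        self.lasso_alpha = lasso_alpha
        self.C = C
        self.logistic_lasso = logistic_lasso

    def fit(self, X, y):
        M, names = _as_matrix(X)
        y = np.asarray(y, dtype=int)
        if not np.isfinite(M).all():
            raise ValueError("non-finite feature values")
        if M.shape[0] < 2:
            raise ValueError("need at least 2 training scans")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("selection is inapplicable with a single-class label")
        self.feature_names_in_ = names
        self.center_ = M.mean(axis=0)
        sd = M.std(axis=0, ddof=0)
        self.scale_ = np.where(sd > 0, sd, 1.0)
        Z = (M - self.center_) / self.scale_

        if self.logistic_lasso:
            sel_model = LogisticRegression(
                penalty="l1", C=1.0 / (max(self.lasso_alpha, 1e-12) * len(y)),
                solver="liblinear",
            ).fit(Z, y)
            coefs = sel_model.coef_[0]
        else:
            coefs = Lasso(alpha=self.lasso_alpha).fit(Z, y).coef_
        mask = coefs != 0
        self.selected_features_ = [n for n, m in zip(names, mask) if m]
        self.selected_mask_ = mask
        self.lasso_coefficients_ = coefs

        if not mask.any():
            self.fallback_ = True
            self.weights_ = np.zeros(0)
            self.bias_ = FALLBACK_SCORE
            return self
        self.fallback_ = False
        svm = SVC(kernel="linear", C=self.C).fit(Z[:, mask], y)
        self.weights_ = svm.coef_[0]
        self.bias_ = float(svm.intercept_[0])
        return self

    def _standardized_selection(self, X):
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names_in_ if f not in X.columns]
            if missing:
                raise SchemaError(f"missing selected feature column(s): {missing[:5]}")
            M = X[self.feature_names_in_].to_numpy(dtype=float)
        else:
            M = np.asarray(X, dtype=float)
            if M.shape[1] != len(self.feature_names_in_):
                raise SchemaError(
                    f"expected {len(self.feature_names_in_)} feature columns, "
                    f"got {M.shape[1]}"
                )
        Z = (M - self.center_) / self.scale_
        return Z[:, self.selected_mask_]

    def decision_function(self, X):
        if not hasattr(self, "fallback_"):
            raise RuntimeError("classifier is not fitted")
        n = len(X)
        if self.fallback_:
            return np.full(n, FALLBACK_SCORE)
        return self._standardized_selection(X) @ self.weights_ + self.bias_

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)

    def to_dict(self):
        return {
            "lasso_alpha": self.lasso_alpha,
            "C": self.C,
            "logistic_lasso": self.logistic_lasso,
            "feature_names_in": list(self.feature_names_in_),
            "center": self.center_.tolist(),
            "scale": self.scale_.tolist(),
            "selected_features": list(self.selected_features_),
            "selected_mask": self.selected_mask_.tolist(),
            "weights": np.asarray(self.weights_).tolist(),
            "bias": self.bias_,
            "fallback": bool(self.fallback_),
        }

    @classmethod
    def from_dict(cls, d):
        m = cls(lasso_alpha=d["lasso_alpha"], C=d["C"], logistic_lasso=d["logistic_lasso"])
        m.feature_names_in_ = list(d["feature_names_in"])
        m.center_ = np.array(d["center"])
        m.scale_ = np.array(d["scale"])
        m.selected_features_ = list(d["selected_features"])
        m.selected_mask_ = np.array(d["selected_mask"], dtype=bool)
        m.weights_ = np.array(d["weights"])
        m.bias_ = d["bias"]
        m.fallback_ = d["fallback"]
        m.classes_ = np.array([0, 1])
        return m


def lasso_select(features, labels, alpha=0.05):
    """Names (or indices) of features with nonzero LASSO coefficients, in
    original column order."""
    M, names = _as_matrix(features)
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("selection is inapplicable with a single-class label")
    center = M.mean(axis=0)
    sd = M.std(axis=0, ddof=0)
    Z = (M - center) / np.where(sd > 0, sd, 1.0)
    coefs = Lasso(alpha=alpha).fit(Z, y).coef_
    return [n for n, c in zip(names, coefs) if c != 0]


def train_classifier(features, labels, C=1.0, lasso_alpha=0.05):
    """Fit the full LASSO->SVM model; returns the fitted classifier (with
    the all-benign fallback when nothing survives selection)."""
    return LassoSvmClassifier(lasso_alpha=lasso_alpha, C=C).fit(features, labels)


def predict_scores(model: LassoSvmClassifier, features):
    """Signed distances to the hyperplane and thresholded labels
    (score > 0 means malignant)."""
    scores = model.decision_function(features)
    return scores, (scores > 0).astype(int)
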