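"""PLS1 discriminant analysis via NIPALS, with the discriminant Q^2 (dQ^2)
and misclassification-count (NMC) figures of merit.

Class labels are coded 0 (hypoxia) / 1 (normoxia) and mean-centered inside
each training fold; predictions are reported back on the 0/1 scale by adding
the fold's label mean. On that scale the dQ^2 clipping thresholds are the
class codes 0 and 1 and the NMC decision midpoint is 0.5 — algebraically
identical to using the fold-specific centered codes (-p, 1-p), since the
centering shifts codes and predictions equally.

dQ^2 (discriminant Q^2) zeroes the residual of any prediction that
overshoots its own class code in the correct direction, so a classifier is
not penalized for predicting "too correctly"; consequently dQ^2 >= the
standard Q^2 on identical predictions.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ValidationError
from .io import FeatureMatrix
from .preprocessing import Autoscaler

LV_MAX_DEFAULT = 3
_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500


def nipals_pls1(X, y, n_lv: int, tol: float = _NIPALS_TOL,
                max_iter: int = _NIPALS_MAX_ITER):
    """PLS1 by NIPALS deflation on a centered (X, y) pair.

    Returns ``(W, P, q, T, B)`` where ``W`` (p, A) are the orthonormal
    weight vectors, ``P`` (p, A) the x-loadings, ``q`` (A,) the y-loadings,
    ``T`` (n, A) the mutually orthogonal scores, and ``B`` (p, A) the
    cumulative regression vectors: column a-1 predicts with the first a
    latent variables via ``yhat = X @ B[:, a-1]``.

    For a univariate response the weight update is stationary after one
    pass; the iteration loop (tolerance on the weight change, capped at
    ``max_iter``) is retained as a guard and exits on its second sweep.
    """
    X = np.array(X, dtype=float)
    y = np.array(y, dtype=float)
    n, p = X.shape
    if n_lv < 1:
        raise ValidationError("n_lv must be >= 1")
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    for a in range(n_lv):
        u = y  # single-column Y: u is y itself
        w = X.T @ u
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValidationError(
                f"NIPALS breakdown: zero covariance at latent variable {a + 1}"
            )
        w /= nw
        for _ in range(max_iter):
            t = X @ w
            w_new = X.T @ y
            w_new /= np.linalg.norm(w_new)
            if np.linalg.norm(w_new - w) < tol:
                w = w_new
                break
            w = w_new  # pragma: no cover - PLS1 converges in one pass
        t = X @ w
        tt = float(t @ t)
        if tt == 0:
            raise ValidationError("NIPALS breakdown: zero score vector")
        qa = float(t @ y) / tt
        pa = X.T @ t / tt
        X = X - np.outer(t, pa)
        y = y - qa * t
        W[:, a], P[:, a], q[a], T[:, a] = w, pa, qa, t

    # cumulative regression vectors: B_a = W_a (P_a^T W_a)^{-1} q_a;
    # P^T W is unit upper triangular for PLS1-NIPALS, so plain
    # back-substitution (no divisions) suffices.
    R = P.T @ W
    B = np.zeros((p, n_lv))
    for a in range(1, n_lv + 1):
        beta = q[:a].copy()
        for i in range(a - 2, -1, -1):
            beta[i] -= R[i, i + 1 : a] @ beta[i + 1 : a]
        B[:, a - 1] = W[:, :a] @ beta
    return W, P, q, T, B


def dq2(y_true, y_pred, codes=None) -> float:
    """Discriminant Q^2 of predictions against two-class codes.

    ``codes`` is the (low, high) pair of class codes; inferred from the
    unique values of ``y_true`` when omitted. Residuals of predictions past
    their own class code in the correct direction are set to zero before
    PRESS; the total sum of squares uses the mean of ``y_true``.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if codes is None:
        uniq = np.unique(y_true)
        if uniq.size != 2:
            raise ValidationError("dq2 needs exactly two class codes in y_true")
        codes = (float(uniq[0]), float(uniq[1]))
    lo, hi = codes
    e = y_pred - y_true
    e[(y_true == hi) & (y_pred >= hi)] = 0.0
    e[(y_true == lo) & (y_pred <= lo)] = 0.0
    tss = float(np.sum((y_true - y_true.mean()) ** 2))
    if tss == 0:
        raise ValidationError("zero total sum of squares (single class)")
    return 1.0 - float(e @ e) / tss


def q2(y_true, y_pred) -> float:
    """Standard cross-validated Q^2 (no residual clipping)."""
    y_true = np.asarray(y_true, dtype=float)
    e = np.asarray(y_pred, dtype=float) - y_true
    tss = float(np.sum((y_true - y_true.mean()) ** 2))
    if tss == 0:
        raise ValidationError("zero total sum of squares (single class)")
    return 1.0 - float(e @ e) / tss


def nmc(y_true, y_pred, codes=None) -> int:
    """Number of misclassified samples at the midpoint of the class codes.

    A prediction exactly on the midpoint counts as misclassified.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if codes is None:
        uniq = np.unique(y_true)
        if uniq.size != 2:
            raise ValidationError("nmc needs exactly two class codes in y_true")
        codes = (float(uniq[0]), float(uniq[1]))
    lo, hi = codes
    mid = 0.5 * (lo + hi)
    correct = ((y_true == hi) & (y_pred > mid)) | ((y_true == lo) & (y_pred < mid))
    return int(np.sum(~correct))


def _check_two_class(y01):
    y01 = np.asarray(y01, dtype=float)
    uniq = np.unique(y01)
    if uniq.size != 2:
        raise ValidationError("both classes must be present")
    return y01


def select_n_lv(X, y01, lv_max: int = LV_MAX_DEFAULT, scale: bool = True) -> int:
    """Pick the PLS dimensionality by leave-one-out dQ^2.

    For each row, pretreatment (autoscaling of X, centering of the 0/1
    labels) is refit without it; out-of-fold predictions for 1..lv_max
    latent variables come from one nested NIPALS fit. Returns the smallest
    dimensionality attaining the maximal dQ^2.
    """
    X = _as_array(X)
    y01 = _check_two_class(y01)
    n = X.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 samples for LOO selection")
    lv_max = min(lv_max, n - 2) or 1
    preds = np.empty((n, lv_max))
    for i in range(n):
        rest = np.delete(np.arange(n), i)
        Xtr, ytr = X[rest], y01[rest]
        if np.unique(ytr).size != 2:
            raise ValidationError("a leave-one-out fold lost a class entirely")
        scaler = Autoscaler(on_constant="raise").fit(Xtr) if scale else None
        Xs = scaler.transform(Xtr) if scale else Xtr - Xtr.mean(axis=0)
        ym = ytr.mean()
        *_, B = nipals_pls1(Xs, ytr - ym, lv_max)
        xi = (
            scaler.transform(X[i : i + 1])[0]
            if scale
            else X[i] - Xtr.mean(axis=0)
        )
        preds[i] = xi @ B + ym
    scores = [dq2(y01, preds[:, a], codes=(0.0, 1.0)) for a in range(lv_max)]
    return int(np.argmax(scores)) + 1  # argmax returns the smallest on ties


def _as_array(X):
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


class PLSDA(BaseEstimator, ClassifierMixin):
    """Two-class PLS1 discriminant classifier (NIPALS).

    Parameters
    ----------
    n_lv : int or "loo-cv"
        Number of latent variables, or leave-one-out dQ^2 selection up to
        ``lv_max``.
    lv_max : int
        Dimensionality ceiling (default 3).
    scale : bool
        Autoscale X inside ``fit`` (training statistics are stored and
        applied to prediction rows).

    Attributes
    ----------
    classes_ : (2,) array of the sorted class labels; coded 0 and 1.
    coef_ : (p,) regression vector of the fitted dimensionality, acting on
        autoscaled inputs against centered labels.
    b_per_lv_ : (p, n_lv_) cumulative regression vectors.
    """

    def __init__(self, n_lv="loo-cv", lv_max: int = LV_MAX_DEFAULT, scale: bool = True):
        self.n_lv = n_lv
        self.lv_max = lv_max
        self.scale = scale

    def fit(self, X, y):
        X = _as_array(X)
        y = np.asarray(y)
        self.classes_, y01 = np.unique(y, return_inverse=True)
        if self.classes_.size != 2:
            raise ValidationError("PLSDA requires exactly two classes")
        y01 = y01.astype(float)
        if self.n_lv == "loo-cv":
            self.n_lv_ = select_n_lv(X, y01, self.lv_max, scale=self.scale)
        else:
            self.n_lv_ = int(self.n_lv)
            if not 1 <= self.n_lv_ <= self.lv_max:
                raise ValidationError(
                    f"n_lv must lie in 1..{self.lv_max}, got {self.n_lv_}"
                )
        self.scaler_ = Autoscaler(on_constant="raise").fit(X) if self.scale else None
        Xs = self.scaler_.transform(X) if self.scale else X - X.mean(axis=0)
        self._x_mean = X.mean(axis=0)
        self.y_mean_ = float(y01.mean())
        W, P, q, T, B = nipals_pls1(Xs, y01 - self.y_mean_, self.n_lv_)
        self.x_weights_, self.x_loadings_, self.y_loadings_, self.x_scores_ = W, P, q, T
        self.b_per_lv_ = B
        self.coef_ = B[:, self.n_lv_ - 1]
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        """Continuous predictions on the 0/1 class-code scale."""
        check_is_fitted(self, "coef_")
        X = np.atleast_2d(_as_array(X))
        if X.shape[1] != self.n_features_in_:
            raise ValidationError("dimension mismatch in prediction")
        Xs = self.scaler_.transform(X) if self.scale else X - self._x_mean
        return Xs @ self.coef_ + self.y_mean_

    def predict(self, X):
        yhat = self.decision_function(X)
        return self.classes_[(yhat > 0.5).astype(int)]

    def score_figures(self, X, y_true01):
        """dQ^2 and NMC of predictions for rows with known 0/1 labels."""
        yhat = self.decision_function(X)
        return dq2(y_true01, yhat, codes=(0.0, 1.0)), nmc(
            y_true01, yhat, codes=(0.0, 1.0)
        )
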