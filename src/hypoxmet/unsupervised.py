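"""Unsupervised exploration: PCA with Q-residual and Hotelling's T^2
outlier statistics, leave-one-out component selection, and Ward
hierarchical clustering on PCA scores.

PCA is computed by singular value decomposition (equivalent to NIPALS-PCA
at convergence, deterministic and rank-safe). The Q statistic is the
squared norm of a sample's residual after projection onto the retained
subspace; T^2 is the sum of squared scores each normalized by its
component's score variance (ddof=1). 95% control limits use the
F-distribution form for T^2 and the Jackson-Mudholkar approximation for Q,
falling back to the Box chi-square form when fewer than three informative
residual eigenvalues remain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .errors import ValidationError
from .io import FeatureMatrix
from .preprocessing import Autoscaler

_EIG_TOL = 1e-12


def _as_array(X):
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


class PCAOutlierModel(BaseEstimator):
    """PCA with autoscaling, LOO-CV rank selection and Q/T^2 limits.

    Parameters
    ----------
    n_components : int or "loo-cv"
        Number of retained PCs, or leave-one-out PRESS minimization
        (scaling refit without the held-out row in every fold; smallest
        minimizer wins on ties).
    a_max : int, optional
        Search ceiling for "loo-cv"; defaults to ``min(n - 2, 6)``.
    scale : bool
        Autoscale (mean-center, unit sample variance) before decomposition;
        when False the data are only mean-centered unless ``center`` is
        also False.
    """

    def __init__(self, n_components="loo-cv", a_max=None, scale=True, center=True):
        self.n_components = n_components
        self.a_max = a_max
        self.scale = scale
        self.center = center

    # -- internals -----------------------------------------------------------

    def _pretreat_fit(self, X):
        if self.scale:
            scaler = Autoscaler(on_constant="raise").fit(X)
            return scaler.transform(X), scaler
        if self.center:
            mean = X.mean(axis=0)
            return X - mean, ("center", mean)
        return X.copy(), None

    def _pretreat_apply(self, X, state):
        if self.scale:
            return state.transform(X)
        if self.center:
            return X - state[1]
        return np.asarray(X, dtype=float)

    # -- estimator API -------------------------------------------------------

    def fit(self, X, y=None):
        X = _as_array(X)
        n, p = X.shape
        Xs, self.scaler_ = self._pretreat_fit(X)

        U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
        eig = S**2 / (n - 1)  # per-PC score variances
        total = eig.sum()
        self.eigenvalues_ = eig
        self.explained_variance_ratio_full_ = eig / total

        if self.n_components == "loo-cv":
            a_max = self.a_max or min(n - 2, 6)
            a_max = max(1, min(a_max, int((eig > _EIG_TOL * eig[0]).sum())))
            press = loo_cv_press(X, a_max, scale=self.scale, center=self.center)
            self.press_ = press
            A = int(np.argmin(press)) + 1
        else:
            A = int(self.n_components)
            rank = int((eig > _EIG_TOL * max(eig[0], 1)).sum())
            if A > min(n - 1, p) or A > rank:
                raise ValidationError(f"n_components={A} exceeds rank {rank}")
        self.n_components_ = A
        self.loadings_ = Vt[:A].T  # (p, A), orthonormal columns
        self.scores_ = Xs @ self.loadings_
        self.explained_variance_ratio_ = self.explained_variance_ratio_full_[:A]
        self.q_limit_95_, self.t2_limit_95_ = limits_95(
            residual_eigenvalues=eig[A:], A=A, n=n
        )
        self.n_samples_, self.n_features_in_ = n, p
        return self

    def transform(self, X):
        check_is_fitted(self, "loadings_")
        Xs = self._pretreat_apply(np.atleast_2d(_as_array(X)), self.scaler_)
        return Xs @ self.loadings_

    def q_statistic(self, X):
        """Squared reconstruction residual ||x - x L L^T||^2 per row."""
        check_is_fitted(self, "loadings_")
        Xs = self._pretreat_apply(np.atleast_2d(_as_array(X)), self.scaler_)
        resid = Xs - (Xs @ self.loadings_) @ self.loadings_.T
        return np.einsum("ij,ij->i", resid, resid)

    def t2_statistic(self, X):
        """Sum of normalized squared scores over the retained PCs."""
        check_is_fitted(self, "loadings_")
        lam = self.eigenvalues_[: self.n_components_]
        if np.any(lam <= _EIG_TOL):
            raise ValidationError("zero eigenvalue among retained components")
        t = self.transform(X)
        return np.sum(t**2 / lam, axis=1)


def loo_cv_press(X, a_max: int, scale=True, center=True) -> np.ndarray:
    """Leave-one-out PRESS for 1..a_max components.

    Each fold refits pretreatment and PCA without the held-out row. The
    held-out row's reconstruction error is accumulated element-wise: each
    variable is predicted from the remaining variables through the fold's
    loadings (least-squares score estimate excluding that variable). A
    plain projection of the full row would shrink monotonically with every
    added component and could never identify the informative rank; the
    element-wise scheme penalizes noise components and has a genuine
    minimum.
    """
    X = _as_array(X)
    n = X.shape[0]
    press = np.zeros(a_max)
    for i in range(n):
        rest = np.delete(X, i, axis=0)
        model = PCAOutlierModel(n_components=1, scale=scale, center=center)
        # direct SVD of the pretreated fold; avoid recursion into loo-cv
        Xs, state = model._pretreat_fit(rest)
        _, _, Vt = np.linalg.svd(Xs, full_matrices=False)
        xi = model._pretreat_apply(X[i : i + 1], state)[0]
        for a in range(1, a_max + 1):
            L = Vt[: min(a, Vt.shape[0])].T  # (p, a)
            M = L.T @ L  # ~ identity, kept explicit for rank safety
            Minv = np.linalg.inv(M)
            s_full = L.T @ xi
            for j in range(L.shape[0]):
                lj = L[j]
                # Sherman-Morrison downdate: scores excluding variable j
                Alj = Minv @ lj
                denom = 1.0 - lj @ Alj
                if denom <= 1e-12:
                    continue  # variable j carries a whole component; skip
                t = Minv @ (s_full - lj * xi[j]) + Alj * (
                    lj @ (Minv @ (s_full - lj * xi[j]))
                ) / denom
                press[a - 1] += (xi[j] - lj @ t) ** 2
    return press


def limits_95(residual_eigenvalues, A: int, n: int, alpha: float = 0.05):
    """95% control limits ``(q_limit, t2_limit)``.

    T^2: ``A(n-1)(n+1) / (n(n-A)) * F_{1-alpha}(A, n-A)``.
    Q: Jackson-Mudholkar from the residual eigenvalues; Box chi-square
    fallback when the approximation is unusable.
    """
    if n <= A:
        raise ValidationError("need n > A for the T^2 limit")
    t2_limit = (
        A * (n - 1) * (n + 1) / (n * (n - A)) * stats.f.ppf(1 - alpha, A, n - A)
    )

    lam = np.asarray(residual_eigenvalues, dtype=float)
    lam = lam[lam > _EIG_TOL * (lam.max() if lam.size else 1.0)]
    if lam.size == 0:
        return 0.0, float(t2_limit)
    th1, th2, th3 = (np.sum(lam**k) for k in (1, 2, 3))
    h0 = 1.0 - 2.0 * th1 * th3 / (3.0 * th2**2)
    z = stats.norm.ppf(1 - alpha)
    if h0 <= 0 or lam.size < 3:
        # Box approximation: Q ~ g * chi2(h)
        g, h = th2 / th1, th1**2 / th2
        warnings.warn("falling back to the Box chi-square Q limit")
        return float(g * stats.chi2.ppf(1 - alpha, h)), float(t2_limit)
    q_limit = th1 * (
        z * np.sqrt(2.0 * th2 * h0**2) / th1 + 1.0 + th2 * h0 * (h0 - 1.0) / th1**2
    ) ** (1.0 / h0)
    return float(q_limit), float(t2_limit)


@dataclass
class Dendrogram:
    """Ward/Euclidean agglomeration result.

    ``linkage`` is the scipy-format merge table (left, right, height, size);
    heights are monotone non-decreasing (Ward).
    """

    linkage: np.ndarray
    labels: list[str]

    @property
    def leaf_order(self) -> list[int]:
        return hierarchy.leaves_list(self.linkage).tolist()

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, k: int) -> np.ndarray:
        """Flat cluster assignment at k clusters."""
        return hierarchy.fcluster(self.linkage, k, criterion="maxclust")

    def to_newick(self) -> str:
        """Nested-parenthesis export with merge heights as branch lengths."""
        n = len(self.labels)
        nodes: dict[int, str] = {i: self.labels[i] for i in range(n)}
        heights = {i: 0.0 for i in range(n)}
        for k, (a, b, h, _size) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
            heights[n + k] = h
        return nodes[n + len(self.linkage) - 1] + ";"


def ward_hca(X, labels=None) -> Dendrogram:
    """Agglomerative Ward clustering over Euclidean distances.

    Intended to run on PCA scores of the retained components ("distances
    between samples in the model"), but accepts any samples x variables
    matrix. Deterministic given row order.
    """
    if isinstance(X, FeatureMatrix):
        if labels is None:
            labels = list(X.sample_ids)
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("clustering needs at least 2 rows")
    if labels is None:
        labels = [str(i) for i in range(X.shape[0])]
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    return Dendrogram(linkage=Z, labels=list(labels))
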