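"""Model validation: leave-one-out double cross-validation (2CV), the
exhaustive non-complementary label-permutation test, and permutation-null
selection of differentiating features.

Double CV nests two leave-one-out loops: the outer loop holds one sample
out for testing, the inner loop (on the remaining n-1) picks the PLS
dimensionality by dQ^2, and the outer-fold model predicts the held-out
sample. Aggregated out-of-fold predictions yield the dQ^2 and NMC figures
of merit; the mean of the outer-fold regression vectors is ``b``.

The permutation test enumerates every class-size-preserving relabeling
once per complement pair (a relabeling and its complement produce
mirror-image models), excluding the true labeling — 125 relabelings for a
balanced 5 vs 5 design. Running double CV under each relabeling gives
deterministic null distributions for dQ^2, NMC and the regression vector;
per-feature two-tailed empirical p-values against the null regression
vectors select the differentiating features.

Because the feature matrix is fixed while only the labels permute, the
per-fold autoscaling statistics are label-independent; they are computed
once (:class:`_FoldCache`) and reused across all relabelings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from itertools import combinations

import numpy as np

from .errors import ValidationError
from .io import FeatureMatrix
from .plsda import LV_MAX_DEFAULT, dq2, nipals_pls1, nmc


def _as_array(X):
    return X.values if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)


class _FoldCache:
    """Autoscaled views of X for every outer and (outer, inner) LOO fold.

    ``outer[i]`` holds the scaled training matrix without sample i and the
    identically scaled held-out row; ``inner[i][j]`` the same one level
    deeper. Scaling uses training-fold mean and ddof=1 standard deviation.
    """

    def __init__(self, X, scale: bool = True):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        self.n = n
        self.outer = []
        self.inner = []
        for i in range(n):
            rest = np.delete(np.arange(n), i)
            self.outer.append(self._scaled(X, rest, i, scale))
            level2 = []
            for j in rest:
                sub = rest[rest != j]
                level2.append(self._scaled(X, sub, j, scale))
            self.inner.append(level2)

    @staticmethod
    def _scaled(X, train_idx, test_idx, scale):
        Xtr = X[train_idx]
        mean = Xtr.mean(axis=0)
        if scale:
            std = Xtr.std(axis=0, ddof=1)
            if np.any(std == 0):
                bad = np.flatnonzero(std == 0).tolist()
                raise ValidationError(
                    f"zero-variance features within a CV fold: columns {bad}"
                )
        else:
            std = 1.0
        return (X[train_idx] - mean) / std, (X[test_idx] - mean) / std


@dataclass
class DCVResult:
    """Outcome of leave-one-out double cross-validation."""

    sample_ids: list[str]
    y_true: np.ndarray  # 0/1 codes
    y_pred: np.ndarray  # out-of-fold predictions on the 0/1 scale
    fold_n_lv: list[int]
    dq2: float
    nmc: int
    b_mean: np.ndarray  # mean outer-fold regression vector
    b_folds: np.ndarray  # (n, p)

    @property
    def n_predictions(self) -> int:
        return len(self.y_pred)

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("y_true", "y_pred", "b_mean", "b_folds"):
            d[k] = np.asarray(d[k]).tolist()
        return d


def _dcv_engine(cache: _FoldCache, y01: np.ndarray, lv_max: int):
    """Double CV for one label vector on cached fold scalings.

    Returns ``(y_pred, fold_n_lv, b_folds)``.
    """
    n = cache.n
    y_pred = np.empty(n)
    fold_lv = []
    b_folds = None
    for i in range(n):
        rest = np.delete(np.arange(n), i)
        ytr = y01[rest]
        if np.unique(ytr).size != 2:
            raise ValidationError("an outer training fold lost a class entirely")
        a_max = min(lv_max, len(rest) - 1)
        # inner LOO: dimensionality by dQ2
        inner_pred = np.empty((len(rest), a_max))
        for jloc in range(len(rest)):
            Xin, xval = cache.inner[i][jloc]
            yin = np.delete(ytr, jloc)
            if np.unique(yin).size != 2:
                raise ValidationError("an inner training fold lost a class entirely")
            ym = yin.mean()
            *_, B = nipals_pls1(Xin, yin - ym, a_max)
            inner_pred[jloc] = xval @ B + ym
        scores = [dq2(ytr, inner_pred[:, a], codes=(0.0, 1.0)) for a in range(a_max)]
        a_star = int(np.argmax(scores)) + 1
        fold_lv.append(a_star)
        # outer refit at the chosen dimensionality
        Xtr, xte = cache.outer[i]
        ym = ytr.mean()
        *_, B = nipals_pls1(Xtr, ytr - ym, a_star)
        if b_folds is None:
            b_folds = np.empty((n, B.shape[0]))
        b_folds[i] = B[:, a_star - 1]
        y_pred[i] = float(xte @ B[:, a_star - 1]) + ym
    return y_pred, fold_lv, b_folds


def double_cv(X, y01, lv_max: int = LV_MAX_DEFAULT, sample_ids=None,
              scale: bool = True) -> DCVResult:
    """Leave-one-out double cross-validation of the PLS-DA model.

    ``y01`` are 0/1 class codes (0 = hypoxia, 1 = normoxia by the pipeline
    convention). Requires n >= 4 and at least two members per class.
    """
    if isinstance(X, FeatureMatrix) and sample_ids is None:
        sample_ids = list(X.sample_ids)
    X = _as_array(X)
    y01 = np.asarray(y01, dtype=float)
    n = X.shape[0]
    if n < 4:
        raise ValidationError("double CV needs at least 4 samples")
    _check_class_sizes(y01, minimum=2)
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    cache = _FoldCache(X, scale=scale)
    y_pred, fold_lv, b_folds = _dcv_engine(cache, y01, lv_max)
    return DCVResult(
        sample_ids=list(sample_ids),
        y_true=y01,
        y_pred=y_pred,
        fold_n_lv=fold_lv,
        dq2=dq2(y01, y_pred.copy(), codes=(0.0, 1.0)),
        nmc=nmc(y01, y_pred, codes=(0.0, 1.0)),
        b_mean=b_folds.mean(axis=0),
        b_folds=b_folds,
    )


def _check_class_sizes(y, minimum: int):
    vals, counts = np.unique(np.asarray(y), return_counts=True)
    if vals.size != 2:
        raise ValidationError("exactly two classes required")
    if counts.min() < minimum:
        raise ValidationError(
            f"each class needs at least {minimum} members, got {counts.tolist()}"
        )
    return vals, counts


def enumerate_balanced_permutations(y) -> np.ndarray:
    """All class-size-preserving relabelings, one per complement pair,
    excluding the true labeling.

    For balanced classes a relabeling and its complement assign the same
    partition with swapped names and yield mirror-image discriminant
    models; each such pair is represented once, by the member that assigns
    position 0 to the low-code class. For a 5 vs 5 design this gives C(10,5)/2 - 1 = 125
    label vectors. Unbalanced designs have no complement pairing; all
    relabelings except the true one are returned.
    """
    y = np.asarray(y)
    vals, counts = _check_class_sizes(y, minimum=2)
    n = y.size
    lo = vals[0]
    n_lo = int(counts[0])
    true_lo = frozenset(np.flatnonzero(y == lo).tolist())

    out = []
    if counts[0] == counts[1]:
        # subsets containing index 0 pick one member of each complement pair
        for rest in combinations(range(1, n), n_lo - 1):
            subset = frozenset((0, *rest))
            if subset == true_lo or frozenset(range(n)) - subset == true_lo:
                continue
            lab = np.full(n, vals[1])
            lab[list(subset)] = lo
            out.append(lab)
    else:
        for comb in combinations(range(n), n_lo):
            subset = frozenset(comb)
            if subset == true_lo:
                continue
            lab = np.full(n, vals[1])
            lab[list(subset)] = lo
            out.append(lab)
    return np.array(out)


@dataclass
class PermutationResult:
    """Null distributions and selection outcome of the permutation test."""

    n_permutations: int
    null_dq2: np.ndarray
    null_nmc: np.ndarray
    b_random: np.ndarray  # (n_permutations, p)
    b_real: np.ndarray
    real_dq2: float
    real_nmc: int
    p_dq2: float
    p_nmc: float
    per_feature_p: np.ndarray
    selected_features: list[str]
    alpha: float
    n_failed_permutations: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("null_dq2", "null_nmc", "b_random", "b_real", "per_feature_p"):
            d[k] = np.asarray(d[k]).tolist()
        return d


def permutation_test(
    X,
    y01=None,
    lv_max: int = LV_MAX_DEFAULT,
    alpha: float = 0.025,
    plus_one: bool = False,
    tails: str = "signed",
    feature_ids=None,
    scale: bool = True,
) -> PermutationResult:
    """Exhaustive non-complementary permutation test of the 2CV PLS-DA.

    Model p-values are the plain fractions of permuted statistics at least
    as extreme as the real ones (dQ^2: >=, NMC: <=); ``plus_one`` switches
    to the add-one convention. Per-feature p-values compare ``b_real``
    against the null regression vectors ``b_random`` per tail (``tails =
    "signed"``, threshold ``alpha`` per tail) or on absolute values
    (``tails = "absolute"``); features with p < ``alpha`` are selected.

    Permutations whose double CV fails (a fold losing a class cannot occur
    for size-preserving relabelings, but numerical breakdowns are
    conceivable) are dropped with a warning, never silently imputed.
    """
    if isinstance(X, FeatureMatrix):
        if feature_ids is None:
            feature_ids = X.feature_ids
        if y01 is None:
            y01 = X.y01()
        X = X.values
    X = np.asarray(X, dtype=float)
    y01 = np.asarray(y01, dtype=float)
    if feature_ids is None:
        feature_ids = [str(j) for j in range(X.shape[1])]
    if tails not in ("signed", "absolute"):
        raise ValidationError("tails must be 'signed' or 'absolute'")

    perms = enumerate_balanced_permutations(y01)
    cache = _FoldCache(X, scale=scale)

    y_pred, _, b_folds = _dcv_engine(cache, y01, lv_max)
    real_dq2 = dq2(y01, y_pred.copy(), codes=(0.0, 1.0))
    real_nmc = nmc(y01, y_pred, codes=(0.0, 1.0))
    b_real = b_folds.mean(axis=0)

    null_dq2, null_nmc, b_random = [], [], []
    n_failed = 0
    for lab in perms:
        try:
            yp, _, bf = _dcv_engine(cache, lab.astype(float), lv_max)
        except ValidationError as exc:
            n_failed += 1
            warnings.warn(f"permutation dropped: {exc}")
            continue
        null_dq2.append(dq2(lab.astype(float), yp.copy(), codes=(0.0, 1.0)))
        null_nmc.append(nmc(lab.astype(float), yp, codes=(0.0, 1.0)))
        b_random.append(bf.mean(axis=0))
    null_dq2 = np.asarray(null_dq2)
    null_nmc = np.asarray(null_nmc)
    b_random = np.asarray(b_random)
    K = len(null_dq2)
    if K == 0:
        raise ValidationError("no usable permutations")

    add = 1 if plus_one else 0
    denom = K + add
    p_dq2 = (np.sum(null_dq2 >= real_dq2) + add) / denom
    p_nmc = (np.sum(null_nmc <= real_nmc) + add) / denom
    if tails == "signed":
        hi = (np.sum(b_random >= b_real, axis=0) + add) / denom
        lo = (np.sum(b_random <= b_real, axis=0) + add) / denom
        per_feature_p = np.minimum(hi, lo)
    else:
        per_feature_p = (
            np.sum(np.abs(b_random) >= np.abs(b_real), axis=0) + add
        ) / denom
    selected = [feature_ids[j] for j in np.flatnonzero(per_feature_p < alpha)]
    return PermutationResult(
        n_permutations=K,
        null_dq2=null_dq2,
        null_nmc=null_nmc,
        b_random=b_random,
        b_real=b_real,
        real_dq2=real_dq2,
        real_nmc=real_nmc,
        p_dq2=float(p_dq2),
        p_nmc=float(p_nmc),
        per_feature_p=per_feature_p,
        selected_features=selected,
        alpha=alpha,
        n_failed_permutations=n_failed,
    )
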