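"""Feature-table preprocessing: replicate collapse, blank-feature removal,
low-frequency filtering, autoscaling and data-quality metrics.

The filter chain is fixed and order-dependent — replicate medians first
(X1), then removal of features detected in blank injections (X2), then
removal of features present in fewer than ``min_samples`` collapsed samples
(X3). Zero encodes "not detected" and participates in the median.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import ConfigurationError, ConstantFeatureError, ValidationError
from .io import FeatureMatrix, InjectionTable, ROLE_BLANK


@dataclass
class PreprocessReport:
    """Bookkeeping of the filter chain; counts always reconcile."""

    n_features_in: int
    n_removed_blank: int
    n_removed_lowfreq: int
    n_features_out: int
    missing_fraction_before: float
    missing_fraction_after: float
    missing_fraction_x2: float
    per_sample_detected_counts: list[int]

    def __post_init__(self):
        if (
            self.n_features_in - self.n_removed_blank - self.n_removed_lowfreq
            != self.n_features_out
        ):
            raise ValidationError("preprocessing counts do not reconcile")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class QCReport:
    """Instrument-performance metrics: IS area RSD (%), per-injection signed
    ppm mass errors of the IS, replicate Pearson correlations per sample and
    per-feature replicate RSDs (%)."""

    is_area_rsd: float | None
    is_ppm_errors: list[float] | None
    replicate_correlations: dict[str, list[float]]
    feature_rsd_percent: list[float]

    def to_dict(self) -> dict:
        return asdict(self)


def collapse_replicates(table: InjectionTable) -> FeatureMatrix:
    """Collapse replicate injections to per-sample medians (stage X1).

    Zeros (not detected) participate in the median, so a feature seen in
    only one of three replicates collapses to 0.
    """
    sample_ids = table.sample_ids
    if not sample_ids:
        raise ValidationError("table contains no sample injections")
    values = np.empty((len(sample_ids), table.n_features))
    labels = []
    for i, sid in enumerate(sample_ids):
        idx = table.sample_injection_indices(sid)
        values[i] = np.median(table.intensity[:, idx], axis=1)
        labels.append(table.class_of(sid))
    return FeatureMatrix(
        sample_ids=sample_ids,
        class_labels=labels,
        features=list(table.features),
        values=values,
        provenance="X1",
    )


def remove_blank_features(
    matrix: FeatureMatrix,
    table: InjectionTable,
    min_blank_detections: int = 1,
    intensity_floor: float = 0.0,
):
    """Drop features detected in >= ``min_blank_detections`` blank injections
    (stage X2). Returns ``(filtered_matrix, removed_feature_ids)``."""
    blank_idx = table.blank_indices
    if not blank_idx:
        raise ConfigurationError("no blank injections present for blank removal")
    blanks = table.intensity[:, blank_idx]
    id_to_col = {f.feature_id: j for j, f in enumerate(table.features)}
    detections = (blanks > intensity_floor).sum(axis=1)
    removed, keep = [], []
    for j, f in enumerate(matrix.features):
        if detections[id_to_col[f.feature_id]] >= min_blank_detections:
            removed.append(f.feature_id)
        else:
            keep.append(j)
    return matrix.subset_features(keep, provenance="X2"), removed


def frequency_filter(matrix: FeatureMatrix, min_samples: int = 3):
    """Drop features detected (> 0 after collapse) in fewer than
    ``min_samples`` samples (stage X3). Returns ``(matrix, removed_ids)``."""
    if min_samples < 1:
        raise ConfigurationError("min_samples must be >= 1")
    counts = (matrix.values > 0).sum(axis=0)
    keep = [j for j in range(matrix.n_features) if counts[j] >= min_samples]
    removed = [matrix.features[j].feature_id for j in range(matrix.n_features) if counts[j] < min_samples]
    return matrix.subset_features(keep, provenance="X3"), removed


@dataclass
class PreprocessResult:
    x1: FeatureMatrix
    x2: FeatureMatrix
    x3: FeatureMatrix
    report: PreprocessReport


def preprocess(
    table: InjectionTable,
    min_blank_detections: int = 1,
    min_samples: int = 3,
    intensity_floor: float = 0.0,
) -> PreprocessResult:
    """Run the full X1 -> X2 -> X3 chain and report the reductions."""
    x1 = collapse_replicates(table)
    x2, removed_blank = remove_blank_features(
        x1, table, min_blank_detections, intensity_floor
    )
    x3, removed_lowfreq = frequency_filter(x2, min_samples)
    report = PreprocessReport(
        n_features_in=x1.n_features,
        n_removed_blank=len(removed_blank),
        n_removed_lowfreq=len(removed_lowfreq),
        n_features_out=x3.n_features,
        missing_fraction_before=float(np.mean(x1.values == 0)),
        missing_fraction_after=float(np.mean(x3.values == 0)),
        missing_fraction_x2=float(np.mean(x2.values == 0)),
        per_sample_detected_counts=[int(c) for c in (x3.values > 0).sum(axis=1)],
    )
    return PreprocessResult(x1=x1, x2=x2, x3=x3, report=report)


class Autoscaler(BaseEstimator, TransformerMixin):
    """Column-wise mean-centering and unit-variance scaling (ddof=1).

    The sample (n-1) standard deviation is the chemometrics convention and
    materially matters at n = 10 rows. Stored ``mean_``/``std_`` apply the
    identical transform to held-out rows.

    Parameters
    ----------
    on_constant : {"raise", "drop"}
        Zero-variance columns either raise :class:`ConstantFeatureError`
        naming the features, or are dropped with a warning (batch mode).
    """

    def __init__(self, on_constant: str = "raise"):
        self.on_constant = on_constant

    def fit(self, X, y=None, feature_ids=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValidationError("autoscaling needs a 2-D matrix with >= 2 rows")
        self.mean_ = X.mean(axis=0)
        self.std_ = X.std(axis=0, ddof=1)
        constant = np.flatnonzero(self.std_ == 0)
        self.kept_columns_ = np.arange(X.shape[1])
        if constant.size:
            names = (
                [feature_ids[i] for i in constant]
                if feature_ids is not None
                else constant.tolist()
            )
            if self.on_constant == "raise":
                raise ConstantFeatureError(names)
            warnings.warn(f"dropping zero-variance features: {names}")
            self.kept_columns_ = np.setdiff1d(self.kept_columns_, constant)
            self.mean_ = self.mean_[self.kept_columns_]
            self.std_ = self.std_[self.kept_columns_]
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = np.asarray(X, dtype=float)
        if X.shape[-1] != self.n_features_in_:
            raise ValidationError("dimension mismatch in autoscaling transform")
        return (X[..., self.kept_columns_] - self.mean_) / self.std_

    def inverse_transform(self, X):
        check_is_fitted(self, "mean_")
        return np.asarray(X, dtype=float) * self.std_ + self.mean_


def autoscale(X, feature_ids=None):
    """Autoscale a matrix; returns ``(scaled, means, sds)``.

    Raises :class:`ConstantFeatureError` on zero-variance columns.
    """
    values = X.values if isinstance(X, FeatureMatrix) else X
    ids = feature_ids
    if ids is None and isinstance(X, FeatureMatrix):
        ids = X.feature_ids
    scaler = Autoscaler(on_constant="raise").fit(values, feature_ids=ids)
    return scaler.transform(values), scaler.mean_.copy(), scaler.std_.copy()


def qc_metrics(table: InjectionTable, is_reference_mz: float = 609.2812) -> QCReport:
    """Instrument/data quality metrics.

    IS area RSD = 100*SD/mean over injections (SD with ddof=1); ppm error =
    1e6*(measured - reference)/reference; replicate correlations are Pearson
    r between the replicate intensity vectors of each sample; per-feature
    RSDs are computed across replicates of each sample (detected-in-all
    cells only) and averaged per feature. Metrics lacking inputs (no IS
    channel, < 2 replicates) are reported as unavailable, never as zero.
    """
    is_rsd = None
    ppm = None
    if table.is_area is not None:
        a = table.is_area
        is_rsd = float(100.0 * np.std(a, ddof=1) / np.mean(a))
    if table.is_mz is not None:
        ppm = (1e6 * (table.is_mz - is_reference_mz) / is_reference_mz).tolist()

    correlations: dict[str, list[float]] = {}
    nf = table.n_features
    rsd_num = np.zeros(nf)
    rsd_cnt = np.zeros(nf)
    for sid in table.sample_ids:
        idx = table.sample_injection_indices(sid)
        if len(idx) < 2:
            continue
        reps = table.intensity[:, idx]
        rs = []
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                va, vb = reps[:, a], reps[:, b]
                if np.std(va) == 0 or np.std(vb) == 0:
                    continue
                rs.append(float(np.corrcoef(va, vb)[0, 1]))
        correlations[sid] = rs
        full = (reps > 0).all(axis=1)
        m = reps[full].mean(axis=1)
        s = reps[full].std(axis=1, ddof=1)
        rsd_num[full] += np.where(m > 0, 100.0 * s / np.where(m > 0, m, 1.0), 0.0)
        rsd_cnt[full] += 1
    with np.errstate(invalid="ignore"):
        feature_rsd = np.where(rsd_cnt > 0, rsd_num / np.maximum(rsd_cnt, 1), np.nan)
    return QCReport(
        is_area_rsd=is_rsd,
        is_ppm_errors=ppm,
        replicate_correlations=correlations,
        feature_rsd_percent=[float(v) for v in feature_rsd],
    )
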