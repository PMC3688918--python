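import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hypoxmet.errors import ConfigurationError, ConstantFeatureError
from hypoxmet.io import FeatureDescriptor, InjectionRecord, InjectionTable
from hypoxmet.preprocessing import (
    Autoscaler,
    autoscale,
    collapse_replicates,
    frequency_filter,
    preprocess,
    qc_metrics,
    remove_blank_features,
)


def table_from_replicates(per_sample, blanks=None):
    """One feature; per_sample maps sample id -> replicate intensities."""
    features = [FeatureDescriptor("0.50_100.0000", 0.5, 100.0)]
    injections, cols = [], []
    order = 1
    for sid, reps in per_sample.items():
        for k, v in enumerate(reps):
            injections.append(
                InjectionRecord(f"{sid}_r{k+1}", sid, k + 1, "sample", "hypoxia", order)
            )
            cols.append(v)
            order += 1
    for b, v in enumerate(blanks or []):
        injections.append(InjectionRecord(f"B{b+1}", None, 1, "blank", None, order))
        cols.append(v)
        order += 1
    return InjectionTable(features, injections, np.array([cols], dtype=float))


@pytest.mark.parametrize(
    "reps,expected",
    [((1, 2, 10), 2.0), ((0, 0, 9), 0.0), ((5,), 5.0), ((0, 4, 6), 4.0)],
)
def test_replicate_median_includes_zeros(reps, expected):
    x1 = collapse_replicates(table_from_replicates({"S1": reps}))
    assert x1.values[0, 0] == expected
    assert x1.provenance == "X1"


@settings(deadline=None, derandomize=True)
@given(st.permutations([0.0, 1.5, 7.0]))
def test_collapse_is_replicate_order_invariant(reps):
    x1 = collapse_replicates(table_from_replicates({"S1": list(reps)}))
    assert x1.values[0, 0] == 1.5


def test_blank_feature_removal_rule():
    # feature 0 seen in 1 of 2 blanks -> removed at min=1; feature 1 never
    features = [
        FeatureDescriptor("0.50_100.0000", 0.5, 100.0),
        FeatureDescriptor("1.00_200.0000", 1.0, 200.0),
    ]
    injections = [
        InjectionRecord("S1_r1", "S1", 1, "sample", "hypoxia", 1),
        InjectionRecord("B1", None, 1, "blank", None, 2),
        InjectionRecord("B2", None, 1, "blank", None, 3),
    ]
    table = InjectionTable(
        features, injections, np.array([[5.0, 2.0, 0.0], [5.0, 0.0, 0.0]])
    )
    x1 = collapse_replicates(table)
    x2, removed = remove_blank_features(x1, table, min_blank_detections=1)
    assert removed == ["0.50_100.0000"]
    assert x2.feature_ids == ["1.00_200.0000"]
    assert x2.provenance == "X2"
    _, removed2 = remove_blank_features(x1, table, min_blank_detections=2)
    assert removed2 == []


def test_blank_removal_requires_blank_injections():
    table = table_from_replicates({"S1": (1, 2, 3)})
    x1 = collapse_replicates(table)
    with pytest.raises(ConfigurationError):
        remove_blank_features(x1, table)


@pytest.mark.parametrize("n_present,kept", [(2, False), (3, True), (10, True)])
def test_frequency_filter_boundary(n_present, kept):
    values = np.zeros((10, 1))
    values[:n_present, 0] = 1.0
    from hypoxmet.io import FeatureMatrix

    m = FeatureMatrix(
        sample_ids=[f"S{i}" for i in range(10)],
        class_labels=["hypoxia"] * 10,
        features=[FeatureDescriptor("0.50_100.0000", 0.5, 100.0)],
        values=values,
    )
    x3, removed = frequency_filter(m, min_samples=3)
    assert (x3.n_features == 1) is kept
    assert (removed == ["0.50_100.0000"]) is not kept


def test_paper_shape_reduction_and_report(preprocessed):
    res, truth = preprocessed
    r = res.report
    assert res.x1.values.shape == (10, 365)
    assert r.n_removed_blank == 136 and res.x2.values.shape == (10, 229)
    assert r.n_removed_lowfreq == 117 and res.x3.values.shape == (10, 112)
    assert r.n_features_in - r.n_removed_blank - r.n_removed_lowfreq == r.n_features_out
    # missingness decreases through the filter chain
    assert r.missing_fraction_after < r.missing_fraction_before
    # the removed sets match the generator's ground truth
    assert set(res.x3.feature_ids).isdisjoint(truth.blank_feature_ids)
    assert set(res.x3.feature_ids).isdisjoint(truth.lowfreq_feature_ids)
    assert set(truth.discriminant_ids) <= set(res.x3.feature_ids)


def test_autoscale_columns_standardized(rng):
    X = rng.normal(2.0, 3.0, (10, 6))
    Xs, mean, sd = autoscale(X)
    np.testing.assert_allclose(Xs.mean(axis=0), 0.0, atol=1e-10)
    np.testing.assert_allclose(Xs.std(axis=0, ddof=1), 1.0, rtol=1e-10)
    # stored statistics reproduce the transform on the training data
    np.testing.assert_allclose((X - mean) / sd, Xs, rtol=1e-12)


def test_autoscale_uses_sample_sd():
    col = np.array([[1.0], [2.0], [3.0]])
    _, _, sd = autoscale(col)
    assert sd[0] == pytest.approx(1.0)  # ddof=1


def test_autoscaler_zero_variance_column():
    X = np.column_stack([np.ones(5), np.arange(5.0)])
    with pytest.raises(ConstantFeatureError, match="f0"):
        Autoscaler(on_constant="raise").fit(X, feature_ids=["f0", "f1"])
    with pytest.warns(UserWarning):
        s = Autoscaler(on_constant="drop").fit(X)
    assert s.transform(X).shape == (5, 1)


def test_qc_is_metrics():
    table = table_from_replicates({"S1": (1.0, 2.0, 3.0)})
    table.is_area = np.array([100.0, 100.0, 100.0])
    table.is_mz = np.array([609.2812, 609.28729, 609.2812])
    rep = qc_metrics(table)
    assert rep.is_area_rsd == pytest.approx(0.0)
    assert rep.is_ppm_errors[1] == pytest.approx(10.0, abs=0.01)
    assert rep.is_ppm_errors[0] == pytest.approx(0.0)


def test_qc_identical_replicates_correlate_perfectly():
    features = [
        FeatureDescriptor(f"0.50_{100+i}.0000", 0.5, 100.0 + i) for i in range(4)
    ]
    injections = [
        InjectionRecord("S1_r1", "S1", 1, "sample", "hypoxia", 1),
        InjectionRecord("S1_r2", "S1", 2, "sample", "hypoxia", 2),
    ]
    v = np.array([[1.0], [5.0], [2.0], [9.0]])
    table = InjectionTable(features, injections, np.hstack([v, v]))
    rep = qc_metrics(table)
    assert rep.replicate_correlations["S1"] == [pytest.approx(1.0)]
    assert rep.is_area_rsd is None  # unavailable, not zero


def test_qc_on_synthetic_emulates_study_quality(paper_dataset):
    table, _ = paper_dataset
    rep = qc_metrics(table)
    assert 8.0 < rep.is_area_rsd < 20.0
    assert max(abs(p) for p in rep.is_ppm_errors) <= 10.0 + 1e-9
    rs = [v for vs in rep.replicate_correlations.values() for v in vs]
    assert np.median(rs) > 0.9


def test_qc_without_is_channel_reports_unavailable(paper_dataset):
    table, _ = paper_dataset
    stripped = InjectionTable(
        table.features, table.injections, table.intensity, None, None
    )
    rep = qc_metrics(stripped)
    assert rep.is_area_rsd is None and rep.is_ppm_errors is None
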