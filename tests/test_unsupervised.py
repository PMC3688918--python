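import numpy as np
import pytest
from scipy import linalg, stats

from hypoxmet.errors import ValidationError
from hypoxmet.unsupervised import Dendrogram, PCAOutlierModel, limits_95, ward_hca


def lance_williams_ward_heights(X):
    """Brute-force Ward agglomeration via the Lance-Williams recurrence on
    squared Euclidean distances; returns sorted merge heights."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    sizes = {i: 1 for i in range(n)}
    d2 = {
        (i, j): float(((X[i] - X[j]) ** 2).sum())
        for i in range(n)
        for j in range(i + 1, n)
    }
    heights = []
    nid = n
    while len(sizes) > 1:
        (a, b), m = min(d2.items(), key=lambda kv: (kv[1], kv[0]))
        heights.append(np.sqrt(m))
        na, nb = sizes.pop(a), sizes.pop(b)
        updated = {}
        for k, nk in sizes.items():
            dka = d2[tuple(sorted((k, a)))]
            dkb = d2[tuple(sorted((k, b)))]
            updated[k] = ((na + nk) * dka + (nb + nk) * dkb - nk * m) / (
                na + nb + nk
            )
        d2 = {kk: v for kk, v in d2.items() if a not in kk and b not in kk}
        for k, v in updated.items():
            d2[tuple(sorted((k, nid)))] = v
        sizes[nid] = na + nb
        nid += 1
    return np.sort(heights)


def test_rank_one_data_single_component(rng):
    v = rng.normal(size=6)
    X = np.outer(rng.normal(size=8), v)
    model = PCAOutlierModel(n_components=1, scale=False, center=False).fit(X)
    assert model.explained_variance_ratio_[0] == pytest.approx(1.0)


def test_explained_variance_is_complete(rng):
    X = rng.normal(size=(10, 20))
    model = PCAOutlierModel(n_components=3).fit(X)
    assert model.explained_variance_ratio_full_.sum() == pytest.approx(1.0)
    assert np.all(np.diff(model.explained_variance_ratio_full_) <= 1e-12)


def test_eigenvalues_match_dense_eigensolver(rng):
    X = rng.normal(size=(12, 7))
    model = PCAOutlierModel(n_components=5, scale=True).fit(X)
    Xs = model.scaler_.transform(X)
    lam = np.sort(linalg.eigh(Xs.T @ Xs / (X.shape[0] - 1))[0])[::-1]
    np.testing.assert_allclose(model.eigenvalues_[:7], lam, atol=1e-10)


def test_scores_equal_projection_and_are_uncorrelated(rng):
    X = rng.normal(size=(15, 9))
    model = PCAOutlierModel(n_components=4).fit(X)
    Xs = model.scaler_.transform(X)
    np.testing.assert_allclose(model.scores_, Xs @ model.loadings_, atol=1e-12)
    cov = np.cov(model.scores_.T)
    np.testing.assert_allclose(cov - np.diag(np.diag(cov)), 0.0, atol=1e-10)


def test_q_statistic_reconstruction(rng):
    X = rng.normal(size=(12, 6))
    model = PCAOutlierModel(n_components=3).fit(X)
    Xs = model.scaler_.transform(X)
    # explicit reconstruction oracle
    L = model.loadings_
    q_oracle = np.sum((Xs - Xs @ L @ L.T) ** 2, axis=1)
    np.testing.assert_allclose(model.q_statistic(X), q_oracle, atol=1e-10)
    # a row inside the model subspace has Q = 0
    inside = model.scaler_.inverse_transform((Xs @ L @ L.T)[0])
    assert model.q_statistic(inside)[0] == pytest.approx(0.0, abs=1e-12)


def test_full_rank_model_has_zero_training_residuals(rng):
    X = rng.normal(size=(8, 4))
    model = PCAOutlierModel(n_components=4).fit(X)
    np.testing.assert_allclose(model.q_statistic(X), 0.0, atol=1e-12)


def test_t2_statistic_properties(rng):
    X = rng.normal(size=(11, 6))
    model = PCAOutlierModel(n_components=3).fit(X)
    n, A = X.shape[0], 3
    # centroid row maps to zero scores
    assert model.t2_statistic(X.mean(axis=0))[0] == pytest.approx(0.0, abs=1e-18)
    # brute-force oracle: sum over PCs of t^2 / score variance (ddof=1)
    t = model.transform(X)
    lam = t.var(axis=0, ddof=1)
    np.testing.assert_allclose(
        model.t2_statistic(X), np.sum(t**2 / lam, axis=1), atol=1e-10
    )
    # with the n-1 convention the training mean T^2 is A(n-1)/n exactly
    assert model.t2_statistic(X).mean() == pytest.approx(A * (n - 1) / n)
    # quadratic form: doubling a centered row quadruples T^2
    xc = X[0] - X.mean(axis=0)
    if not model.scale:  # pragma: no cover - guard
        pass
    m2 = PCAOutlierModel(n_components=2, scale=False).fit(X)
    base = m2.t2_statistic(X.mean(axis=0) + xc)[0]
    assert m2.t2_statistic(X.mean(axis=0) + 2 * xc)[0] == pytest.approx(4 * base)


def test_q_t2_invariant_to_feature_permutation(rng):
    X = rng.normal(size=(10, 8))
    perm = rng.permutation(8)
    m1 = PCAOutlierModel(n_components=3).fit(X)
    m2 = PCAOutlierModel(n_components=3).fit(X[:, perm])
    np.testing.assert_allclose(m1.q_statistic(X), m2.q_statistic(X[:, perm]), atol=1e-9)
    np.testing.assert_allclose(
        m1.t2_statistic(X), m2.t2_statistic(X[:, perm]), atol=1e-9
    )


def test_t2_limit_formula_instance():
    q_lim, t2_lim = limits_95(np.array([0.5, 0.3, 0.2]), A=1, n=10)
    expected = (1 * 9 * 11) / (10 * 9) * stats.f.ppf(0.95, 1, 9)
    assert t2_lim == pytest.approx(expected)
    assert q_lim > 0


def test_limit_coverage_on_multivariate_normal():
    """Empirical 95% coverage of the T^2 and Q limits on MVN data
    (2000 simulated datasets, n=50, p=5, A=2)."""
    rng = np.random.default_rng(7)
    cov_t2, cov_q = [], []
    scales = np.array([3.0, 2.0, 1.0, 0.5, 0.25])
    for _ in range(2000):
        X = rng.normal(size=(50, 5)) * scales
        model = PCAOutlierModel(n_components=2, scale=False).fit(X)
        cov_t2.append(np.mean(model.t2_statistic(X) <= model.t2_limit_95_))
        cov_q.append(np.mean(model.q_statistic(X) <= model.q_limit_95_))
    assert np.mean(cov_t2) == pytest.approx(0.95, abs=0.02)
    assert np.mean(cov_q) == pytest.approx(0.95, abs=0.03)


def two_component_data(rng):
    t1 = rng.normal(size=20)
    t2 = rng.normal(size=20)
    return (
        np.outer(t1, rng.normal(size=8)) * 3
        + np.outer(t2, rng.normal(size=8)) * 2
        + rng.normal(size=(20, 8)) * 0.05
    )


def test_loo_cv_picks_informative_rank(rng):
    # two strong orthogonal directions + tiny noise: LOO-CV should keep 2
    model = PCAOutlierModel(n_components="loo-cv", scale=False).fit(
        two_component_data(rng)
    )
    assert model.n_components_ == 2


def test_loo_cv_press_matches_brute_force(rng):
    """The Sherman-Morrison element-wise PRESS equals an explicit
    leave-one-variable-out least-squares oracle."""
    from hypoxmet.unsupervised import loo_cv_press

    X = two_component_data(rng)
    press = loo_cv_press(X, 4, scale=False)
    n, p = X.shape
    oracle = np.zeros(4)
    for i in range(n):
        rest = np.delete(X, i, axis=0)
        mu = rest.mean(axis=0)
        _, _, Vt = np.linalg.svd(rest - mu, full_matrices=False)
        xi = X[i] - mu
        for a in range(1, 5):
            L = Vt[:a].T
            for j in range(p):
                t = np.linalg.lstsq(
                    np.delete(L, j, axis=0), np.delete(xi, j), rcond=None
                )[0]
                oracle[a - 1] += (xi[j] - L[j] @ t) ** 2
    np.testing.assert_allclose(press, oracle, rtol=1e-8)


def test_n_components_beyond_rank_rejected(rng):
    X = rng.normal(size=(5, 10))
    with pytest.raises(ValidationError):
        PCAOutlierModel(n_components=5).fit(X)


def test_two_points_merge_at_their_distance():
    X = np.array([[0.0, 0.0], [3.0, 4.0]])
    dend = ward_hca(X)
    assert dend.merge_heights[0] == pytest.approx(5.0)


def test_two_separated_blobs_split_at_top(rng):
    a = rng.normal(0.0, 1.0, (5, 3))
    b = rng.normal(0.0, 1.0, (5, 3)) + 30.0  # ~10 SD apart per axis
    dend = ward_hca(np.vstack([a, b]))
    top_cut = dend.cut(2)
    assert len(set(top_cut[:5])) == 1 and len(set(top_cut[5:])) == 1
    assert top_cut[0] != top_cut[5]


def test_ward_heights_match_lance_williams_oracle(rng):
    X = rng.normal(size=(9, 4))
    dend = ward_hca(X)
    np.testing.assert_allclose(
        np.sort(dend.merge_heights), lance_williams_ward_heights(X), rtol=1e-10
    )


def test_ward_heights_monotone(rng):
    X = rng.normal(size=(12, 5))
    dend = ward_hca(X)
    assert np.all(np.diff(dend.merge_heights) >= -1e-12)


def test_newick_export_has_all_leaves():
    X = np.arange(8.0).reshape(4, 2)
    dend = ward_hca(X, labels=["a", "b", "c", "d"])
    nwk = dend.to_newick()
    assert nwk.endswith(";")
    for leaf in "abcd":
        assert leaf in nwk
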