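"""Cross-validation engine, its building blocks, and the group statistics."""

import numpy as np
import pytest

from hyperconn import predict as pr


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


# ---------------------------------------------------------------------------
# k-fold splits


@pytest.mark.parametrize(
    "n,k,train,test", [(16, 4, 12, 4), (48, 3, 32, 16), (10, 5, 8, 2)]
)
def test_kfold_sizes(n, k, train, test):
    folds = pr.kfold_split(n, k, 0)
    assert len(folds) == k
    all_test = []
    for tr, te in folds:
        assert len(tr) == train and len(te) == test
        assert len(np.intersect1d(tr, te)) == 0
        all_test.append(te)
    np.testing.assert_array_equal(np.sort(np.concatenate(all_test)), np.arange(n))


def test_kfold_deterministic_and_rejects():
    a = pr.kfold_split(20, 4, 7)
    b = pr.kfold_split(20, 4, 7)
    assert all(
        np.array_equal(x[0], y[0]) and np.array_equal(x[1], y[1])
        for x, y in zip(a, b)
    )
    with pytest.raises(ValueError):
        pr.kfold_split(3, 4, 0)


# ---------------------------------------------------------------------------
# PCA


def test_pca_line_captures_all_variance(rng):
    t = rng.normal(size=50)
    X = np.outer(t, [1.0, 2.0, -0.5]) + [4.0, 5.0, 6.0]
    scores, loadings, mean = pr.pca_reduce(X, 2)
    assert scores.shape[1] == 1  # rank 1: truncated
    np.testing.assert_allclose(mean, X.mean(axis=0))
    recon = scores @ loadings.T + mean
    np.testing.assert_allclose(recon, X, atol=1e-10)


def test_pca_orthonormal_loadings(rng):
    X = rng.normal(size=(40, 12))
    scores, loadings, _ = pr.pca_reduce(X, 5)
    np.testing.assert_allclose(loadings.T @ loadings, np.eye(5), atol=1e-10)
    variances = scores.var(axis=0)
    assert np.all(np.diff(variances) <= 1e-12)  # decreasing variance


def test_pca_low_rank_truncation(rng):
    basis = rng.normal(size=(3, 20))
    X = rng.normal(size=(100, 3)) @ basis
    scores, loadings, mean = pr.pca_reduce(X, 10)
    assert scores.shape[1] == 3
    np.testing.assert_allclose(scores @ loadings.T + mean, X, atol=1e-9)


def test_pca_rejects_constant_input():
    with pytest.raises(ValueError):
        pr.pca_reduce(np.ones((10, 4)), 2)


# ---------------------------------------------------------------------------
# discriminant axis and selection


def test_discriminant_axis_spherical_clouds(rng):
    """With isotropic within-class scatter the Fisher axis is the mean
    difference direction."""
    mu = np.zeros(6)
    shift = np.array([3.0, -1.0, 0.0, 0.0, 2.0, 0.0])
    x0 = mu + rng.normal(0, 1.0, (400, 6))
    x1 = mu + shift + rng.normal(0, 1.0, (400, 6))
    scores = np.vstack([x0, x1])
    labels = np.array([0] * 400 + [1] * 400)
    a = pr.discriminant_axis(scores, labels)
    cos = abs(a @ shift / np.linalg.norm(shift))
    assert np.degrees(np.arccos(min(1.0, cos))) < 5.0
    assert (x1.mean(0) - x0.mean(0)) @ a > 0  # sign convention


def test_discriminant_axis_label_swap_negates(rng):
    scores = rng.normal(size=(30, 4))
    labels = np.array([0] * 15 + [1] * 15)
    a = pr.discriminant_axis(scores, labels)
    b = pr.discriminant_axis(scores, 1 - labels)
    np.testing.assert_allclose(a, -b, atol=1e-10)
    np.testing.assert_allclose(a**2, b**2, atol=1e-10)  # energies unchanged


def test_discriminant_axis_needs_two_groups(rng):
    with pytest.raises(ValueError):
        pr.discriminant_axis(rng.normal(size=(10, 3)), np.zeros(10))


def test_select_regions_energy_and_ties():
    axis = np.zeros(30)
    axis[[2, 5, 11]] = [1.0, -1.0, 0.5]
    np.testing.assert_array_equal(pr.select_regions(axis, 2), [2, 5])  # sign-blind
    tie = np.ones(17)
    np.testing.assert_array_equal(pr.select_regions(tie, 16), np.arange(16))
    with pytest.raises(ValueError):
        pr.select_regions(axis, 31)


# ---------------------------------------------------------------------------
# linear model


def test_linear_model_exact_recovery(rng):
    X = rng.normal(size=(40, 6))
    beta = rng.normal(size=6)
    y = X @ beta + 2.5
    coef, intercept, dropped = pr.fit_linear_model(X, y)
    np.testing.assert_allclose(coef, beta, atol=1e-10)
    assert intercept == pytest.approx(2.5, abs=1e-10)
    assert len(dropped) == 0
    resid = y - (X @ coef + intercept)
    assert np.all(np.abs(X.T @ resid) < 1e-8)  # normal equations


def test_linear_model_constant_columns_dropped(rng):
    X = np.column_stack([np.full(20, 3.0), rng.normal(size=20)])
    y = 2 * X[:, 1] + 1
    coef, intercept, dropped = pr.fit_linear_model(X, y)
    assert dropped.tolist() == [0]
    assert coef[0] == 0.0
    assert coef[1] == pytest.approx(2.0, abs=1e-10)


def test_linear_model_all_constant_predicts_mean(rng):
    X = np.ones((15, 3))
    y = rng.normal(size=15)
    coef, intercept, dropped = pr.fit_linear_model(X, y)
    assert np.all(coef == 0)
    assert intercept == pytest.approx(y.mean())


def test_linear_model_noise_ladder(rng):
    """Coefficient error shrinks as the noise level drops."""
    X = rng.normal(size=(32, 16))
    beta = rng.normal(size=16)
    errs = []
    for sigma in (2.0, 0.5, 0.05):
        y = X @ beta + rng.normal(0, sigma, 32)
        coef, _, _ = pr.fit_linear_model(X, y)
        errs.append(np.sqrt(np.mean((coef - beta) ** 2)))
    assert errs[0] > errs[1] > errs[2]


# ---------------------------------------------------------------------------
# correlations and rank statistics


def test_pearson_r_values():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    assert pr.pearson_r(a, 2 * a + 1) == pytest.approx(1.0)
    assert pr.pearson_r(a, -a) == pytest.approx(-1.0)
    assert pr.pearson_r(a, [1, 3, 2, 4]) == pytest.approx(0.8)
    with pytest.raises(ValueError):
        pr.pearson_r(a, np.ones(4))
    with pytest.raises(ValueError):
        pr.pearson_r([1, 2], [3, 4])


def test_mann_whitney_exact_small_sample():
    u, p = pr.mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert u == 0.0
    assert p == pytest.approx(0.1)  # 2 / C(6,3)
    u2, p2 = pr.mann_whitney_u([4, 5, 6], [1, 2, 3])
    assert u2 == 9.0 and p2 == pytest.approx(0.1)


def test_mann_whitney_identical_samples():
    _, p = pr.mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert p >= 0.99


def test_mann_whitney_matches_scipy_large_samples(rng):
    from scipy.stats import mannwhitneyu

    for _ in range(10):
        x = rng.normal(size=int(rng.integers(8, 30)))
        y = rng.normal(0.4, 1.2, int(rng.integers(8, 30)))
        u, p = pr.mann_whitney_u(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue), abs=1e-9)


def test_mann_whitney_exact_matches_scipy(rng):
    from scipy.stats import mannwhitneyu

    for _ in range(10):
        x = rng.normal(size=5)
        y = rng.normal(size=6)
        u, p = pr.mann_whitney_u(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert p == pytest.approx(float(ref.pvalue), abs=1e-12)


def test_auroc_values(rng):
    assert pr.auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    assert pr.auroc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)
    assert pr.auroc([1.0, 1.0], [0, 1]) == pytest.approx(0.5)  # tie -> 1/2
    with pytest.raises(ValueError):
        pr.auroc([1.0, 2.0], [1, 1])
    # null calibration
    means = [
        pr.auroc(rng.normal(size=16), np.repeat([0, 1], 8)) for _ in range(400)
    ]
    assert 0.47 < np.mean(means) < 0.53


# ---------------------------------------------------------------------------
# the CV engine


def planted_feature_matrix(rng, n=48, p=30, k_inf=6, sigma=0.0):
    """Two groups shifted on k_inf features; y linear in those features."""
    informative = np.arange(k_inf)
    X = rng.normal(size=(n, p))
    groups = np.repeat(["a", "b"], n // 2)
    X[groups == "b"][:, :0]  # no-op clarity
    X[n // 2:, informative] += 3.0
    beta = np.zeros(p)
    beta[informative] = rng.uniform(1, 2, k_inf)
    y = X @ beta + 100 + rng.normal(0, sigma, n)
    weeks = np.tile([1, 2, 3], n // 3)
    return pr.FeatureMatrix(X, y, groups, weeks, [f"f{i}" for i in range(p)]), informative


def test_cv_noiseless_recovery(rng):
    data, informative = planted_feature_matrix(rng, sigma=0.0)
    cfg = pr.CVConfig(scheme="integral", n_iterations=30, n_components=10,
                      n_selected_regions=6, seed=3)
    res = pr.run_cv_prediction(data, cfg)
    assert res.pooled_r >= 0.99
    top = np.argsort(-res.selection_frequency)[:6]
    assert set(top.tolist()) == set(informative.tolist())


def test_cv_weekly_scheme_filters_subjects(rng):
    data, _ = planted_feature_matrix(rng)
    cfg = pr.CVConfig(scheme="weekly", week=2, n_iterations=5, n_components=5,
                      n_selected_regions=6, seed=1)
    res = pr.run_cv_prediction(data, cfg)
    week2 = np.flatnonzero(data.weeks == 2)
    assert set(np.unique(res.oob_subject).tolist()) <= set(week2.tolist())


def test_cv_deterministic(rng):
    data, _ = planted_feature_matrix(rng, sigma=1.0)
    cfg = pr.CVConfig(scheme="integral", n_iterations=10, n_selected_regions=6, seed=9)
    r1 = pr.run_cv_prediction(data, cfg)
    r2 = pr.run_cv_prediction(data, cfg)
    assert r1.pooled_r == r2.pooled_r
    np.testing.assert_array_equal(r1.oob_pred, r2.oob_pred)
    np.testing.assert_array_equal(r1.selection_frequency, r2.selection_frequency)


def test_cv_no_information_leak(rng):
    """Corrupting held-out rows must not change fitted models: predictions
    for the training-side subjects of other folds stay identical."""
    data, _ = planted_feature_matrix(rng, sigma=1.0)
    cfg = pr.CVConfig(scheme="integral", n_iterations=1, n_selected_regions=6, seed=5)
    res = pr.run_cv_prediction(data, cfg)
    # corrupt one subject's features and score wildly
    folds = pr.kfold_split(len(data.y), cfg.k_folds, np.random.default_rng(cfg.seed))
    victim = folds[0][1][0]  # in the first test fold
    X2 = data.X.copy()
    X2[victim] += 1e3
    y2 = data.y.copy()
    y2[victim] = 1e6
    data2 = pr.FeatureMatrix(X2, y2, data.groups, data.weeks, data.region_names)
    res2 = pr.run_cv_prediction(data2, cfg)
    # the fold holding the victim trains without it: its other held-out
    # subjects must receive identical predictions
    siblings = [s for s in folds[0][1] if s != victim]
    for s in siblings:
        a = res.oob_pred[res.oob_subject == s]
        b = res2.oob_pred[res2.oob_subject == s]
        np.testing.assert_allclose(a, b, atol=1e-8)


def test_cv_leave_one_out_coverage(rng):
    data, _ = planted_feature_matrix(rng, n=12, p=8, k_inf=3, sigma=0.5)
    cfg = pr.CVConfig(scheme="integral", k_folds=12, n_iterations=1,
                      n_components=5, n_selected_regions=3, seed=2)
    res = pr.run_cv_prediction(data, cfg)
    counts = np.bincount(res.oob_subject, minlength=12)
    assert np.all(counts == 1)


def test_cv_column_permutation_equivariance(rng):
    data, _ = planted_feature_matrix(rng, sigma=1.0)
    cfg = pr.CVConfig(scheme="integral", n_iterations=5, n_selected_regions=6, seed=4)
    res = pr.run_cv_prediction(data, cfg)
    perm = np.random.default_rng(1).permutation(data.X.shape[1])
    data_p = pr.FeatureMatrix(
        data.X[:, perm], data.y, data.groups, data.weeks,
        [data.region_names[i] for i in perm],
    )
    res_p = pr.run_cv_prediction(data_p, cfg)
    assert res_p.pooled_r == pytest.approx(res.pooled_r, abs=1e-10)
    np.testing.assert_allclose(
        res_p.selection_frequency, res.selection_frequency[perm], atol=1e-12
    )


def test_cv_rejects_too_few_subjects(rng):
    data, _ = planted_feature_matrix(rng, n=6, p=8, k_inf=2)
    with pytest.raises(ValueError):
        pr.run_cv_prediction(
            data, pr.CVConfig(scheme="integral", k_folds=12, n_iterations=1)
        )
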