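"""Pairwise shrinkage-LDA estimator and the Haufe pattern transform."""

import numpy as np
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from perisacc.lda import (
    balanced_accuracy,
    balanced_accuracy_timecourse,
    fit_lda_timecourse,
    train_pairwise_lda,
    weights_to_patterns,
)


def _two_clouds(n=60, n_ch=8, sep=4.0, seed=0, sep_channel=2):
    rng = np.random.default_rng(seed)
    x = rng.normal(0, 1.0, (2 * n, n_ch))
    y = np.array([1] * n + [3] * n)
    x[:n, sep_channel] += sep / 2
    x[n:, sep_channel] -= sep / 2
    return x, y


def test_axis_aligned_separation_dominant_weight():
    x, y = _two_clouds(sep_channel=5)
    clf = train_pairwise_lda(x, y, (1, 3), 0.0)
    assert np.argmax(np.abs(clf.weights)) == 5
    # sign convention: positive decision assigns the first pair member
    assert clf.predict(x[:5]).tolist() == [1] * 5


def test_no_signal_gives_chance_accuracy():
    rng = np.random.default_rng(2)
    x_tr = rng.normal(size=(200, 8))
    y_tr = np.array([1, 3] * 100)
    clf = train_pairwise_lda(x_tr, y_tr, (1, 3), 0.0)
    x_te = rng.normal(size=(2000, 8))
    y_te = np.array([1, 3] * 1000)
    acc = balanced_accuracy(clf, x_te, y_te)
    assert abs(acc - 0.5) < 0.06


def test_noise_free_epochs_perfectly_separable():
    x, y = _two_clouds(sep=8.0)
    x[:, :] += 0  # clouds already well separated
    clf = train_pairwise_lda(x, y, (1, 3), 0.0)
    assert balanced_accuracy(clf, x, y) == 1.0


def test_min_trials_per_class():
    x = np.zeros((3, 4))
    with pytest.raises(ValueError):
        train_pairwise_lda(x, np.array([1, 1, 3]), (1, 3), 0.0)


def test_labels_outside_pair_rejected():
    x = np.zeros((4, 4))
    with pytest.raises(ValueError):
        train_pairwise_lda(x, np.array([1, 1, 3, 5]), (1, 3), 0.0)


def test_singular_covariance_without_shrinkage():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(10, 64))
    y = np.array([1] * 5 + [3] * 5)
    with pytest.raises(np.linalg.LinAlgError):
        train_pairwise_lda(x, y, (1, 3), 0.0, shrinkage=None)
    clf = train_pairwise_lda(x, y, (1, 3), 0.0, shrinkage="auto")
    assert np.isfinite(clf.weights).all()


def test_agreement_with_sklearn_lsqr_ledoit_wolf():
    """Independent route: sklearn's lsqr/auto LDA and our vectorized
    estimator agree on predictions and weight direction."""
    rng = np.random.default_rng(7)
    for seed in range(3):
        x, y = _two_clouds(n=40, n_ch=16, sep=1.5, seed=seed)
        ours = train_pairwise_lda(x, y, (1, 3), 0.0, shrinkage="auto")
        sk = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto").fit(x, y)
        x_test = rng.normal(0, 1.2, (400, 16))
        x_test[:200, 2] += 0.75
        x_test[200:, 2] -= 0.75
        pred_ours = ours.predict(x_test)
        pred_sk = sk.predict(x_test)
        assert (pred_ours == pred_sk).mean() > 0.95
        w_sk = sk.coef_.ravel()
        if sk.classes_[1] != 1:
            w_sk = -w_sk
        cos = np.dot(ours.weights, w_sk) / (
            np.linalg.norm(ours.weights) * np.linalg.norm(w_sk)
        )
        assert cos > 0.95


def test_channel_permutation_invariance():
    """Permuting channels consistently in train and test leaves the
    accuracy unchanged."""
    rng = np.random.default_rng(5)
    x, y = _two_clouds(n=30, sep=1.0, seed=3)
    x_te, y_te = _two_clouds(n=50, sep=1.0, seed=4)
    perm = rng.permutation(x.shape[1])
    clf = train_pairwise_lda(x, y, (1, 3), 0.0)
    clf_p = train_pairwise_lda(x[:, perm], y, (1, 3), 0.0)
    a = balanced_accuracy(clf, x_te, y_te)
    b = balanced_accuracy(clf_p, x_te[:, perm], y_te)
    assert a == pytest.approx(b)


def test_timecourse_fit_matches_single_timepoint():
    rng = np.random.default_rng(9)
    x = rng.normal(size=(40, 8, 5))
    x[:20, 3, :] += 1.0
    y = np.array([1] * 20 + [3] * 20)
    w, b = fit_lda_timecourse(x, y, (1, 3))
    for t in range(5):
        single = train_pairwise_lda(x[:, :, t], y, (1, 3), 0.0)
        np.testing.assert_allclose(single.weights, w[t], rtol=1e-10)
        assert single.bias == pytest.approx(b[t])
    acc = balanced_accuracy_timecourse(w, b, x, y, (1, 3))
    assert acc.shape == (5,)
    assert (acc > 0.7).all()


def test_pattern_identity_covariance_proportional_to_weights():
    clf = train_pairwise_lda(*_two_clouds(sep=3.0)[:2], (1, 3), 0.0)
    p = weights_to_patterns(clf, np.eye(8))
    w = clf.weights / np.linalg.norm(clf.weights)
    np.testing.assert_allclose(np.abs(p), np.abs(w), atol=1e-12)


def test_pattern_invariant_to_covariance_scale():
    rng = np.random.default_rng(11)
    clf = train_pairwise_lda(*_two_clouds(sep=2.0)[:2], (1, 3), 0.0)
    a = rng.normal(size=(8, 8))
    cov = a @ a.T + np.eye(8)
    p1 = weights_to_patterns(clf, cov)
    p2 = weights_to_patterns(clf, 13.7 * cov)
    np.testing.assert_allclose(p1, p2, atol=1e-12)


def test_pattern_recovers_generating_topography():
    """On data generated as a topography difference plus noise, the Haufe
    pattern correlates > 0.9 with the generating difference even when the
    raw weights do not."""
    rng = np.random.default_rng(13)
    n_ch, n = 32, 400
    t_a = rng.normal(size=n_ch)
    t_b = rng.normal(size=n_ch)
    mix = rng.normal(size=(n_ch, n_ch)) * 0.3 + np.eye(n_ch)
    noise = rng.normal(size=(2 * n, n_ch)) @ mix.T
    x = noise.copy()
    x[:n] += t_a
    x[n:] += t_b
    y = np.array([1] * n + [3] * n)
    clf = train_pairwise_lda(x, y, (1, 3), 0.0)
    cov = np.cov(x.T)
    pattern = weights_to_patterns(clf, cov)
    diff = t_a - t_b
    corr = np.dot(pattern, diff) / (np.linalg.norm(pattern) * np.linalg.norm(diff))
    assert abs(corr) > 0.9
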