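"""Pairwise linear discriminant classifiers on single-timepoint topographies.

Features are the 64 channel amplitudes at one epoch timepoint.  The pooled
(class-centered) covariance is regularized with Ledoit-Wolf analytic
shrinkage, appropriate when trials-per-class is comparable to the channel
count; class priors are taken as equal (accuracies are class-balanced
downstream anyway).  Sign convention: ``w . x + b > 0`` assigns the first
location of the pair, ``<= 0`` the second.

The time-resolved analyses need thousands of such fits per subject, so the
core estimator (:func:`fit_lda_timecourse`) is vectorized over timepoints;
:func:`train_pairwise_lda` is the single-timepoint view of the same
estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class PairwiseClassifier:
    pair: tuple[int, int]
    timepoint_s: float
    weights: np.ndarray  # (n_channels,)
    bias: float

    def decision(self, x: np.ndarray) -> np.ndarray:
        """Decision values for (n_trials, n_channels) features."""
        return x @ self.weights + self.bias

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Predicted location ids (first of pair where decision > 0)."""
        d = self.decision(np.atleast_2d(x))
        return np.where(d > 0, self.pair[0], self.pair[1])


def ledoit_wolf_shrinkage(z: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Ledoit-Wolf (2004) optimal shrinkage intensity, per timepoint.

    ``z`` is (n, ch, T) centered data, ``cov`` the matching (T, ch, ch)
    sample covariances.  Returns the intensity in [0, 1] for shrinking
    toward ``mu * I`` with ``mu = trace(cov) / ch``.
    """
    n, p, n_t = z.shape
    mu = np.trace(cov, axis1=1, axis2=2) / p  # (T,)
    cov2 = np.einsum("tij,tij->t", cov, cov)
    d2 = cov2 - 2 * mu * np.trace(cov, axis1=1, axis2=2) + p * mu**2
    # E ||x x^T - S||^2 estimate
    sq_norms = np.einsum("nct->nt", z**2)  # (n, T) of ||z_n||^2
    beta_bar = (np.einsum("nt->t", sq_norms**2) / n - cov2) / n
    beta2 = np.minimum(np.maximum(beta_bar, 0.0), d2)
    with np.errstate(invalid="ignore", divide="ignore"):
        shrink = np.where(d2 > 0, beta2 / d2, 0.0)
    return np.clip(shrink, 0.0, 1.0)


def fit_lda_timecourse(
    x: np.ndarray,
    labels: np.ndarray,
    pair: tuple[int, int],
    shrinkage: str | float | None = "auto",
) -> tuple[np.ndarray, np.ndarray]:
    """Fit the pairwise LDA independently at every timepoint.

    ``x`` is (n_trials, n_channels, n_times); returns ``(weights, bias)``
    with shapes (n_times, n_channels) and (n_times,) under the fixed sign
    convention (positive decision -> first element of ``pair``).

    Raises
    ------
    ValueError
        If a class has fewer than 2 trials or labels fall outside the pair.
    numpy.linalg.LinAlgError
        If shrinkage is disabled (0/None) with fewer trials than channels
        (singular pooled covariance) - enable shrinkage.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    a, b = pair
    ma, mb = labels == a, labels == b
    n_a, n_b = int(ma.sum()), int(mb.sum())
    if n_a < 2 or n_b < 2:
        raise ValueError(f"need >= 2 trials per class, got {n_a} and {n_b}")
    if n_a + n_b != len(labels):
        raise ValueError("labels contain values outside the pair")
    n, p, n_t = x.shape
    if shrinkage in (None, 0, 0.0) and n < p:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular with fewer trials than channels; "
            "enable shrinkage (e.g. shrinkage='auto')"
        )

    mean_a = x[ma].mean(axis=0)  # (ch, T)
    mean_b = x[mb].mean(axis=0)
    z = x.copy()
    z[ma] -= mean_a
    z[mb] -= mean_b
    cov = np.einsum("nct,ndt->tcd", z, z) / (n - 2)  # (T, ch, ch)

    if shrinkage == "auto":
        lam = ledoit_wolf_shrinkage(np.ascontiguousarray(z), cov)
    else:
        lam = np.full(n_t, float(shrinkage or 0.0))
    mu = np.trace(cov, axis1=1, axis2=2) / p
    eye = np.eye(p)
    cov_shrunk = (1 - lam)[:, None, None] * cov + (lam * mu)[:, None, None] * eye

    diff = (mean_a - mean_b).T  # (T, ch)
    weights = np.linalg.solve(cov_shrunk, diff[..., None])[..., 0]  # (T, ch)
    mid = ((mean_a + mean_b) / 2).T
    bias = -np.einsum("tc,tc->t", weights, mid)
    return weights, bias


def train_pairwise_lda(
    features: np.ndarray,
    labels: np.ndarray,
    pair: tuple[int, int],
    timepoint_s: float,
    shrinkage: str | float | None = "auto",
) -> PairwiseClassifier:
    """Fit an LDA on single-timepoint features for one location pair.

    ``features`` is (n_trials, n_channels); ``labels`` holds location ids,
    all of which must be members of ``pair``.
    """
    w, b = fit_lda_timecourse(
        np.asarray(features, dtype=float)[:, :, None], labels, pair, shrinkage
    )
    return PairwiseClassifier(
        pair=tuple(pair), timepoint_s=timepoint_s, weights=w[0], bias=float(b[0])
    )


def balanced_accuracy(
    clf: PairwiseClassifier, features: np.ndarray, labels: np.ndarray
) -> float:
    """Unweighted mean of per-class accuracies of the pair classifier."""
    pred = clf.predict(features)
    accs = []
    for cls in clf.pair:
        m = labels == cls
        if m.any():
            accs.append(float((pred[m] == cls).mean()))
    return float(np.mean(accs))


def balanced_accuracy_timecourse(
    weights: np.ndarray,
    bias: np.ndarray,
    x: np.ndarray,
    labels: np.ndarray,
    pair: tuple[int, int],
) -> np.ndarray:
    """Balanced accuracy per timepoint for a bank of per-timepoint LDAs.

    ``x`` is (n_trials, n_channels, n_times); ``weights``/``bias`` as
    returned by :func:`fit_lda_timecourse`.
    """
    dec = np.einsum("nct,tc->nt", x, weights) + bias[None, :]
    pred_a = dec > 0
    accs = []
    for is_a, cls in ((True, pair[0]), (False, pair[1])):
        m = labels == cls
        if m.any():
            accs.append((pred_a[m] == is_a).mean(axis=0))
    return np.mean(accs, axis=0)


def weights_to_patterns(
    clf: PairwiseClassifier, channel_covariance: np.ndarray
) -> np.ndarray:
    """Activation pattern corresponding to classifier weights (Haufe
    transform): ``pattern = Sigma w``, normalized to unit norm.

    Unlike the weights, the pattern is interpretable as the scalp
    topography of the decoded signal difference.
    """
    p = channel_covariance @ clf.weights
    nrm = np.linalg.norm(p)
    return p / nrm if nrm > 0 else p
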