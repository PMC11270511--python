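"""Ocular-artifact component rejection by the saccade/fixation variance ratio.

The decomposition itself is pluggable (any linear unmixing of the channel
data into component activations will do); the pipeline default is a PCA
computed from the channel covariance, which is deterministic and isolates a
dominant corneoretinal source well.  The selection rule is fixed: a
component is rejected when its mean variance in windows around saccade
onsets (-20 to +10 ms) exceeds its mean variance during fixation windows by
more than the ratio criterion (default 1.10, i.e. "10% greater").
"""

from __future__ import annotations

import logging

import numpy as np

logger = logging.getLogger(__name__)

SACCADE_WINDOW_S = (-0.020, 0.010)


def pca_decomposition(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition-based unmixing of (n_channels, n_samples) data.

    Returns ``(unmixing, mixing)`` with components sorted by decreasing
    variance; ``activations = unmixing @ (data - mean)`` and
    ``data ~= mixing @ activations + mean``.
    """
    mean = data.mean(axis=1, keepdims=True)
    centered = data - mean
    cov = centered @ centered.T / centered.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evecs = evecs[:, order]
    return evecs.T, evecs


def _window_variances(
    acts: np.ndarray, fs: float, windows: list[tuple[float, float]]
) -> np.ndarray:
    """Mean over windows of the per-window activation variance."""
    n = acts.shape[1]
    per_window = []
    for w0, w1 in windows:
        i0, i1 = int(round(w0 * fs)), int(round(w1 * fs))
        i0, i1 = max(i0, 0), min(i1, n)
        if i1 - i0 < 2:
            continue
        per_window.append(acts[:, i0:i1].var(axis=1))
    if not per_window:
        raise ValueError("no usable windows")
    return np.mean(per_window, axis=0)


def select_ocular_components(
    activations: np.ndarray,
    saccade_onsets_s: np.ndarray,
    fixation_windows_s: list[tuple[float, float]],
    fs: float,
    ratio: float = 1.10,
    saccade_window_s: tuple[float, float] = SACCADE_WINDOW_S,
) -> list[int]:
    """Indices of components to reject by the variance-ratio criterion.

    ``activations`` is (n_components, n_samples).  Components whose
    fixation variance is zero are flagged degenerate (logged) and kept.
    """
    sacc_windows = [
        (t + saccade_window_s[0], t + saccade_window_s[1])
        for t in np.asarray(saccade_onsets_s, dtype=float)
    ]
    if not sacc_windows or not fixation_windows_s:
        return []
    var_sacc = _window_variances(activations, fs, sacc_windows)
    var_fix = _window_variances(activations, fs, fixation_windows_s)

    rejected: list[int] = []
    for c, (vs, vf) in enumerate(zip(var_sacc, var_fix)):
        if vf == 0:
            logger.warning("component %d has zero fixation variance; kept", c)
            continue
        if vs / vf > ratio:
            rejected.append(c)
    return rejected


def remove_components(
    data: np.ndarray,
    unmixing: np.ndarray,
    mixing: np.ndarray,
    rejected: list[int],
) -> np.ndarray:
    """Reconstruct the channel data without the rejected components."""
    if not rejected:
        return data
    mean = data.mean(axis=1, keepdims=True)
    acts = unmixing @ (data - mean)
    acts[rejected] = 0.0
    return mixing @ acts + mean


def fixation_windows_from_schedule(
    schedule, duration_s: float = 0.15
) -> list[tuple[float, float]]:
    """Stable-fixation windows for the variance-ratio denominator.

    For every trial, a pre-stimulus window; for trials without a saccade,
    additionally a post-stimulus window covering the evoked response, so
    that stimulus-evoked components see comparable variance in both window
    classes and are not mistaken for ocular ones.
    """
    out = []
    for _, tr in schedule.iterrows():
        stim = float(tr["stimulus_onset_s"])
        out.append((stim - 0.05 - duration_s, stim - 0.05))
        if tr["condition"] in ("fixation", "control"):
            out.append((stim + 0.10, stim + 0.10 + duration_s))
    return out
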