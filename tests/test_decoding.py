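"""Time-resolved decoding operations: CV, peak selection, generalization
schemes, SSOA binning and difference timecourses."""

import numpy as np
import pandas as pd
import pytest

from perisacc.decoding import (
    DecodingTimecourse,
    accuracy_from_correctness,
    bin_by_ssoa,
    crossval_fixation,
    difference_timecourse,
    find_peak_timepoint,
    per_trial_correctness,
    train_peak_bank,
)
from perisacc.decoding import test_central as central_diagonal
from perisacc.decoding import test_generalization as generalize
from perisacc.epochs import EpochSet
from perisacc.geometry import ALL_PAIRS, HORIZONTAL_PAIRS, build_stimulus_layout
from perisacc.lda import PairwiseClassifier

from conftest import make_gaussian_epochs

TIMES = np.arange(-51, 129) / 256.0


def _topos(seed=0, n_ch=16):
    rng = np.random.default_rng(seed)
    t = rng.normal(size=(9, n_ch))
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def _kernel(times):
    return 5.0 * np.exp(-0.5 * ((times - 0.165) / 0.02) ** 2) * (times >= 0)


@pytest.fixture(scope="module")
def fixation_epochs():
    return make_gaussian_epochs(
        20, [1, 2, 3, 4], _topos(), _kernel, TIMES, noise_sd=1.5, seed=1
    )


# ---------------------------------------------------------------------------
# SSOA bins


def test_sliding_bins_are_26():
    bins = bin_by_ssoa(np.array([150.0]), "sliding")
    assert bins.n_bins == 26
    assert bins.edges_ms[0] == (300.0, 400.0)
    assert bins.edges_ms[-1] == (50.0, 150.0)
    np.testing.assert_allclose(bins.centers_ms, np.arange(350.0, 90.0, -10.0))


def test_fixed_bins_half_open_convention():
    bins = bin_by_ssoa(np.array([100.0, 150.0, 200.0, 250.0, 300.0, 400.0, 450.0]))
    assign = bins.assignment()
    # 100 is outside (100, 200]; 200 belongs to the Short Bin
    assert assign.tolist() == [-1, 0, 0, 1, 1, 2, -1]


def test_sliding_uniform_occupancy():
    """Uniform SSOAs on [100, 400]: each 100 ms sliding bin holds about a
    third of the trials (edge bins extend past the support)."""
    rng = np.random.default_rng(0)
    ssoa = rng.uniform(100, 400, 6000)
    bins = bin_by_ssoa(ssoa, "sliding")
    frac = bins.membership.mean(axis=1)
    inner = [
        f
        for (lo, hi), f in zip(bins.edges_ms, frac)
        if lo >= 100 and hi <= 400
    ]
    np.testing.assert_allclose(inner, 1 / 3, atol=0.025)


# ---------------------------------------------------------------------------
# fixation CV and peak


def test_crossval_recovers_peak_latency(fixation_epochs):
    acc = crossval_fixation(fixation_epochs, k=5, seed=0)
    assert acc.shape == (6, len(TIMES))
    curve = np.nanmean(acc, axis=0)
    idx, t_peak = find_peak_timepoint(TIMES, curve)
    assert abs(t_peak - 0.165) <= 0.010
    assert curve[idx] > 0.8
    # pre-stimulus timepoints hover at chance
    pre = curve[TIMES < -0.05]
    assert abs(pre.mean() - 0.5) < 0.05


def test_label_shuffle_is_at_chance(fixation_epochs):
    rng = np.random.default_rng(3)
    md = fixation_epochs.metadata.copy()
    md["location_id"] = rng.permutation(md["location_id"].to_numpy())
    shuffled = EpochSet(
        fixation_epochs.data,
        fixation_epochs.times,
        fixation_epochs.fs,
        fixation_epochs.alignment,
        md,
    )
    acc = crossval_fixation(shuffled, k=5, seed=0)
    assert abs(np.nanmean(acc) - 0.5) < 0.03


def test_crossval_k_exceeding_class_size():
    eps = make_gaussian_epochs(
        3, [1, 2, 3, 4], _topos(), _kernel, TIMES, noise_sd=1.0, seed=5
    )
    with pytest.raises(ValueError):
        crossval_fixation(eps, k=5, seed=0)


def test_peak_tiebreak_earliest():
    curve = np.zeros(len(TIMES))
    plateau = (TIMES >= 0.1) & (TIMES <= 0.2)
    curve[plateau] = 0.9
    idx, t_peak = find_peak_timepoint(TIMES, curve)
    assert idx == np.flatnonzero(plateau)[0]
    # and the search is restricted to the post-stimulus window
    curve2 = curve.copy()
    curve2[TIMES < 0] = 1.0
    idx2, _ = find_peak_timepoint(TIMES, curve2)
    assert idx2 == idx


# ---------------------------------------------------------------------------
# generalization schemes


def _peripheral_epochs(layout, scheme_topos, n=16, noise=1.0, seed=11):
    """Peripheral test epochs whose patterns are the given per-location
    topographies (index 5..8)."""
    return make_gaussian_epochs(
        n, [5, 6, 7, 8], scheme_topos, _kernel, TIMES, noise_sd=noise, seed=seed
    )


def test_remapped_and_nearest_accuracies_are_complementary(fixation_epochs):
    layout = build_stimulus_layout()
    acc_cv = crossval_fixation(fixation_epochs, k=5, seed=0)
    idx, _ = find_peak_timepoint(TIMES, np.nanmean(acc_cv, axis=0))
    bank = train_peak_bank(fixation_epochs, idx)
    topos = _topos(seed=21)
    test_eps = _peripheral_epochs(layout, topos)
    a_remap = generalize(bank, test_eps, layout, "remapped", HORIZONTAL_PAIRS)
    a_near = generalize(bank, test_eps, layout, "nearest", HORIZONTAL_PAIRS)
    np.testing.assert_allclose(a_remap + a_near, 1.0, atol=1e-12)


def test_confused_peripheral_patterns_decode_below_chance(fixation_epochs):
    """Peripheral responses that partly resemble the confusion target are
    scored below chance under remapped labels near the evoked peak."""
    layout = build_stimulus_layout()
    acc_cv = crossval_fixation(fixation_epochs, k=5, seed=0)
    idx, _ = find_peak_timepoint(TIMES, np.nanmean(acc_cv, axis=0))
    bank = train_peak_bank(fixation_epochs, idx)
    central = _topos()  # same topographies the classifiers were trained on
    mixed = _topos(seed=33).copy()
    for p in (5, 6, 7, 8):
        mixed[p] = 0.5 * mixed[p] + 0.5 * central[layout.nearest_spatiotopic[p]]
    test_eps = _peripheral_epochs(layout, mixed, noise=1.0)
    acc = generalize(bank, test_eps, layout, "remapped", HORIZONTAL_PAIRS)
    assert acc[idx] < 0.4


def test_degenerate_classifier_accuracy_is_class_fraction():
    """A classifier that always answers its first class scores the fraction
    of (balanced) trials whose remapped label is that class."""
    layout = build_stimulus_layout()
    n_t = 10
    bank = {
        ("left", (1, 3)): PairwiseClassifier(
            (1, 3), 0.0, np.zeros(4), bias=1.0
        )
    }
    rng = np.random.default_rng(0)
    data = rng.normal(size=(20, 4, n_t))
    md = pd.DataFrame(
        {
            "location_id": [5, 7] * 10,  # remapped labels 1 and 3, balanced
            "fixation_side": ["left"] * 20,
            "condition": ["control"] * 20,
            "is_catch": [False] * 20,
        }
    )
    eps = EpochSet(data, np.arange(n_t) / 256.0, 256.0, "stimulus_onset", md)
    acc = generalize(bank, eps, layout, "remapped", ((1, 3),))
    np.testing.assert_allclose(acc, 0.5)  # always-1: perfect on 5s, zero on 7s


def test_inapplicable_label_scheme_raises():
    layout = build_stimulus_layout()
    md = pd.DataFrame(
        {
            "location_id": [1],
            "fixation_side": ["left"],
            "condition": ["fixation"],
            "is_catch": [False],
        }
    )
    eps = EpochSet(np.zeros((1, 4, 3)), np.arange(3) / 256.0, 256.0, "stimulus_onset", md)
    with pytest.raises(ValueError):
        per_trial_correctness({}, eps, layout, "remapped", HORIZONTAL_PAIRS)


# ---------------------------------------------------------------------------
# central corresponding-timepoint analysis


def test_central_resubstitution_at_least_cv(fixation_epochs):
    """Training and testing on the same trials upper-bounds held-out CV."""
    cv = crossval_fixation(fixation_epochs, k=5, seed=0)
    resub = central_diagonal(fixation_epochs, fixation_epochs)
    i = np.argmin(np.abs(TIMES - 0.165))
    from perisacc.decoding import _nanmean
    assert _nanmean(resub, axis=0)[i] >= _nanmean(cv, axis=0)[i] - 1e-9


# ---------------------------------------------------------------------------
# differences


def test_difference_timecourse_zero_for_identical():
    acc = np.random.default_rng(0).uniform(0.4, 0.9, (3, 2, 7))
    tc = DecodingTimecourse(acc, np.arange(7) / 256.0, HORIZONTAL_PAIRS)
    d = difference_timecourse(tc, tc)
    np.testing.assert_allclose(d, 0.0)


def test_difference_timecourse_sign():
    t = np.arange(5) / 256.0
    a = DecodingTimecourse(np.full((2, 1, 5), 0.6), t, ((1, 3),))
    b = DecodingTimecourse(np.full((2, 1, 5), 0.45), t, ((1, 3),))
    d = difference_timecourse(a, b)
    assert (d > 0).all()
    np.testing.assert_allclose(d, 0.15)


def test_difference_grid_mismatch_rejected():
    a = DecodingTimecourse(np.zeros((2, 1, 5)), np.arange(5) / 256.0, ((1, 3),))
    b = DecodingTimecourse(np.zeros((2, 1, 6)), np.arange(6) / 256.0, ((1, 3),))
    with pytest.raises(ValueError):
        difference_timecourse(a, b)


def test_averaging_order_is_recorded():
    tc = DecodingTimecourse(np.zeros((1, 1, 2)), np.arange(2.0), ((1, 3),))
    assert tc.averaging_order == ("pairs", "fixation_side", "subjects")
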