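"""Time-resolved pairwise decoding and all train/test generalizations.

All operations here act on a single subject's epochs; cohort assembly and
group inference live in :mod:`perisacc.model`.  Decoding follows a fixed
averaging order: per-class accuracies are averaged within a pair (balanced
accuracy), then over the relevant pairwise comparisons, then over left and
right fixation, and only at the cohort level over subjects.

Label schemes for cross-condition testing:

* ``veridical`` - the presented (retinotopic) location is correct; used for
  fixation cross-validation and central saccade trials.
* ``remapped`` - a peripheral location p counts as correct when the
  classifier assigns its remap partner (the post-saccadic retinotopic
  location, 5->1, 6->2, 7->3, 8->4).  The same correspondence scores
  control trials ("retinotopic position relative to the other fixation
  point").
* ``nearest`` - p counts as correct when assigned its nearest central
  location in screen coordinates (e.g. 5->3).  On the same horizontal-pair
  test set, remapped and nearest accuracies are complementary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .epochs import EpochSet
from .geometry import (
    ALL_PAIRS,
    HORIZONTAL_PAIRS,
    PAIR_CLASSES,
    StimulusLayout,
)
from .lda import (
    PairwiseClassifier,
    balanced_accuracy_timecourse,
    fit_lda_timecourse,
    train_pairwise_lda,
)

SIDES = ("left", "right")

def _nanmean(a, axis=None):
    """np.nanmean without the all-NaN-slice warning (NaN rows are expected
    wherever a pair/side/bin had no evaluable trials)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        return np.nanmean(a, axis=axis)


LABEL_SCHEMES = ("veridical", "remapped", "nearest")


# ---------------------------------------------------------------------------
# containers


@dataclass
class DecodingTimecourse:
    """Accuracy per (subject, comparison, timepoint), chance = 0.5."""

    accuracy: np.ndarray  # (n_subjects, n_comparisons, n_times)
    times: np.ndarray
    comparisons: tuple[tuple[int, int], ...]
    alignment: str = "stimulus_onset"
    label_scheme: str = "veridical"
    averaging_order: tuple[str, ...] = ("pairs", "fixation_side", "subjects")

    @property
    def comparison_classes(self) -> tuple[str, ...]:
        return tuple(PAIR_CLASSES[p] for p in self.comparisons)

    def subject_mean(self, comparison_class: str | None = None) -> np.ndarray:
        """Pair-averaged accuracy per subject: (n_subjects, n_times)."""
        if comparison_class is None:
            sel = np.arange(len(self.comparisons))
        else:
            sel = np.array(
                [
                    i
                    for i, p in enumerate(self.comparisons)
                    if PAIR_CLASSES[p] == comparison_class
                ]
            )
        return _nanmean(self.accuracy[:, sel, :], axis=1)

    def group_mean(self, comparison_class: str | None = None) -> np.ndarray:
        return _nanmean(self.subject_mean(comparison_class), axis=0)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in range(self.accuracy.shape[0]):
            for c, pair in enumerate(self.comparisons):
                for t, time in enumerate(self.times):
                    rows.append(
                        {
                            "subject": s,
                            "comparison": f"{pair[0]}v{pair[1]}",
                            "comparison_class": PAIR_CLASSES[pair],
                            "alignment": self.alignment,
                            "label_scheme": self.label_scheme,
                            "time_s": float(time),
                            "accuracy": float(self.accuracy[s, c, t]),
                        }
                    )
        return pd.DataFrame(rows)


@dataclass
class SSOABins:
    """SSOA bin definition and trial membership.

    ``edges_ms`` are half-open intervals (low, high]; a 200 ms SSOA belongs
    to the Short Bin under the fixed-three scheme.  The sliding scheme has
    26 overlapping 100 ms bins stepped by 10 ms, ordered from long SSOAs
    (center 350 ms) to short (center 100 ms).
    """

    edges_ms: list[tuple[float, float]]
    membership: np.ndarray  # (n_bins, n_trials) bool
    kind: str
    labels: list[str] = field(default_factory=list)

    @property
    def n_bins(self) -> int:
        return len(self.edges_ms)

    @property
    def centers_ms(self) -> np.ndarray:
        return np.array([(lo + hi) / 2 for lo, hi in self.edges_ms])

    def assignment(self) -> np.ndarray:
        """Trial -> bin index (first matching bin; -1 if none)."""
        out = np.full(self.membership.shape[1], -1, dtype=int)
        for b in range(self.n_bins - 1, -1, -1):
            out[self.membership[b]] = b
        return out


def bin_by_ssoa(ssoa_ms: np.ndarray | pd.Series, kind: str = "fixed_three") -> SSOABins:
    """Assign trials to SSOA bins.

    ``kind='fixed_three'``: Short (100, 200], Medium (200, 300], Long
    (300, 400].  ``kind='sliding'``: 100 ms windows stepped by 10 ms from
    (300, 400] down to (50, 150], 26 bins in total.
    """
    if hasattr(ssoa_ms, "to_numpy"):
        ssoa_ms = ssoa_ms.to_numpy()
    ssoa_ms = np.asarray(ssoa_ms, dtype=float)
    if kind == "fixed_three":
        edges = [(100.0, 200.0), (200.0, 300.0), (300.0, 400.0)]
        labels = ["short", "medium", "long"]
    elif kind == "sliding":
        lows = np.arange(300.0, 49.0, -10.0)  # 300, 290, ..., 50
        edges = [(lo, lo + 100.0) for lo in lows]
        labels = [f"bin_{int(lo)}_{int(lo + 100)}" for lo in lows]
    else:
        raise ValueError(f"unknown bin kind {kind!r}")
    membership = np.stack(
        [(ssoa_ms > lo) & (ssoa_ms <= hi) for lo, hi in edges], axis=0
    )
    return SSOABins(edges_ms=edges, membership=membership, kind=kind, labels=labels)


# ---------------------------------------------------------------------------
# fixation cross-validation


def crossval_fixation(
    epochs: EpochSet,
    k: int = 5,
    seed: int = 0,
    shrinkage: str | float | None = "auto",
    pairs: tuple[tuple[int, int], ...] = ALL_PAIRS,
) -> np.ndarray:
    """k-fold CV accuracy per (pair, timepoint) on one subject's fixation
    epochs, computed separately for left/right fixation and averaged.

    Returns an array (n_pairs, n_times); entries are NaN for pairs that
    could not be evaluated on either side (missing class).

    Raises
    ------
    ValueError
        If ``k`` exceeds the smallest class size of an evaluable pair.
    """
    md = epochs.metadata
    locs = md["location_id"].to_numpy()
    sides = md["fixation_side"].to_numpy()
    n_times = len(epochs.times)
    out = np.full((len(SIDES), len(pairs), n_times), np.nan)

    for si, side in enumerate(SIDES):
        for pi, (a, b) in enumerate(pairs):
            idx = np.flatnonzero((sides == side) & ((locs == a) | (locs == b)))
            y = locs[idx]
            n_a, n_b = (y == a).sum(), (y == b).sum()
            if n_a < 2 or n_b < 2:
                continue
            if k > min(n_a, n_b):
                raise ValueError(
                    f"k={k} exceeds smallest class size {min(n_a, n_b)} "
                    f"for pair {(a, b)} ({side})"
                )
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
            folds = list(skf.split(np.zeros(len(y)), y))
            x_all = epochs.data[idx]  # (n, ch, T)
            accs = np.zeros((k, n_times))
            for fi, (tr_i, te_i) in enumerate(folds):
                w, bias = fit_lda_timecourse(x_all[tr_i], y[tr_i], (a, b), shrinkage)
                accs[fi] = balanced_accuracy_timecourse(
                    w, bias, x_all[te_i], y[te_i], (a, b)
                )
            out[si, pi] = accs.mean(axis=0)
    return _nanmean(out, axis=0)


def find_peak_timepoint(
    times: np.ndarray,
    accuracy_curve: np.ndarray,
    window_s: tuple[float, float] = (0.0, 0.5),
) -> tuple[int, float]:
    """Index and time of peak accuracy within the post-stimulus window.

    Ties are broken toward the earliest timepoint (argmax convention).
    """
    mask = (times >= window_s[0]) & (times <= window_s[1])
    idx = np.flatnonzero(mask)
    best = idx[int(np.argmax(accuracy_curve[idx]))]
    return int(best), float(times[best])


# ---------------------------------------------------------------------------
# peak-trained classifier banks and generalization testing


def train_peak_bank(
    epochs: EpochSet,
    peak_index: int,
    shrinkage: str | float | None = "auto",
    pairs: tuple[tuple[int, int], ...] = ALL_PAIRS,
) -> dict[tuple[str, tuple[int, int]], PairwiseClassifier]:
    """Train one classifier per (fixation side, pair) at the peak timepoint,
    using all of the subject's fixation trials."""
    md = epochs.metadata
    locs = md["location_id"].to_numpy()
    sides = md["fixation_side"].to_numpy()
    bank: dict[tuple[str, tuple[int, int]], PairwiseClassifier] = {}
    for side in SIDES:
        for pair in pairs:
            a, b = pair
            idx = np.flatnonzero((sides == side) & ((locs == a) | (locs == b)))
            y = locs[idx]
            if (y == a).sum() < 2 or (y == b).sum() < 2:
                continue
            bank[(side, pair)] = train_pairwise_lda(
                epochs.data[idx, :, peak_index],
                y,
                pair,
                float(epochs.times[peak_index]),
                shrinkage,
            )
    return bank


def map_label(location_id: int, scheme: str, layout: StimulusLayout) -> int:
    """Map a presented location to the label counted as correct."""
    if scheme == "veridical":
        return location_id
    if scheme == "remapped":
        return layout.remap_pairs[location_id]
    if scheme == "nearest":
        return layout.nearest_spatiotopic[location_id]
    raise ValueError(f"unknown label scheme {scheme!r}")


def per_trial_correctness(
    bank: dict,
    test_epochs: EpochSet,
    layout: StimulusLayout,
    label_scheme: str = "remapped",
    pairs: tuple[tuple[int, int], ...] = HORIZONTAL_PAIRS,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-trial, per-timepoint correctness under peak-trained classifiers.

    Every test trial is mapped to its correct label (see ``map_label``) and
    scored against each applicable pair (pairs containing the mapped
    label, with a classifier trained on the trial's fixation side).
    Returns ``(correct, info)`` where ``correct`` is (n_entries, n_times)
    in {0, 1} and ``info`` has columns trial_index, fixation_side, pair,
    mapped_label - one row per (trial, applicable pair).

    Raises
    ------
    ValueError
        If the label scheme cannot map a tested location (e.g. ``remapped``
        on central locations).
    """
    md = test_epochs.metadata
    locs = md["location_id"].to_numpy()
    sides = md["fixation_side"].to_numpy()
    rows = []
    correct_rows = []
    for i in range(test_epochs.n_trials):
        loc = int(locs[i])
        try:
            m = map_label(loc, label_scheme, layout)
        except KeyError as exc:
            raise ValueError(
                f"label scheme {label_scheme!r} inapplicable to location {loc}"
            ) from exc
        for pair in pairs:
            if m not in pair:
                continue
            clf = bank.get((sides[i], pair))
            if clf is None:
                continue
            pred = clf.predict(test_epochs.data[i].T)  # (n_times,)
            correct_rows.append((pred == m).astype(float))
            rows.append(
                {
                    "trial_index": i,
                    "fixation_side": sides[i],
                    "pair": f"{pair[0]}v{pair[1]}",
                    "mapped_label": m,
                }
            )
    correct = (
        np.stack(correct_rows, axis=0)
        if correct_rows
        else np.zeros((0, len(test_epochs.times)))
    )
    return correct, pd.DataFrame(rows)


def accuracy_from_correctness(
    correct: np.ndarray,
    info: pd.DataFrame,
    trial_mask: np.ndarray | None = None,
    pairs: tuple[tuple[int, int], ...] = HORIZONTAL_PAIRS,
    per_pair: bool = False,
) -> np.ndarray:
    """Average correctness into an accuracy timecourse.

    Balanced within pair (unweighted mean over mapped labels), then
    averaged over pairs, then over fixation sides.  ``trial_mask`` (over
    trial indices) restricts to a subset, e.g. one SSOA bin.  Returns
    (n_times,) — or (n_pairs, n_times) with ``per_pair=True`` (sides
    averaged, pairs kept) — with NaN where no trials are available.
    """
    n_times = correct.shape[1] if correct.ndim == 2 else 0
    if len(info) == 0:
        shape = (len(pairs), n_times) if per_pair else (n_times,)
        return np.full(shape, np.nan)
    keep = np.ones(len(info), dtype=bool)
    if trial_mask is not None:
        keep = trial_mask[info["trial_index"].to_numpy()]

    # (side, pair) balanced-accuracy curves
    curves = np.full((len(SIDES), len(pairs), n_times), np.nan)
    for si, side in enumerate(SIDES):
        for pi, pair in enumerate(pairs):
            pname = f"{pair[0]}v{pair[1]}"
            label_curves = []
            for lab in pair:
                m = (
                    keep
                    & (info["fixation_side"] == side).to_numpy()
                    & (info["pair"] == pname).to_numpy()
                    & (info["mapped_label"] == lab).to_numpy()
                )
                if m.any():
                    label_curves.append(correct[m].mean(axis=0))
            if label_curves:
                curves[si, pi] = np.mean(label_curves, axis=0)
    by_pair = _nanmean(curves, axis=0)  # (n_pairs, T), sides averaged
    if per_pair:
        return by_pair
    per_side = _nanmean(curves, axis=1)  # pairs averaged within side
    return _nanmean(per_side, axis=0)


def test_generalization(
    bank: dict,
    test_epochs: EpochSet,
    layout: StimulusLayout,
    label_scheme: str = "remapped",
    pairs: tuple[tuple[int, int], ...] = HORIZONTAL_PAIRS,
    trial_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Accuracy timecourse of peak-trained classifiers on test epochs."""
    correct, info = per_trial_correctness(
        bank, test_epochs, layout, label_scheme, pairs
    )
    return accuracy_from_correctness(correct, info, trial_mask, pairs)


# ---------------------------------------------------------------------------
# central saccade trials: corresponding-timepoint analysis


def test_central(
    fixation_epochs: EpochSet,
    central_epochs: EpochSet,
    shrinkage: str | float | None = "auto",
    pairs: tuple[tuple[int, int], ...] = ALL_PAIRS,
    start_s: float = 0.0,
) -> np.ndarray:
    """Diagonal of the temporal-generalization matrix.

    For every timepoint from ``start_s`` on, classifiers are trained on all
    fixation trials at that timepoint and tested on central saccade trials
    at the same timepoint (veridical labels, all six pairs by default).
    Returns (n_pairs, n_times), NaN before ``start_s``.
    """
    md_f = fixation_epochs.metadata
    locs_f = md_f["location_id"].to_numpy()
    sides_f = md_f["fixation_side"].to_numpy()
    md_c = central_epochs.metadata
    locs_c = md_c["location_id"].to_numpy()
    sides_c = md_c["fixation_side"].to_numpy()
    times = fixation_epochs.times
    if len(central_epochs.times) != len(times) or not np.allclose(
        central_epochs.times, times
    ):
        raise ValueError("fixation and central epochs must share the time grid")

    n_times = len(times)
    t_idx = np.flatnonzero(times >= start_s)
    out = np.full((len(SIDES), len(pairs), n_times), np.nan)
    for si, side in enumerate(SIDES):
        for pi, (a, b) in enumerate(pairs):
            tr = np.flatnonzero((sides_f == side) & ((locs_f == a) | (locs_f == b)))
            te = np.flatnonzero((sides_c == side) & ((locs_c == a) | (locs_c == b)))
            y_tr, y_te = locs_f[tr], locs_c[te]
            if (
                (y_tr == a).sum() < 2
                or (y_tr == b).sum() < 2
                or len(te) == 0
            ):
                continue
            w, bias = fit_lda_timecourse(
                fixation_epochs.data[tr], y_tr, (a, b), shrinkage
            )
            acc = balanced_accuracy_timecourse(
                w, bias, central_epochs.data[te], y_te, (a, b)
            )
            out[si, pi, t_idx] = acc[t_idx]
    return _nanmean(out, axis=0)


# ---------------------------------------------------------------------------
# differences


def difference_timecourse(
    a: DecodingTimecourse | np.ndarray, b: DecodingTimecourse | np.ndarray
) -> np.ndarray:
    """Per-subject, per-timepoint accuracy difference a - b.

    Accepts (subjects, times) arrays or DecodingTimecourses (which are
    reduced with ``subject_mean``).  Time grids / shapes must match.
    """
    arr_a = a.subject_mean() if isinstance(a, DecodingTimecourse) else np.asarray(a)
    arr_b = b.subject_mean() if isinstance(b, DecodingTimecourse) else np.asarray(b)
    if isinstance(a, DecodingTimecourse) and isinstance(b, DecodingTimecourse):
        if len(a.times) != len(b.times) or not np.allclose(a.times, b.times):
            raise ValueError("time grids do not match")
    if arr_a.shape != arr_b.shape:
        raise ValueError(f"shape mismatch: {arr_a.shape} vs {arr_b.shape}")
    return arr_a - arr_b
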