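"""Cohort-level model/results interface for the remapping analysis.

:class:`SaccadeRemappingModel` is built from per-subject stimulus-locked
epochs (fixation, control, peripheral-saccade and central-saccade trials)
and a stimulus layout; ``fit()`` runs the full decoding battery and group
Bayes-factor inference and returns a :class:`SaccadeRemappingResults`
carrying the timecourses, difference matrices, evidence categories and a
``summary()`` table.

Per subject, fitting performs:

1. fivefold cross-validated time-resolved pairwise decoding of fixation
   trials (all six pairs, left/right fixation separately, then averaged);
2. peak-timepoint selection (argmax of the pair-averaged curve, 0-500 ms,
   ties to the earliest sample) and training of the peak classifier bank;
3. remapped-label testing of control trials and of peripheral saccade
   trials split into Short/Medium/Long SSOA bins and 26 sliding bins
   (horizontal pairs only);
4. corresponding-timepoint decoding of Short-Bin central saccade trials
   (train t -> test t, all six pairs, veridical labels).

Group inference applies the JZS Bayes factor across subjects at every
timepoint (null 0.5 for accuracies, 0 for saccade-minus-control
differences) and the BF > 10 mask over the sliding-bin difference matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import BFSettings, BFTimecourse, bf_mask, bf_timecourse, evidence_clusters
from .decoding import (
    _nanmean,
    ALL_PAIRS,
    HORIZONTAL_PAIRS,
    DecodingTimecourse,
    accuracy_from_correctness,
    bin_by_ssoa,
    crossval_fixation,
    find_peak_timepoint,
    per_trial_correctness,
    test_central,
    train_peak_bank,
)
from .epochs import EpochSet
from .geometry import StimulusLayout

FIXED_BIN_LABELS = ("short", "medium", "long")


@dataclass
class SubjectEpochs:
    """One subject's stimulus-locked epochs, split by condition."""

    fixation: EpochSet
    control: EpochSet
    peripheral: EpochSet
    central: EpochSet
    #: optional saccade-locked re-epochings (times relative to the saccade)
    central_offset_locked: EpochSet | None = None
    peripheral_onset_locked: EpochSet | None = None
    peripheral_offset_locked: EpochSet | None = None

    @classmethod
    def from_epochset(cls, epochs: EpochSet) -> "SubjectEpochs":
        md = epochs.metadata
        not_catch = ~md["is_catch"].to_numpy(dtype=bool)
        cond = md["condition"].to_numpy()
        return cls(
            fixation=epochs.select((cond == "fixation") & not_catch),
            control=epochs.select((cond == "control") & not_catch),
            peripheral=epochs.select((cond == "saccade_peripheral") & not_catch),
            central=epochs.select((cond == "saccade_central") & not_catch),
        )


class SaccadeRemappingModel:
    """Time-resolved cross-condition decoding model for a cohort.

    Parameters
    ----------
    subjects
        Per-subject :class:`SubjectEpochs` (stimulus-locked, baselined).
    layout
        Task geometry (remap and proximity correspondences).
    k
        Cross-validation folds for fixation decoding.
    shrinkage
        LDA covariance shrinkage ('auto' = Ledoit-Wolf).
    peak_window_s
        Search window for the peak training timepoint.
    """

    def __init__(
        self,
        subjects: list[SubjectEpochs],
        layout: StimulusLayout,
        k: int = 5,
        shrinkage: str | float | None = "auto",
        peak_window_s: tuple[float, float] = (0.0, 0.5),
        bf_settings: BFSettings | None = None,
        mask_threshold: float = 10.0,
    ):
        if not subjects:
            raise ValueError("need at least one subject")
        self.subjects = subjects
        self.layout = layout
        self.k = k
        self.shrinkage = shrinkage
        self.peak_window_s = peak_window_s
        self.bf_settings = bf_settings or BFSettings(null_value=0.5)
        self.mask_threshold = mask_threshold
        self.times = subjects[0].fixation.times

    def fit(self, seed: int = 0, inference: bool = True) -> "SaccadeRemappingResults":
        times = self.times
        n_sub = len(self.subjects)
        n_times = len(times)

        cv = np.full((n_sub, len(ALL_PAIRS), n_times), np.nan)
        peak_idx = np.zeros(n_sub, dtype=int)
        peak_s = np.zeros(n_sub)
        control_acc = np.full((n_sub, len(HORIZONTAL_PAIRS), n_times), np.nan)
        bin_acc = np.full((n_sub, 3, n_times), np.nan)
        sliding_acc = np.full((n_sub, 26, n_times), np.nan)
        central_acc = np.full((n_sub, len(ALL_PAIRS), n_times), np.nan)
        bin_counts = np.zeros((n_sub, 3), dtype=int)
        central_offset_acc = None
        central_offset_times = None
        periph_locked_acc: dict[str, np.ndarray] = {}
        periph_locked_times: dict[str, np.ndarray] = {}

        for s, sub in enumerate(self.subjects):
            cv[s] = crossval_fixation(
                sub.fixation, k=self.k, seed=seed + s, shrinkage=self.shrinkage
            )
            curve = _nanmean(cv[s], axis=0)
            peak_idx[s], peak_s[s] = find_peak_timepoint(
                times, curve, self.peak_window_s
            )
            bank = train_peak_bank(
                sub.fixation, peak_idx[s], shrinkage=self.shrinkage
            )

            if sub.control.n_trials:
                c_corr, c_info = per_trial_correctness(
                    bank, sub.control, self.layout, "remapped", HORIZONTAL_PAIRS
                )
                control_acc[s] = accuracy_from_correctness(
                    c_corr, c_info, pairs=HORIZONTAL_PAIRS, per_pair=True
                )

            if sub.peripheral.n_trials:
                p_corr, p_info = per_trial_correctness(
                    bank, sub.peripheral, self.layout, "remapped", HORIZONTAL_PAIRS
                )
                fixed = bin_by_ssoa(sub.peripheral.metadata["ssoa_ms"], "fixed_three")
                sliding = bin_by_ssoa(sub.peripheral.metadata["ssoa_ms"], "sliding")
                bin_counts[s] = fixed.membership.sum(axis=1)
                for b in range(3):
                    bin_acc[s, b] = accuracy_from_correctness(
                        p_corr, p_info, fixed.membership[b], HORIZONTAL_PAIRS
                    )
                for b in range(26):
                    sliding_acc[s, b] = accuracy_from_correctness(
                        p_corr, p_info, sliding.membership[b], HORIZONTAL_PAIRS
                    )

            if sub.central.n_trials:
                cen_bins = bin_by_ssoa(sub.central.metadata["ssoa_ms"], "fixed_three")
                cen_short = sub.central.select(cen_bins.membership[0])
                if cen_short.n_trials:
                    central_acc[s] = test_central(
                        sub.fixation, cen_short, shrinkage=self.shrinkage
                    )

            # saccade-locked variants (times relative to the saccade event)
            if sub.central_offset_locked is not None:
                eps = sub.central_offset_locked
                cb = bin_by_ssoa(eps.metadata["ssoa_ms"], "fixed_three")
                short = eps.select(cb.membership[0])
                if short.n_trials:
                    if central_offset_acc is None:
                        central_offset_acc = np.full((n_sub, len(eps.times)), np.nan)
                        central_offset_times = eps.times
                    corr, inf_ = per_trial_correctness(
                        bank, short, self.layout, "veridical", ALL_PAIRS
                    )
                    central_offset_acc[s] = accuracy_from_correctness(
                        corr, inf_, pairs=ALL_PAIRS
                    )
            for attr, store in (
                ("peripheral_onset_locked", "onset"),
                ("peripheral_offset_locked", "offset"),
            ):
                eps = getattr(sub, attr)
                if eps is None or eps.n_trials == 0:
                    continue
                pb = bin_by_ssoa(eps.metadata["ssoa_ms"], "fixed_three")
                corr, inf_ = per_trial_correctness(
                    bank, eps, self.layout, "remapped", HORIZONTAL_PAIRS
                )
                if store not in periph_locked_acc:
                    periph_locked_acc[store] = np.full(
                        (n_sub, 3, len(eps.times)), np.nan
                    )
                    periph_locked_times[store] = eps.times
                for b in range(3):
                    periph_locked_acc[store][s, b] = accuracy_from_correctness(
                        corr, inf_, pb.membership[b], HORIZONTAL_PAIRS
                    )

        res = SaccadeRemappingResults(
            model=self,
            times=times,
            fixation_cv=DecodingTimecourse(
                cv, times, ALL_PAIRS, label_scheme="veridical"
            ),
            peak_index=peak_idx,
            peak_time_s=peak_s,
            control=DecodingTimecourse(
                control_acc, times, HORIZONTAL_PAIRS, label_scheme="remapped"
            ),
            ssoa_bins=DecodingTimecourse(
                bin_acc,
                times,
                HORIZONTAL_PAIRS,
                label_scheme="remapped",
            ),
            bin_accuracy=bin_acc,
            bin_counts=bin_counts,
            sliding_accuracy=sliding_acc,
            central=DecodingTimecourse(
                central_acc, times, ALL_PAIRS, label_scheme="veridical"
            ),
            central_offset_acc=central_offset_acc,
            central_offset_times=central_offset_times,
            periph_locked_acc=periph_locked_acc,
            periph_locked_times=periph_locked_times,
            seed=seed,
        )
        if inference:
            res.run_inference()
        return res


@dataclass
class SaccadeRemappingResults:
    """Fitted decoding timecourses, differences and Bayes-factor series."""

    model: SaccadeRemappingModel
    times: np.ndarray
    fixation_cv: DecodingTimecourse
    peak_index: np.ndarray
    peak_time_s: np.ndarray
    control: DecodingTimecourse
    ssoa_bins: DecodingTimecourse  # container reuse; accuracy axis 1 = bins
    bin_accuracy: np.ndarray  # (subjects, 3, times)
    bin_counts: np.ndarray
    sliding_accuracy: np.ndarray  # (subjects, 26, times)
    central: DecodingTimecourse
    central_offset_acc: np.ndarray | None = None  # (subjects, times), sacc-offset-locked
    central_offset_times: np.ndarray | None = None
    periph_locked_acc: dict = field(default_factory=dict)
    periph_locked_times: dict = field(default_factory=dict)
    seed: int = 0
    bf_fixation: BFTimecourse | None = None
    bf_control: BFTimecourse | None = None
    bf_bins: dict = field(default_factory=dict)
    bf_bin_diffs: dict = field(default_factory=dict)
    bf_central: BFTimecourse | None = None
    bf_central_offset: BFTimecourse | None = None
    sliding_diff: np.ndarray | None = None  # (subjects, 26, times)
    sliding_mask: np.ndarray | None = None  # (26, times) BF>threshold

    # -- group curves ------------------------------------------------------
    def control_curve(self) -> np.ndarray:
        return self.control.group_mean()

    def bin_curve(self, which: str) -> np.ndarray:
        b = FIXED_BIN_LABELS.index(which)
        return _nanmean(self.bin_accuracy[:, b, :], axis=0)

    def central_curve(self) -> np.ndarray:
        return self.central.group_mean()

    # -- inference ---------------------------------------------------------
    def run_inference(self) -> None:
        chance = self.model.bf_settings
        diff_settings = BFSettings(
            null_value=0.0,
            prior_scale=chance.prior_scale,
            sidedness=chance.sidedness,
        )
        self.bf_fixation = bf_timecourse(
            self.fixation_cv.subject_mean(), self.times, chance
        )
        self.bf_control = bf_timecourse(
            self.control.subject_mean(), self.times, chance
        )
        control_sub = self.control.subject_mean()
        for b, lab in enumerate(FIXED_BIN_LABELS):
            acc = self.bin_accuracy[:, b, :]
            self.bf_bins[lab] = bf_timecourse(acc, self.times, chance)
            self.bf_bin_diffs[lab] = bf_timecourse(
                acc - control_sub, self.times, diff_settings
            )
        self.bf_central = bf_timecourse(
            self.central.subject_mean(), self.times, chance
        )
        if self.central_offset_acc is not None:
            self.bf_central_offset = bf_timecourse(
                self.central_offset_acc, self.central_offset_times, chance
            )
        self.sliding_diff = self.sliding_accuracy - control_sub[:, None, :]
        self.sliding_mask = bf_mask(
            self.sliding_diff, diff_settings, self.model.mask_threshold
        )

    def central_persistence_ms(self, min_len: int = 2) -> float:
        """How long (ms) the pre-saccadic stimulus location stays decodable
        past saccade offset, from the offset-locked central analysis.

        The group accuracy curve holds a plateau while the retinotopic
        trace lasts and collapses to chance afterwards; the estimate is the
        end time of the last run of samples at or above the half-plateau
        level (midway between the pre-offset plateau and chance) among
        runs already present shortly after the offset.  Negative values
        mean decodability collapsed before the eyes landed; NaN means the
        pre-offset plateau itself was not decodable.
        """
        if self.central_offset_acc is None:
            return float("nan")
        times = self.central_offset_times
        curve = _nanmean(self.central_offset_acc, axis=0)
        # light smoothing stabilizes the crossing against sample noise
        kernel = np.ones(3) / 3
        smooth = np.convolve(np.nan_to_num(curve, nan=0.5), kernel, mode="same")
        plateau = np.nanmean(smooth[(times >= -0.05) & (times <= 0.0)])
        if not np.isfinite(plateau) or plateau < 0.52:
            return float("nan")
        thr = 0.5 + (plateau - 0.5) / 2
        in_range = (times >= -0.2) & (times <= 0.35)
        above = (smooth >= thr) & in_range
        runs = evidence_clusters(above, min_len)
        ends = [times[e - 1] for s, e in runs if times[s] <= 0.05]
        if not ends:
            return float("nan")
        return float(max(ends) * 1000.0)

    def bin_alt_clusters(
        self,
        which: str,
        min_len: int = 3,
        window_s: tuple[float, float] = (0.12, 0.45),
    ) -> list[tuple[float, float]]:
        """Sustained above-chance evidence clusters for remapped-label
        decoding in one SSOA bin: runs of at least ``min_len`` consecutive
        timepoints with BF > 3 and group accuracy above chance, inside the
        window where a remapped representation can physically occur (after
        the feedforward visual response, away from the epoch edge).  The
        run-length and window defaults were calibrated once on a
        null (no-remapping) simulation so that isolated one- to two-sample
        Bayes-factor excursions do not count as detections.
        """
        bf = self.bf_bins[which]
        b = FIXED_BIN_LABELS.index(which)
        above = (
            bf.mask("substantial_alt")
            & (_nanmean(self.bin_accuracy[:, b, :], axis=0) > 0.5)
            & (self.times >= window_s[0])
            & (self.times <= window_s[1])
        )
        return [
            (float(self.times[s]), float(self.times[e - 1]))
            for s, e in evidence_clusters(above, min_len)
        ]

    def shortbin_alt_clusters(self, **kw) -> list[tuple[float, float]]:
        return self.bin_alt_clusters("short", **kw)

    def remapping_detected(self) -> bool:
        """Sustained above-chance Short-Bin cluster present?"""
        return len(self.shortbin_alt_clusters()) > 0

    # -- screening ---------------------------------------------------------
    def mean_fixation_accuracy(self) -> np.ndarray:
        """Per-subject fixation CV accuracy averaged over 0-500 ms."""
        sub = self.fixation_cv.subject_mean()
        post = (self.times >= 0) & (self.times <= 0.5)
        return _nanmean(sub[:, post], axis=1)

    # -- summary -----------------------------------------------------------
    def summary(self) -> str:
        times_ms = self.times * 1000
        lines = []
        lines.append("Peri-saccadic decoding summary")
        lines.append("=" * 62)
        lines.append(f"subjects: {len(self.model.subjects)}")
        for cls in ("vertical", "diagonal", "horizontal"):
            g = _nanmean(self.fixation_cv.subject_mean(cls), axis=0)
            i = int(np.nanargmax(np.where(self.times >= 0, g, np.nan)))
            lines.append(
                f"fixation CV peak ({cls:10s}): {g[i] * 100:5.1f}% "
                f"at {times_ms[i]:5.0f} ms"
            )
        lines.append(
            "mean peak training timepoint: "
            f"{np.mean(self.peak_time_s) * 1000:.0f} ms "
            f"(SD {np.std(self.peak_time_s) * 1000:.0f} ms)"
        )
        c = self.control_curve()
        i = int(np.nanargmin(np.where(self.times >= 0, c, np.nan)))
        lines.append(
            f"control (remapped labels, horizontal): min {c[i] * 100:5.1f}% "
            f"at {times_ms[i]:5.0f} ms"
        )
        for lab in FIXED_BIN_LABELS:
            b = self.bin_curve(lab)
            i = int(np.nanargmax(np.where(self.times >= 0.1, b, np.nan)))
            j = int(np.nanargmin(np.where(self.times >= 0, b, np.nan)))
            lines.append(
                f"{lab:6s} bin: peak {b[i] * 100:5.1f}% at {times_ms[i]:5.0f} ms; "
                f"min {b[j] * 100:5.1f}% at {times_ms[j]:5.0f} ms"
            )
        cen = self.central_curve()
        i = int(np.nanargmax(np.where(self.times >= 0, cen, np.nan)))
        lines.append(
            f"central (short-bin) peak: {cen[i] * 100:5.1f}% at {times_ms[i]:5.0f} ms"
        )
        if self.bf_central_offset is not None:
            p = self.central_persistence_ms()
            lines.append(
                f"pre-saccadic location decodable until {p:.0f} ms after saccade offset"
            )
        if self.bf_bins:
            clusters = self.shortbin_alt_clusters()
            if clusters:
                spans = ", ".join(
                    f"{a * 1000:.0f}-{b * 1000:.0f} ms" for a, b in clusters
                )
                lines.append(f"remapping detected: Short-Bin BF>3 clusters at {spans}")
            else:
                lines.append("no remapping detected (no Short-Bin BF>3 cluster)")
        return "\n".join(lines)

    # -- export ------------------------------------------------------------
    def to_frames(self) -> dict[str, pd.DataFrame]:
        """Long-format CSV-ready tables of all timecourses."""
        out = {
            "fixation_cv": self.fixation_cv.to_frame(),
            "control": self.control.to_frame(),
            "central": self.central.to_frame(),
        }
        rows = []
        n_sub = self.bin_accuracy.shape[0]
        for s in range(n_sub):
            for b, lab in enumerate(FIXED_BIN_LABELS):
                for t, time in enumerate(self.times):
                    rows.append(
                        {
                            "subject": s,
                            "bin": lab,
                            "time_s": float(time),
                            "accuracy": float(self.bin_accuracy[s, b, t]),
                        }
                    )
        out["ssoa_bins"] = pd.DataFrame(rows)
        for store, acc in self.periph_locked_acc.items():
            times = self.periph_locked_times[store]
            rows = []
            for s in range(acc.shape[0]):
                for b, lab in enumerate(FIXED_BIN_LABELS):
                    for t, time in enumerate(times):
                        rows.append(
                            {
                                "subject": s,
                                "bin": lab,
                                "alignment": f"saccade_{store}",
                                "time_s": float(time),
                                "accuracy": float(acc[s, b, t]),
                            }
                        )
            out[f"peripheral_saccade_{store}_locked"] = pd.DataFrame(rows)
        return out

    def bf_frame(self) -> pd.DataFrame:
        rows = []

        def add(name, bftc):
            if bftc is None:
                return
            for t, time in enumerate(bftc.times):
                rows.append(
                    {
                        "series": name,
                        "time_s": float(time),
                        "bf": float(bftc.bf[t]),
                        "category": bftc.category[t],
                    }
                )

        add("fixation_cv", self.bf_fixation)
        add("control", self.bf_control)
        for lab, tc in self.bf_bins.items():
            add(f"bin_{lab}", tc)
        for lab, tc in self.bf_bin_diffs.items():
            add(f"bin_{lab}_minus_control", tc)
        add("central", self.bf_central)
        add("central_offset_locked", self.bf_central_offset)
        return pd.DataFrame(rows)

    # -- plotting ----------------------------------------------------------
    def plot_timecourses(self, path=None):
        """Figure with fixation CV, control, SSOA-bin and central curves."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(2, 2, figsize=(11, 7), sharex=True)
        t = self.times * 1000
        ax = axes[0, 0]
        for cls in ("vertical", "diagonal", "horizontal"):
            ax.plot(t, _nanmean(self.fixation_cv.subject_mean(cls), axis=0), label=cls)
        ax.set_title("fixation CV")
        ax = axes[0, 1]
        ax.plot(t, self.control_curve(), color="brown", label="control")
        ax.set_title("control, remapped labels")
        ax = axes[1, 0]
        for lab in FIXED_BIN_LABELS:
            ax.plot(t, self.bin_curve(lab), label=lab)
        ax.plot(t, self.control_curve(), color="brown", ls="--", label="control")
        ax.set_title("peripheral saccade bins, remapped labels")
        ax = axes[1, 1]
        ax.plot(t, self.central_curve(), color="k", label="short bin")
        ax.set_title("central saccade (short bin)")
        for a in axes.ravel():
            a.axhline(0.5, color="gray", lw=0.5)
            a.axvline(0, color="gray", lw=0.5)
            a.legend(fontsize=7)
            a.set_xlabel("time after stimulus onset (ms)")
            a.set_ylabel("accuracy")
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig

    def plot_sliding_matrix(self, path=None):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if self.sliding_diff is None:
            raise RuntimeError("run_inference() first")
        mat = _nanmean(self.sliding_diff, axis=0)
        fig, ax = plt.subplots(figsize=(8, 5))
        centers = np.arange(350, 90, -10)
        im = ax.imshow(
            mat,
            aspect="auto",
            origin="upper",
            extent=[self.times[0] * 1000, self.times[-1] * 1000, centers[-1], centers[0]],
            cmap="RdBu_r",
            vmin=-0.15,
            vmax=0.15,
        )
        if self.sliding_mask is not None:
            ax.contour(
                self.times * 1000,
                centers,
                self.sliding_mask.astype(float),
                levels=[0.5],
                colors="k",
            )
        ax.set_xlabel("time after stimulus onset (ms)")
        ax.set_ylabel("SSOA bin center (ms)")
        ax.set_title("saccade minus control accuracy (BF>10 outlined)")
        fig.colorbar(im, ax=ax, label="accuracy difference")
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig


def screen_subjects(
    mean_fixation_accuracy: np.ndarray, threshold: float = 0.52
) -> np.ndarray:
    """Indices of subjects whose mean fixation decoding passes screening.

    Subjects below the threshold (default 52%) are excluded, mirroring the
    screening-session inclusion rule; the threshold is exposed as a
    parameter.
    """
    acc = np.asarray(mean_fixation_accuracy, dtype=float)
    return np.flatnonzero(acc >= threshold)
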