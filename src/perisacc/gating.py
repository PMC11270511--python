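"""Trial gating by gaze and saccade criteria.

A trial is kept only if it passes, in precedence order:

1. ``no_valid_saccade`` - saccade trials must contain a detected saccade of
   amplitude > 15 dva starting after the cue (within the trial slot).
2. ``stimulus_visible_at_landing`` - on saccade trials the stimulus must
   have left the screen strictly before the eyes land (saccade offset).
3. ``landing_error`` - the saccade must land within 2.5 dva of the saccade
   target (the other fixation point).
4. ``gaze_deviation`` - gaze may not deviate more than 2.5 dva from the
   currently fixated point while the stimulus is on the screen.
5. ``amplitude_artifact`` - optional per-epoch EEG peak-to-peak threshold
   (a deliberately simple stand-in for subspace-reconstruction cleaning).

Exactly one reason (or ``kept``) is recorded per trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eyes import EyeTrace
from .geometry import StimulusLayout
from .saccades import SaccadeEvent, validate_saccade

REASONS = (
    "no_valid_saccade",
    "stimulus_visible_at_landing",
    "landing_error",
    "gaze_deviation",
    "amplitude_artifact",
    "kept",
)

GAZE_LIMIT_DVA = 2.5
LANDING_LIMIT_DVA = 2.5


@dataclass
class RejectionReport:
    """Per-trial keep flag and rejection reason."""

    table: pd.DataFrame  # columns: trial_id, keep, reason

    @property
    def keep_mask(self) -> np.ndarray:
        return self.table["keep"].to_numpy(dtype=bool)

    def counts(self) -> pd.Series:
        return self.table["reason"].value_counts()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _gaze_in_interval(trace: EyeTrace, t0: float, t1: float):
    m = (trace.sample_times_s >= t0) & (trace.sample_times_s < t1) & trace.valid
    return trace.gaze_x_dva[m], trace.gaze_y_dva[m]


def _landing_position(trace: EyeTrace, t_land: float, win_s: float = 0.02):
    x, y = _gaze_in_interval(trace, t_land, t_land + win_s)
    if len(x) == 0:
        return None
    return float(np.mean(x)), float(np.mean(y))


def gate_trials(
    trials: pd.DataFrame,
    trace: EyeTrace,
    saccades: list[SaccadeEvent],
    layout: StimulusLayout,
    epoch_p2p_uv: np.ndarray | None = None,
    p2p_threshold_uv: float = 150.0,
    trial_slot_s: float | None = None,
) -> RejectionReport:
    """Apply the gaze/saccade/amplitude gates to every trial.

    ``epoch_p2p_uv`` is an optional per-trial peak-to-peak EEG amplitude
    (max over channels) aligned with ``trials`` rows.

    Raises
    ------
    ValueError
        If the trace does not cover a trial's stimulus interval.
    """
    if trial_slot_s is None:
        trial_slot_s = (
            float(np.median(np.diff(trials["trial_start_s"])))
            if len(trials) > 1
            else 2.5
        )
    onsets = np.array([ev.onset_s for ev in saccades])

    rows = []
    for i, (_, tr) in enumerate(trials.iterrows()):
        reason = "kept"
        start = float(tr["trial_start_s"])
        stim_on = float(tr["stimulus_onset_s"])
        stim_off = float(tr["stimulus_offset_s"])
        side = tr["fixation_side"]
        fix = layout.fixation_point(side)
        is_sacc_trial = tr["condition"] in ("saccade_central", "saccade_peripheral")

        if trace.sample_times_s[-1] < stim_off or trace.sample_times_s[0] > stim_on:
            raise ValueError(f"eye trace does not cover trial {tr['trial_id']}")

        landing_t = None
        if is_sacc_trial:
            cue = float(tr["cue_onset_s"])
            in_trial = (onsets >= cue) & (onsets < start + trial_slot_s)
            valid_evs = [
                saccades[j] for j in np.flatnonzero(in_trial) if validate_saccade(saccades[j])
            ]
            if not valid_evs:
                reason = "no_valid_saccade"
            else:
                ev = valid_evs[0]
                landing_t = ev.offset_s
                if stim_off >= landing_t:
                    reason = "stimulus_visible_at_landing"
                else:
                    target = layout.fixation_point(
                        "right" if side == "left" else "left"
                    )
                    land = _landing_position(trace, landing_t)
                    if land is None:
                        reason = "no_valid_saccade"
                    elif np.hypot(land[0] - target[0], land[1] - target[1]) > (
                        LANDING_LIMIT_DVA
                    ):
                        reason = "landing_error"

        if reason == "kept":
            x, y = _gaze_in_interval(trace, stim_on, stim_off)
            if len(x) and np.any(
                np.hypot(x - fix[0], y - fix[1]) > GAZE_LIMIT_DVA
            ):
                reason = "gaze_deviation"

        if reason == "kept" and epoch_p2p_uv is not None:
            if epoch_p2p_uv[i] > p2p_threshold_uv:
                reason = "amplitude_artifact"

        rows.append(
            {"trial_id": tr["trial_id"], "keep": reason == "kept", "reason": reason}
        )
    return RejectionReport(pd.DataFrame(rows))
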