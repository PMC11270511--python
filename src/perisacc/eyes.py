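"""Synthetic gaze traces for the saccade task.

Gaze is sampled at 1000 Hz (monocular "left eye" convention).  Fixation
periods show slow drift plus sample noise around the currently fixated
point; saccade trials contain one 20.08 dva horizontal saccade with a
raised-cosine velocity profile whose onset/offset equal the schedule's
ground-truth event times.  Optional microsaccades (<1 dva) and blinks
(validity flag False, NaN position) can be injected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import StimulusLayout

EYE_FS_HZ = 1000.0


@dataclass(frozen=True)
class SaccadeParams:
    """Oculomotor parameters of the generator.

    ``duration_s`` is the saccade duration (raised-cosine velocity profile;
    for a 20 dva saccade the default 45 ms gives a peak velocity near
    890 dva/s, on the human main sequence).  ``noise_sd_dva`` is white
    positional noise per sample; ``drift_sd_dva`` scales a slow random-walk
    drift.  ``microsaccade_rate_hz`` is the Poisson rate of <1 dva
    microsaccades during fixation; ``blink_rate_hz`` the rate of blinks
    (validity gaps) of ``blink_duration_s``.
    """

    duration_s: float = 0.045
    noise_sd_dva: float = 0.02
    drift_sd_dva: float = 0.15
    microsaccade_rate_hz: float = 0.1
    microsaccade_amp_dva: float = 0.4
    blink_rate_hz: float = 0.0
    blink_duration_s: float = 0.150


@dataclass
class EyeTrace:
    """Uniformly sampled gaze trace (degrees of visual angle)."""

    sample_times_s: np.ndarray
    gaze_x_dva: np.ndarray
    gaze_y_dva: np.ndarray
    valid: np.ndarray  # bool; False during blinks
    #: ground-truth onsets of all eye movements (saccades + microsaccades),
    #: used by the forward model to time spike-potential artifacts
    movement_onsets_s: np.ndarray | None = None

    @property
    def fs(self) -> float:
        return 1.0 / float(np.median(np.diff(self.sample_times_s)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.sample_times_s,
                "x_dva": self.gaze_x_dva,
                "y_dva": self.gaze_y_dva,
                "valid": self.valid.astype(int),
            }
        )


def raised_cosine_displacement(t: np.ndarray, duration_s: float) -> np.ndarray:
    """Normalized displacement profile of a raised-cosine-velocity saccade.

    The velocity is v(t) = (1 - cos(2 pi t / D)) / D on [0, D] (unit total
    displacement); this returns its integral, clipped to [0, 1] outside.
    """
    x = np.clip(t / duration_s, 0.0, 1.0)
    return x - np.sin(2 * np.pi * x) / (2 * np.pi)


def _smooth_drift(n: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Slow drift: heavily smoothed random walk, bounded by construction."""
    if sd == 0 or n == 0:
        return np.zeros(n)
    # low-frequency random signal: cumulative noise, high-pass removed
    w = rng.standard_normal(n)
    walk = np.cumsum(w)
    k = min(n, 2001)
    kernel = np.hanning(k)
    kernel /= kernel.sum()
    slow = np.convolve(walk, kernel, mode="same")
    slow -= slow.mean()
    s = slow.std()
    return slow / s * sd if s > 0 else np.zeros(n)


def simulate_session_eye_trace(
    schedule: pd.DataFrame,
    layout: StimulusLayout,
    params: SaccadeParams,
    seed: int,
    fs: float = EYE_FS_HZ,
) -> EyeTrace:
    """Continuous gaze trace spanning a whole scheduled session.

    The eye rests on the fixated point of each trial and executes the
    scheduled saccade (current point -> other point) on saccade trials at the
    ground-truth onset time.
    """
    rng = np.random.default_rng(seed)
    if len(schedule) == 0:
        t = np.zeros(0)
        return EyeTrace(t, t.copy(), t.copy(), np.zeros(0, dtype=bool))

    slot = np.median(np.diff(schedule["trial_start_s"])) if len(schedule) > 1 else 2.5
    t_end = float(schedule["trial_start_s"].iloc[-1]) + float(slot)
    n = int(round(t_end * fs))
    t = np.arange(n) / fs

    x = np.zeros(n)
    y = np.zeros(n)

    # piecewise-constant fixated point, switching at each saccade
    sacc = schedule.dropna(subset=["true_saccade_onset_s"])
    fix_times = [0.0]
    fix_pos = [layout.fixation_point(schedule["fixation_side"].iloc[0])]
    for _, tr in sacc.iterrows():
        side = tr["fixation_side"]
        target = layout.fixation_point("right" if side == "left" else "left")
        fix_times.append(float(tr["true_saccade_onset_s"]))
        fix_pos.append(target)
    fix_times.append(t_end + 1.0)

    for i in range(len(fix_pos)):
        seg = (t >= fix_times[i]) & (t < fix_times[i + 1])
        x[seg] = fix_pos[i][0]
        y[seg] = fix_pos[i][1]

    # replace the step at each saccade by the raised-cosine trajectory
    for _, tr in sacc.iterrows():
        on = float(tr["true_saccade_onset_s"])
        off = float(tr["true_saccade_offset_s"])
        dur = off - on
        side = tr["fixation_side"]
        start = layout.fixation_point(side)
        target = layout.fixation_point("right" if side == "left" else "left")
        seg = (t >= on) & (t < off)
        frac = raised_cosine_displacement(t[seg] - on, dur)
        x[seg] = start[0] + frac * (target[0] - start[0])
        y[seg] = start[1] + frac * (target[1] - start[1])

    # microsaccades: brief (<1 dva) excursions with the same velocity shape,
    # kept away from real saccades by construction (random times may overlap
    # rarely; their amplitude is too small to matter downstream)
    movement_onsets = [float(tr["true_saccade_onset_s"]) for _, tr in sacc.iterrows()]
    if params.microsaccade_rate_hz > 0:
        n_ms = rng.poisson(params.microsaccade_rate_hz * t_end)
        for _ in range(n_ms):
            t0 = rng.uniform(0, t_end - 0.05)
            movement_onsets.append(t0)
            dur = 0.012
            amp = rng.uniform(0.1, params.microsaccade_amp_dva)
            ang = rng.uniform(0, 2 * np.pi)
            seg = (t >= t0) & (t < t0 + 2 * dur)
            ts = t[seg] - t0
            # out-and-back excursion
            frac = raised_cosine_displacement(ts, dur) - raised_cosine_displacement(
                ts - dur, dur
            )
            x[seg] += amp * np.cos(ang) * frac
            y[seg] += amp * np.sin(ang) * frac

    x += _smooth_drift(n, params.drift_sd_dva, rng)
    y += _smooth_drift(n, params.drift_sd_dva, rng)
    x += rng.normal(0, params.noise_sd_dva, n)
    y += rng.normal(0, params.noise_sd_dva, n)

    valid = np.ones(n, dtype=bool)
    if params.blink_rate_hz > 0:
        n_blinks = rng.poisson(params.blink_rate_hz * t_end)
        for _ in range(n_blinks):
            b0 = rng.uniform(0, t_end - params.blink_duration_s)
            seg = (t >= b0) & (t < b0 + params.blink_duration_s)
            valid[seg] = False
            x[seg] = np.nan
            y[seg] = np.nan

    return EyeTrace(t, x, y, valid, np.sort(np.asarray(movement_onsets)))


def simulate_eye_trace(
    trial: pd.Series,
    layout: StimulusLayout,
    params: SaccadeParams,
    seed: int,
    fs: float = EYE_FS_HZ,
) -> EyeTrace:
    """Gaze trace for a single trial (times relative to the session clock)."""
    schedule = pd.DataFrame([trial])
    full = simulate_session_eye_trace(schedule, layout, params, seed, fs=fs)
    start = float(trial["trial_start_s"])
    keep = full.sample_times_s >= start
    return EyeTrace(
        full.sample_times_s[keep],
        full.gaze_x_dva[keep],
        full.gaze_y_dva[keep],
        full.valid[keep],
    )
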