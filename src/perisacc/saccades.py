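"""Velocity-threshold saccade detection (Engbert-Kliegl style).

2-D velocity is estimated with the 5-sample moving-window differentiator
v[i] = (p[i+2] + p[i+1] - p[i-1] - p[i-2]) / (6 dt).  A median-based
standard deviation sigma = sqrt(median(v^2) - median(v)^2) is computed per
axis over all valid samples (blink intervals excluded), and samples whose
velocity lies outside the ellipse (vx/(lambda sx))^2 + (vy/(lambda sy))^2 = 1
for at least ``min_dur_ms`` form candidate saccades.  Candidates closer than
``merge_ms`` to the preceding one are discarded (only the first is kept), to
avoid counting post-saccadic oscillations as separate saccades.  Detected
saccades are only treated as valid task saccades if their amplitude exceeds
15 dva (strict inequality); the low detection threshold itself is meant to
catch microsaccades too, which matter for ocular-artifact correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eyes import EyeTrace

logger = logging.getLogger(__name__)

MIN_VALID_AMPLITUDE_DVA = 15.0


@dataclass(frozen=True)
class SaccadeEvent:
    onset_s: float
    offset_s: float
    amplitude_dva: float
    peak_velocity_dva_s: float

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


def moving_window_velocity(pos: np.ndarray, fs: float) -> np.ndarray:
    """5-sample moving-window velocity estimate (same length as input).

    The two samples at each edge are set to 0.
    """
    n = len(pos)
    if n < 5:
        raise ValueError("trace shorter than the 5-sample differentiator window")
    v = np.zeros(n)
    v[2:-2] = (pos[4:] + pos[3:-1] - pos[1:-3] - pos[:-4]) * (fs / 6.0)
    return v


def _median_sd(v: np.ndarray) -> float:
    med = np.median(v)
    return float(np.sqrt(np.median(v**2) - med**2))


def detect_saccades(
    trace: EyeTrace,
    lam: float = 5.0,
    min_dur_ms: float = 15.0,
    merge_ms: float = 50.0,
) -> list[SaccadeEvent]:
    """Detect saccades in a uniformly sampled gaze trace.

    Returns events sorted by onset.  A constant trace (zero median-based
    velocity SD) yields an empty list with a logged warning.
    """
    fs = trace.fs
    x = np.asarray(trace.gaze_x_dva, dtype=float)
    y = np.asarray(trace.gaze_y_dva, dtype=float)
    valid = np.asarray(trace.valid, dtype=bool)

    # blink samples must not poison the differentiator: interpolate over
    # them for velocity computation but exclude them (and their neighbours)
    # from threshold estimation and from candidate membership
    xf, yf = x.copy(), y.copy()
    if not valid.all():
        idx = np.arange(len(x))
        xf[~valid] = np.interp(idx[~valid], idx[valid], x[valid])
        yf[~valid] = np.interp(idx[~valid], idx[valid], y[valid])
    vx = moving_window_velocity(xf, fs)
    vy = moving_window_velocity(yf, fs)

    usable = valid.copy()
    if not valid.all():
        # dilate the blink mask by the differentiator half-width
        bad = ~valid
        for shift in range(-2, 3):
            usable &= ~np.roll(bad, shift)
    usable[:2] = usable[-2:] = False

    sx = _median_sd(vx[usable])
    sy = _median_sd(vy[usable])
    if sx == 0 or sy == 0:
        logger.warning("zero median-based velocity SD; no saccades detected")
        return []

    crit = (vx / (lam * sx)) ** 2 + (vy / (lam * sy)) ** 2
    above = (crit > 1.0) & usable

    min_samples = int(np.ceil(min_dur_ms / 1000.0 * fs))
    events: list[SaccadeEvent] = []
    # find runs of suprathreshold samples
    d = np.diff(above.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, len(above)]
    speed = np.hypot(vx, vy)
    for s, e in zip(starts, ends):
        if e - s < min_samples:
            continue
        i0, i1 = s, e - 1
        amp = float(np.hypot(xf[i1] - xf[i0], yf[i1] - yf[i0]))
        events.append(
            SaccadeEvent(
                onset_s=float(trace.sample_times_s[i0]),
                offset_s=float(trace.sample_times_s[i1]),
                amplitude_dva=amp,
                peak_velocity_dva_s=float(speed[s:e].max()),
            )
        )

    # merge rule: if the gap to the previous kept event is < merge_ms,
    # keep only the first
    merged: list[SaccadeEvent] = []
    for ev in events:
        if merged and (ev.onset_s - merged[-1].offset_s) * 1000.0 < merge_ms:
            continue
        merged.append(ev)
    return merged


def validate_saccade(
    event: SaccadeEvent, min_amplitude_dva: float = MIN_VALID_AMPLITUDE_DVA
) -> bool:
    """True iff the saccade amplitude strictly exceeds the validity bound."""
    return event.amplitude_dva > min_amplitude_dva


def events_to_frame(events: list[SaccadeEvent], trial_ids=None) -> pd.DataFrame:
    rows = []
    for i, ev in enumerate(events):
        rows.append(
            {
                "onset_s": ev.onset_s,
                "offset_s": ev.offset_s,
                "amplitude_dva": ev.amplitude_dva,
                "peak_velocity_dva_s": ev.peak_velocity_dva_s,
                "trial_id": None if trial_ids is None else trial_ids[i],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["onset_s", "offset_s", "amplitude_dva", "peak_velocity_dva_s", "trial_id"],
    )
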