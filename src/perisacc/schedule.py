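"""Trial schedule generation for the saccade task.

A full experimental session holds 2,400 trials in 5 blocks of 480: per block
224 fixation trials, 224 saccade trials (split evenly between central and
peripheral stimulus placement), and 32 control trials, randomly interleaved.
Grating orientations are evenly spaced between 0 and 150 degrees in 30-degree
steps (6 orientations).  Oddball catch trials occur every 11-20 trials
(uniform) and are flagged, not counted as a separate condition.

Trial timing is laid out on a fixed per-trial slot so that a whole session
can be rendered as one continuous recording.  Fixation and control trials
present the stimulus 400-800 ms after trial onset.  On saccade trials the
saccade cue (gradual fixation-color change) starts 200-600 ms after trial
onset; the stimulus-to-saccade-onset asynchrony (SSOA) is drawn from a
truncated normal (mean 250 ms, SD 80 ms, range 100-400 ms) so that the
short/medium/long SSOA bins are all populated, and the stimulus onset is
placed at saccade onset minus SSOA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

TRIALS_PER_BLOCK = 480
FIXATION_PER_BLOCK = 224
SACCADE_PER_BLOCK = 224
CONTROL_PER_BLOCK = 32
BLOCKS_PER_SESSION = 5
STIMULUS_DURATION_S = 0.100
ORIENTATIONS_DEG = tuple(range(0, 180, 30))  # 0..150 in 30 deg steps

COLUMNS = [
    "trial_id",
    "session",
    "block",
    "condition",
    "is_catch",
    "location_id",
    "orientation_deg",
    "fixation_side",
    "trial_start_s",
    "stimulus_onset_s",
    "stimulus_offset_s",
    "cue_onset_s",
    "true_saccade_onset_s",
    "true_saccade_offset_s",
    "ssoa_ms",
]


@dataclass(frozen=True)
class SSOADistribution:
    """Truncated-normal SSOA distribution (seconds)."""

    mean_s: float = 0.250
    sd_s: float = 0.080
    low_s: float = 0.100
    high_s: float = 0.400

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a = (self.low_s - self.mean_s) / self.sd_s
        b = (self.high_s - self.mean_s) / self.sd_s
        return stats.truncnorm.rvs(
            a, b, loc=self.mean_s, scale=self.sd_s, size=n, random_state=rng
        )


def _balanced_choices(values, n: int, rng: np.random.Generator) -> np.ndarray:
    """n draws spread as evenly as possible over `values`, then shuffled."""
    values = np.asarray(values)
    reps = int(np.ceil(n / len(values)))
    out = np.tile(values, reps)[:n]
    rng.shuffle(out)
    return out


def build_trial_schedule(
    n_sessions: int,
    seed: int,
    *,
    blocks_per_session: int = BLOCKS_PER_SESSION,
    trial_slot_s: float = 2.5,
    ssoa: SSOADistribution | None = None,
    saccade_duration_s: float = 0.045,
    cue_to_saccade_range_s: tuple[float, float] = (0.55, 0.85),
) -> pd.DataFrame:
    """Generate the trial table for ``n_sessions`` sessions.

    Parameters
    ----------
    n_sessions
        Number of sessions; 0 yields an empty table.
    seed
        Seed for all randomness (same seed -> identical table).
    blocks_per_session
        5 for a full 2,400-trial session; smaller values give desk-scale
        sessions with the same per-block composition.
    trial_slot_s
        Duration reserved for each trial in the continuous timeline.
    """
    if n_sessions < 0:
        raise ValueError("n_sessions must be >= 0")
    rng = np.random.default_rng(seed)
    ssoa = ssoa or SSOADistribution()

    rows: list[dict] = []
    t_cursor = 0.0
    trial_id = 0
    side = "left"
    next_catch = int(rng.integers(11, 21))
    for session in range(n_sessions):
        for block in range(blocks_per_session):
            n_sacc_central = SACCADE_PER_BLOCK // 2
            n_sacc_periph = SACCADE_PER_BLOCK - n_sacc_central
            conditions = np.array(
                ["fixation"] * FIXATION_PER_BLOCK
                + ["saccade_central"] * n_sacc_central
                + ["saccade_peripheral"] * n_sacc_periph
                + ["control"] * CONTROL_PER_BLOCK
            )
            rng.shuffle(conditions)
            locs = {
                "fixation": _balanced_choices([1, 2, 3, 4], FIXATION_PER_BLOCK, rng),
                "saccade_central": _balanced_choices([1, 2, 3, 4], n_sacc_central, rng),
                "saccade_peripheral": _balanced_choices(
                    [5, 6, 7, 8], n_sacc_periph, rng
                ),
                "control": _balanced_choices([5, 6, 7, 8], CONTROL_PER_BLOCK, rng),
            }
            counters = {k: 0 for k in locs}
            orientations = _balanced_choices(
                ORIENTATIONS_DEG, TRIALS_PER_BLOCK, rng
            )
            for i, cond in enumerate(conditions):
                loc = int(locs[cond][counters[cond]])
                counters[cond] += 1
                start = t_cursor
                is_catch = False
                next_catch -= 1
                if next_catch == 0:
                    is_catch = True
                    next_catch = int(rng.integers(11, 21))
                row = {
                    "trial_id": trial_id,
                    "session": session,
                    "block": block,
                    "condition": cond,
                    "is_catch": is_catch,
                    "location_id": loc,
                    "orientation_deg": float(orientations[i]),
                    "fixation_side": side,
                    "trial_start_s": start,
                    "cue_onset_s": np.nan,
                    "true_saccade_onset_s": np.nan,
                    "true_saccade_offset_s": np.nan,
                    "ssoa_ms": np.nan,
                }
                if cond in ("fixation", "control"):
                    stim = start + rng.uniform(0.400, 0.800)
                else:
                    cue = start + rng.uniform(0.200, 0.600)
                    sacc_on = cue + rng.uniform(*cue_to_saccade_range_s)
                    ssoa_s = float(ssoa.sample(1, rng)[0])
                    stim = sacc_on - ssoa_s
                    row["cue_onset_s"] = cue
                    row["true_saccade_onset_s"] = sacc_on
                    row["true_saccade_offset_s"] = sacc_on + saccade_duration_s
                    row["ssoa_ms"] = ssoa_s * 1000.0
                    side = "right" if side == "left" else "left"
                row["stimulus_onset_s"] = stim
                row["stimulus_offset_s"] = stim + STIMULUS_DURATION_S
                rows.append(row)
                trial_id += 1
                t_cursor += trial_slot_s
    table = pd.DataFrame(rows, columns=COLUMNS)
    return table
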