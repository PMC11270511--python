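"""Synthetic multichannel EEG with a parameterized remapping effect.

Each trial contributes ``evoked_kernel(t - stimulus_onset) * topography`` to
the continuous recording, where the topography is determined by the
stimulus's *retinotopic* location (position relative to the currently
fixated point).  Three manipulations give the generator the structure the
downstream analyses are designed to detect:

* **proximity confusion** - peripheral stimuli (locations 5-8) evoke a
  mixture ``(1-w) * T_periph(p) + w * T(nearest_central(p))`` so that, e.g.,
  a stimulus at 5 partially drives the pattern of central location 3.  This
  produces below-chance *horizontal* cross-decoding of control trials under
  the remapped-label scheme.
* **remapping** - on peripheral saccade trials whose SSOA falls inside the
  remapping window (default 100-200 ms), a second kernel peaking ~184 ms
  after stimulus onset adds the topography of the remap partner
  ``remap_pairs[p]`` (the post-saccadic retinotopic location).
* **retinotopic trace** - on saccade trials the evoked response is truncated
  ``trace_duration_ms`` after saccade offset (smooth cosine fade), emulating
  the lingering pre-saccadic representation.

Noise is spatially correlated Gaussian; a corneoretinal artifact (a fixed
frontal topography driven by horizontal gaze position) is added so the
ocular-component rejection stage has something real to remove.  Channel
montage: 64 abstract channels, of which a designated block is "occipital"
(where stimulus topographies load most strongly) and the last two are the
"mastoids" used as reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .eyes import EyeTrace
from .geometry import StimulusLayout

EEG_FS_HZ = 256.0
N_CHANNELS = 64
OCCIPITAL_CHANNELS = tuple(range(44, 60))
MASTOID_CHANNELS = (62, 63)


@dataclass(frozen=True)
class ForwardModel:
    """Generator of scalp patterns and response kernels.

    Amplitudes are in microvolts.  ``confusion_weight`` is the fraction of
    the nearest central location's topography mixed into peripheral
    responses.  ``remap_window_ms`` bounds the SSOAs (half-open interval,
    (low, high]) for which the remapped component is injected; setting
    ``remap_gain_uv`` to 0 disables the effect.
    """

    n_channels: int = N_CHANNELS
    occipital: tuple[int, ...] = OCCIPITAL_CHANNELS
    mastoids: tuple[int, ...] = MASTOID_CHANNELS
    evoked_peak_ms: float = 165.0
    evoked_width_ms: float = 20.0
    evoked_gain_uv: float = 6.0
    sustain_gain_uv: float = 4.0
    sustain_end_ms: float = 350.0
    remap_peak_ms: float = 184.0
    remap_width_ms: float = 20.0
    remap_gain_uv: float = 8.0
    remap_window_ms: tuple[float, float] = (100.0, 200.0)
    confusion_weight: float = 0.5
    trace_duration_ms: float = 100.0
    persistence_reference: str = "offset"  # or "onset"
    fade_ms: float = 30.0
    noise_sd_uv: float = 7.5
    noise_spatial_corr: float = 0.3
    eog_gain_uv_per_dva: float = 10.0
    spike_gain_uv: float = 30.0
    spike_width_ms: float = 5.0
    topography_seed: int = 7

    def topographies(self) -> np.ndarray:
        """Unit-norm scalp pattern per retinotopic location id (index 1..8).

        Row 0 is unused; rows 1-8 hold the patterns.  Occipital channels
        load with SD 1.0, all others with SD 0.15, so occipital loadings
        dominate; mastoid loadings are zeroed (they serve as reference).
        Patterns for distinct locations are linearly independent with
        probability 1 (independent Gaussian draws).
        """
        rng = np.random.default_rng(self.topography_seed)
        topo = np.zeros((9, self.n_channels))
        occ = np.zeros(self.n_channels, dtype=bool)
        occ[list(self.occipital)] = True
        for loc in range(1, 9):
            t = rng.normal(0.0, 0.15, self.n_channels)
            t[occ] = rng.normal(0.0, 1.0, occ.sum())
            t[list(self.mastoids)] = 0.0
            topo[loc] = t / np.linalg.norm(t)
        return topo

    def topography(self, location_id: int) -> np.ndarray:
        return self.topographies()[location_id]

    def effective_topography(
        self, location_id: int, layout: StimulusLayout
    ) -> np.ndarray:
        """Topography actually evoked by a stimulus at ``location_id``."""
        topo = self.topographies()
        if location_id in layout.nearest_spatiotopic:
            w = self.confusion_weight
            # unnormalized mixture: activation mass is shared between the
            # peripheral pattern and its nearest central pattern
            return (1 - w) * topo[location_id] + w * topo[
                layout.nearest_spatiotopic[location_id]
            ]
        return topo[location_id]

    def evoked_kernel(self, t_s: np.ndarray) -> np.ndarray:
        """Evoked response kernel (uV) vs time after stimulus onset.

        A transient Gaussian component at ``evoked_peak_ms`` plus a
        sustained plateau (smooth rise over ~100-150 ms, dying out with a
        cosine fade at ``sustain_end_ms``), mirroring the transient +
        sustained decodability of stimulus position.  Zero before stimulus
        onset.
        """
        t = np.asarray(t_s, dtype=float)
        peak = self.evoked_peak_ms / 1000.0
        width = self.evoked_width_ms / 1000.0
        transient = self.evoked_gain_uv * np.exp(-0.5 * ((t - peak) / width) ** 2)
        sustained = self.sustain_gain_uv * np.clip((t - 0.100) / 0.050, 0.0, 1.0)
        sustained = sustained * self.persistence_window(t, self.sustain_end_ms / 1000.0)
        return np.where(t >= 0.0, transient + sustained, 0.0)

    def remap_kernel(self, t_s: np.ndarray) -> np.ndarray:
        """Remapped-component kernel (uV) vs time after stimulus onset."""
        t = np.asarray(t_s, dtype=float)
        peak = self.remap_peak_ms / 1000.0
        width = self.remap_width_ms / 1000.0
        k = self.remap_gain_uv * np.exp(-0.5 * ((t - peak) / width) ** 2)
        return np.where(t >= 0.0, k, 0.0)

    def persistence_window(self, t_s: np.ndarray, cut_s: float) -> np.ndarray:
        """1 until ``cut_s``, cosine fade to 0 over ``fade_ms``."""
        t = np.asarray(t_s, dtype=float)
        fade = self.fade_ms / 1000.0
        w = np.ones_like(t)
        ramp = (t - cut_s) / fade
        w = np.where(t > cut_s, 0.5 * (1 + np.cos(np.pi * np.clip(ramp, 0, 1))), w)
        w[t > cut_s + fade] = 0.0
        return w


def _spatial_mixing(fm: ForwardModel, rng: np.random.Generator) -> np.ndarray:
    """Cholesky factor of the (compound-symmetric) spatial noise covariance."""
    rho = fm.noise_spatial_corr
    cov = np.full((fm.n_channels, fm.n_channels), rho)
    np.fill_diagonal(cov, 1.0)
    return np.linalg.cholesky(cov)


def simulate_session_eeg(
    schedule: pd.DataFrame,
    layout: StimulusLayout,
    fm: ForwardModel,
    eye_trace: EyeTrace | None,
    seed: int,
    fs: float = EEG_FS_HZ,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a continuous 64-channel recording for one scheduled session.

    Returns ``(data, events)`` where ``data`` has shape (n_channels,
    n_samples) in microvolts and ``events`` is the schedule augmented with
    the injected component flags (whether a remapped component was added).

    Raises
    ------
    ValueError
        If the schedule references an unknown stimulus location id.
    """
    if len(schedule) == 0:
        raise ValueError("schedule is empty")
    known = set(layout.stimulus_locations) if layout.stimulus_locations else set(
        range(1, 9)
    )
    bad = set(schedule["location_id"]) - known
    if bad:
        raise ValueError(f"schedule references unknown location ids: {sorted(bad)}")

    rng = np.random.default_rng(seed)
    slot = (
        float(np.median(np.diff(schedule["trial_start_s"])))
        if len(schedule) > 1
        else 2.5
    )
    t_end = float(schedule["trial_start_s"].iloc[-1]) + slot
    n = int(round(t_end * fs))
    t = np.arange(n) / fs

    if fm.noise_sd_uv > 0:
        L = _spatial_mixing(fm, rng)
        data = (L @ rng.standard_normal((fm.n_channels, n))) * fm.noise_sd_uv
    else:
        data = np.zeros((fm.n_channels, n))
    data = data.astype(np.float64)

    topo = fm.topographies()
    remap_added = np.zeros(len(schedule), dtype=bool)
    lo, hi = fm.remap_window_ms

    for i, (_, tr) in enumerate(schedule.iterrows()):
        stim = float(tr["stimulus_onset_s"])
        loc = int(tr["location_id"])
        cond = tr["condition"]
        # local sample window covering the response support
        i0 = max(0, int(np.floor(stim * fs)) - 1)
        i1 = min(n, int(np.ceil((stim + 0.9) * fs)))
        tt = t[i0:i1] - stim

        kern = fm.evoked_kernel(tt)
        if cond in ("saccade_central", "saccade_peripheral"):
            ref = (
                float(tr["true_saccade_offset_s"])
                if fm.persistence_reference == "offset"
                else float(tr["true_saccade_onset_s"])
            )
            cut = (ref - stim) + fm.trace_duration_ms / 1000.0
            kern = kern * fm.persistence_window(tt, cut)
        eff = fm.effective_topography(loc, layout)
        data[:, i0:i1] += np.outer(eff, kern)

        if cond == "saccade_peripheral":
            ssoa = float(tr["ssoa_ms"])
            if lo < ssoa <= hi and fm.remap_gain_uv > 0:
                rkern = fm.remap_kernel(tt)
                data[:, i0:i1] += np.outer(topo[layout.remap_pairs[loc]], rkern)
                remap_added[i] = True

    # ocular artifact: corneoretinal potential following horizontal gaze
    # position plus a brief spike potential at every eye-movement onset
    # (saccades and microsaccades), sharing one frontal topography
    if eye_trace is not None and len(eye_trace.sample_times_s):
        artifact = np.zeros(n)
        if fm.eog_gain_uv_per_dva > 0:
            gx = np.interp(
                t,
                eye_trace.sample_times_s,
                np.nan_to_num(eye_trace.gaze_x_dva, nan=0.0),
            )
            artifact += (gx - np.mean(gx)) * fm.eog_gain_uv_per_dva
        if fm.spike_gain_uv > 0 and eye_trace.movement_onsets_s is not None:
            sw = fm.spike_width_ms / 1000.0
            for on in eye_trace.movement_onsets_s:
                i0 = max(0, int((on - 4 * sw) * fs))
                i1 = min(n, int((on + 4 * sw) * fs) + 1)
                artifact[i0:i1] += fm.spike_gain_uv * np.exp(
                    -0.5 * ((t[i0:i1] - on) / sw) ** 2
                )
        if np.any(artifact):
            data += np.outer(_eog_topography(fm), artifact)

    events = schedule.copy()
    events["remap_component_added"] = remap_added
    return data, events


def _eog_topography(fm: ForwardModel) -> np.ndarray:
    """Fixed frontal-dominant corneoretinal artifact pattern (unit norm)."""
    rng = np.random.default_rng(fm.topography_seed + 1000)
    topo = np.zeros(fm.n_channels)
    frontal = [c for c in range(fm.n_channels) if c not in fm.occipital]
    # dipolar-ish: strong mixed-sign frontal loadings, weak posterior ones
    topo[frontal] = rng.normal(0.0, 1.0, len(frontal))
    topo[list(fm.occipital)] = rng.normal(0.0, 0.1, len(fm.occipital))
    topo[list(fm.mastoids)] = 0.0
    return topo / np.linalg.norm(topo)


def simulate_eeg(
    schedule: pd.DataFrame,
    layout: StimulusLayout,
    fm: ForwardModel,
    seed: int,
    fs: float = EEG_FS_HZ,
    window: tuple[float, float] = (-0.2, 0.5),
    baseline: tuple[float, float] | None = (-0.1, 0.0),
):
    """Stimulus-locked epochs plus the ground-truth event list.

    Convenience wrapper: renders the continuous session (without the ocular
    artifact, which belongs to the full pipeline) and epochs it around
    stimulus onsets.  Returns ``(EpochSet, events)``.
    """
    from .epochs import epoch  # local import to avoid a cycle

    fm_clean = ForwardModel(**{**fm.__dict__, "eog_gain_uv_per_dva": 0.0})
    data, events = simulate_session_eeg(schedule, layout, fm_clean, None, seed, fs=fs)
    es = epoch(
        data,
        fs,
        events["stimulus_onset_s"].to_numpy(),
        alignment="stimulus_onset",
        window=window,
        baseline=baseline,
        metadata=events,
    )
    return es, events
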