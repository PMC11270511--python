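"""End-to-end seeded pipeline: simulate -> preprocess -> decode -> infer.

A :class:`RunConfig` fully determines a run (config + seed -> byte-identical
result tables).  Per synthetic subject the pipeline:

1. builds a trial schedule and renders the 1000 Hz gaze trace and the
   continuous 64-channel EEG (subject-specific topographies, corneoretinal
   artifact driven by horizontal gaze);
2. conditions the EEG (re-reference to mastoids, 50 Hz notch, 0.1-80 Hz
   bandpass at 256 Hz);
3. detects saccades with the velocity-threshold algorithm, rejects ocular
   components by the saccade/fixation variance-ratio rule (PCA
   decomposition by default), and gates trials on gaze, landing, timing
   and peak-to-peak amplitude criteria;
4. epochs the cleaned recording (stimulus-locked; saccade-onset/offset
   locked variants for the saccade-locked analyses);

and then fits the cohort :class:`~perisacc.model.SaccadeRemappingModel`
(decoding + Bayes-factor inference), writes long-format CSVs, figures and
a JSON manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .bayes import BFSettings
from .components import (
    fixation_windows_from_schedule,
    pca_decomposition,
    remove_components,
    select_ocular_components,
)
from .epochs import EpochSet, epoch
from .eyes import SaccadeParams, simulate_session_eye_trace
from .filtering import preprocess_signal
from .forward import ForwardModel, simulate_session_eeg
from .gating import RejectionReport, gate_trials
from .geometry import StimulusLayout, build_stimulus_layout
from .model import (
    SaccadeRemappingModel,
    SaccadeRemappingResults,
    SubjectEpochs,
    screen_subjects,
)
from .saccades import detect_saccades, events_to_frame, validate_saccade
from .schedule import SSOADistribution, build_trial_schedule

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    seed: int = 0
    n_subjects: int = 10
    n_sessions: int = 1
    blocks_per_session: int = 1
    # generator
    forward: dict = field(default_factory=dict)  # ForwardModel overrides
    ssoa: dict = field(default_factory=dict)  # SSOADistribution overrides
    eyes: dict = field(default_factory=dict)  # SaccadeParams overrides
    subject_topographies: bool = True
    # preprocessing
    notch_hz: float = 50.0
    band_hz: tuple[float, float] = (0.1, 80.0)
    detector_lambda: float = 5.0
    detector_min_dur_ms: float = 15.0
    detector_merge_ms: float = 50.0
    ica_ratio: float = 1.10
    p2p_threshold_uv: float = 150.0
    run_component_rejection: bool = True
    # decoding
    k_folds: int = 5
    shrinkage: str | float = "auto"
    peak_window_s: tuple[float, float] = (0.0, 0.5)
    saccade_locked: bool = True
    # screening / inference
    screening_threshold: float = 0.52
    bf_prior_scale: float = float(np.sqrt(2) / 2)
    mask_threshold: float = 10.0
    out_dir: str = "perisacc_out"

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as f:
            json.dump(asdict(self), f, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            d = json.load(f)
        for key in ("band_hz", "peak_window_s"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    def forward_model(self, subject: int) -> ForwardModel:
        fm = ForwardModel(**{k: _detuple(v) for k, v in self.forward.items()})
        if self.subject_topographies:
            fm = replace(fm, topography_seed=fm.topography_seed + 7919 * subject)
        return fm


def _detuple(v):
    return tuple(v) if isinstance(v, list) else v


@dataclass
class SubjectRecord:
    """Everything produced for one subject before cohort fitting."""

    subject: int
    schedule: pd.DataFrame
    saccade_events: pd.DataFrame
    rejection: RejectionReport
    epochs: SubjectEpochs
    n_rejected_components: int


def _subject_seed(seed: int, subject: int, stream: int) -> int:
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(subject, stream))
    return int(ss.generate_state(1)[0] % (2**31))


def process_subject(config: RunConfig, subject: int, layout: StimulusLayout | None = None) -> SubjectRecord:
    """Simulate and preprocess a single synthetic subject."""
    layout = layout or build_stimulus_layout()
    sched = build_trial_schedule(
        config.n_sessions,
        seed=_subject_seed(config.seed, subject, 0),
        blocks_per_session=config.blocks_per_session,
        ssoa=SSOADistribution(**config.ssoa),
    )
    eye_params = SaccadeParams(**config.eyes)
    trace = simulate_session_eye_trace(
        sched, layout, eye_params, seed=_subject_seed(config.seed, subject, 1)
    )
    fm = config.forward_model(subject)
    data, events = simulate_session_eeg(
        sched, layout, fm, trace, seed=_subject_seed(config.seed, subject, 2)
    )
    return preprocess_subject(config, subject, sched, trace, data, fm, layout)


def preprocess_subject(
    config: RunConfig,
    subject: int,
    sched: pd.DataFrame,
    trace,
    data: np.ndarray,
    fm: ForwardModel,
    layout: StimulusLayout,
) -> SubjectRecord:
    """Signal conditioning, saccade detection, gating and epoching."""
    from .forward import EEG_FS_HZ

    data, fs, _prov = preprocess_signal(
        data,
        EEG_FS_HZ,
        mastoid_channels=fm.mastoids,
        notch_hz=config.notch_hz,
        band_hz=config.band_hz,
    )

    saccades = detect_saccades(
        trace,
        lam=config.detector_lambda,
        min_dur_ms=config.detector_min_dur_ms,
        merge_ms=config.detector_merge_ms,
    )
    valid_sacc = [ev for ev in saccades if validate_saccade(ev)]

    n_rejected = 0
    if config.run_component_rejection:
        unmixing, mixing = pca_decomposition(data)
        acts = unmixing @ (data - data.mean(axis=1, keepdims=True))
        rejected = select_ocular_components(
            acts,
            np.array([ev.onset_s for ev in saccades]),
            fixation_windows_from_schedule(sched),
            fs,
            ratio=config.ica_ratio,
        )
        data = remove_components(data, unmixing, mixing, rejected)
        n_rejected = len(rejected)

    # per-trial peak-to-peak amplitude on provisional stimulus-locked epochs
    prov_epochs = epoch(
        data, fs, sched["stimulus_onset_s"].to_numpy(), metadata=sched
    )
    p2p = np.full(len(sched), 0.0)
    kept_ids = prov_epochs.metadata["trial_id"].to_numpy()
    ptp = prov_epochs.data.max(axis=2) - prov_epochs.data.min(axis=2)
    p2p_kept = ptp.max(axis=1)
    id_to_pos = {tid: i for i, tid in enumerate(sched["trial_id"])}
    for tid, v in zip(kept_ids, p2p_kept):
        p2p[id_to_pos[tid]] = v

    report = gate_trials(
        sched,
        trace,
        valid_sacc,
        layout,
        epoch_p2p_uv=p2p,
        p2p_threshold_uv=config.p2p_threshold_uv,
    )
    kept = sched[report.keep_mask].reset_index(drop=True)

    # attach detected saccade times to kept saccade trials for re-epoching
    det_on = np.full(len(kept), np.nan)
    det_off = np.full(len(kept), np.nan)
    onsets = np.array([ev.onset_s for ev in valid_sacc])
    offsets = np.array([ev.offset_s for ev in valid_sacc])
    slot = float(np.median(np.diff(sched["trial_start_s"]))) if len(sched) > 1 else 2.5
    for i, (_, tr) in enumerate(kept.iterrows()):
        if tr["condition"] in ("saccade_central", "saccade_peripheral"):
            m = (onsets >= tr["cue_onset_s"]) & (onsets < tr["trial_start_s"] + slot)
            j = np.flatnonzero(m)
            if len(j):
                det_on[i] = onsets[j[0]]
                det_off[i] = offsets[j[0]]
    kept = kept.assign(det_saccade_onset_s=det_on, det_saccade_offset_s=det_off)

    stim_locked = epoch(
        data, fs, kept["stimulus_onset_s"].to_numpy(), "stimulus_onset", metadata=kept
    )
    sub = SubjectEpochs.from_epochset(stim_locked)

    if config.saccade_locked:
        cond = kept["condition"].to_numpy()
        cen = kept[cond == "saccade_central"]
        per = kept[cond == "saccade_peripheral"]
        sub.central_offset_locked = _epoch_saccade_locked(
            data, fs, cen, "det_saccade_offset_s", "saccade_offset"
        )
        sub.peripheral_onset_locked = _epoch_saccade_locked(
            data, fs, per, "det_saccade_onset_s", "saccade_onset"
        )
        sub.peripheral_offset_locked = _epoch_saccade_locked(
            data, fs, per, "det_saccade_offset_s", "saccade_offset"
        )

    sacc_frame = events_to_frame(saccades)
    return SubjectRecord(
        subject=subject,
        schedule=sched,
        saccade_events=sacc_frame,
        rejection=report,
        epochs=sub,
        n_rejected_components=n_rejected,
    )


def _epoch_saccade_locked(
    data: np.ndarray,
    fs: float,
    trials: pd.DataFrame,
    time_col: str,
    alignment: str,
) -> EpochSet:
    """Saccade-locked re-epoching with the trial's *pre-stimulus* baseline.

    The default baseline window would fall on stimulus-evoked activity when
    epochs are locked to the saccade, so the per-trial, per-channel mean
    over the 100 ms before stimulus onset is subtracted instead.
    """
    trials = trials.reset_index(drop=True)
    eps = epoch(
        data,
        fs,
        trials[time_col].to_numpy(),
        alignment,
        baseline=None,
        metadata=trials,
    )
    if eps.n_trials == 0:
        return eps
    base = np.zeros((eps.n_trials, eps.n_channels))
    for i, stim in enumerate(eps.metadata["stimulus_onset_s"].to_numpy()):
        j0 = int(round((stim - 0.1) * fs))
        j1 = int(round(stim * fs))
        base[i] = data[:, max(j0, 0) : j1].mean(axis=1)
    eps.data = eps.data - base[:, :, None]
    return eps


def run_pipeline(
    config: RunConfig, write: bool = True
) -> tuple[SaccadeRemappingResults, dict]:
    """Execute the full pipeline; returns (results, manifest)."""
    layout = build_stimulus_layout()
    records: list[SubjectRecord] = []
    for s in range(config.n_subjects):
        logger.info("processing subject %d/%d", s + 1, config.n_subjects)
        records.append(process_subject(config, s, layout))

    model = SaccadeRemappingModel(
        [r.epochs for r in records],
        layout,
        k=config.k_folds,
        shrinkage=config.shrinkage,
        peak_window_s=tuple(config.peak_window_s),
        bf_settings=BFSettings(null_value=0.5, prior_scale=config.bf_prior_scale),
        mask_threshold=config.mask_threshold,
    )
    results = model.fit(seed=config.seed, inference=True)

    included = screen_subjects(
        results.mean_fixation_accuracy(), config.screening_threshold
    )
    manifest = {
        "perisacc_version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "n_subjects": config.n_subjects,
        "subjects_included_after_screening": [int(i) for i in included],
        "trials_kept_per_subject": [
            int(r.rejection.keep_mask.sum()) for r in records
        ],
        "components_rejected_per_subject": [
            r.n_rejected_components for r in records
        ],
        "remapping_detected": bool(results.remapping_detected()),
    }
    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_outputs(out, config, records, results, manifest)
    return results, manifest


def write_outputs(
    out: Path,
    config: RunConfig,
    records: list[SubjectRecord],
    results: SaccadeRemappingResults,
    manifest: dict,
) -> None:
    config.to_json(out / "config.json")
    for name, frame in results.to_frames().items():
        frame.to_csv(out / f"{name}.csv", index=False)
    results.bf_frame().to_csv(out / "bayes_factors.csv", index=False)
    if results.sliding_mask is not None:
        np.savetxt(out / "sliding_mask.csv", results.sliding_mask, fmt="%d", delimiter=",")
        np.savetxt(
            out / "sliding_diff.csv",
            np.nanmean(results.sliding_diff, axis=0),
            delimiter=",",
        )
    rej = pd.concat(
        [r.rejection.table.assign(subject=r.subject) for r in records]
    )
    rej.to_csv(out / "rejection_report.csv", index=False)
    sacc = pd.concat(
        [r.saccade_events.assign(subject=r.subject) for r in records]
    )
    sacc.to_csv(out / "saccade_events.csv", index=False)
    with open(out / "summary.txt", "w") as f:
        f.write(results.summary() + "\n")
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2)
    try:
        results.plot_timecourses(out / "timecourses.png")
        results.plot_sliding_matrix(out / "sliding_matrix.png")
    except Exception as exc:  # plotting must never sink a run
        logger.warning("plotting failed: %s", exc)
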