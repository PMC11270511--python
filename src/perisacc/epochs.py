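"""Epoch extraction and the trials x channels x time container.

Sample-grid convention
----------------------
For an event at time ``t0`` and window ``(w0, w1)`` seconds, the epoch holds
the samples at offsets ``n / fs`` for integer ``n`` from ``ceil(w0 * fs)``
to ``floor(w1 * fs)`` inclusive, measured from the event sample
``round(t0 * fs)``.  The event sample (t = 0) is always included.  At
256 Hz the default (-200, 500) ms window therefore spans offsets
-51..+128, i.e. 180 samples.

Baseline correction subtracts, per trial and channel, the mean over the
samples with ``b0 <= t < 0`` (the event sample is excluded), the default
being the 100 ms before the event.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ALIGNMENTS = ("stimulus_onset", "saccade_onset", "saccade_offset")


@dataclass
class EpochSet:
    """Epoched EEG: ``data`` (n_trials, n_channels, n_times) with metadata."""

    data: np.ndarray
    times: np.ndarray  # seconds relative to the alignment event
    fs: float
    alignment: str
    metadata: pd.DataFrame  # one row per kept trial

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def time_index(self, t_s: float) -> int:
        """Index of the sample closest to ``t_s``."""
        return int(np.argmin(np.abs(self.times - t_s)))

    def select(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            self.data[mask],
            self.times,
            self.fs,
            self.alignment,
            self.metadata.iloc[mask].reset_index(drop=True),
        )

    def save(self, directory: str | Path) -> None:
        """Write the container: data.npy + times.npy + meta sidecars."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.save(d / "data.npy", self.data)
        np.save(d / "times.npy", self.times)
        self.metadata.to_csv(d / "metadata.csv", index=False)
        with open(d / "epochs.json", "w") as f:
            json.dump(
                {
                    "fs": self.fs,
                    "alignment": self.alignment,
                    "shape": list(self.data.shape),
                    "time_range_s": [float(self.times[0]), float(self.times[-1])],
                },
                f,
                indent=2,
            )

    @classmethod
    def load(cls, directory: str | Path) -> "EpochSet":
        d = Path(directory)
        with open(d / "epochs.json") as f:
            meta = json.load(f)
        return cls(
            data=np.load(d / "data.npy"),
            times=np.load(d / "times.npy"),
            fs=meta["fs"],
            alignment=meta["alignment"],
            metadata=pd.read_csv(d / "metadata.csv"),
        )


def epoch_sample_offsets(
    fs: float, window: tuple[float, float]
) -> np.ndarray:
    """Integer sample offsets covered by ``window`` under the convention."""
    n0 = int(np.ceil(window[0] * fs - 1e-9))
    n1 = int(np.floor(window[1] * fs + 1e-9))
    return np.arange(n0, n1 + 1)


def epoch(
    data: np.ndarray,
    fs: float,
    event_times_s: np.ndarray,
    alignment: str = "stimulus_onset",
    window: tuple[float, float] = (-0.2, 0.5),
    baseline: tuple[float, float] | None = (-0.1, 0.0),
    metadata: pd.DataFrame | None = None,
) -> EpochSet:
    """Cut epochs out of a continuous (n_channels, n_samples) recording.

    Events whose window falls outside the recording are dropped with a
    warning (and removed from the metadata).  Events with NaN times (e.g.
    saccade alignment on trials without a saccade) are dropped silently.

    Raises
    ------
    ValueError
        If ``baseline`` is not contained in ``window``.
    """
    if alignment not in ALIGNMENTS:
        raise ValueError(f"alignment must be one of {ALIGNMENTS}")
    if baseline is not None and (
        baseline[0] < window[0] or baseline[1] > window[1]
    ):
        raise ValueError("baseline interval must lie within the epoch window")

    event_times_s = np.asarray(event_times_s, dtype=float)
    offsets = epoch_sample_offsets(fs, window)
    times = offsets / fs
    n_samples = data.shape[1]

    keep_rows: list[int] = []
    epochs: list[np.ndarray] = []
    n_oob = 0
    for i, t0 in enumerate(event_times_s):
        if not np.isfinite(t0):
            continue
        center = int(round(t0 * fs))
        sel = center + offsets
        if sel[0] < 0 or sel[-1] >= n_samples:
            n_oob += 1
            continue
        epochs.append(data[:, sel])
        keep_rows.append(i)
    if n_oob:
        logger.warning("dropped %d events outside the recording bounds", n_oob)

    arr = (
        np.stack(epochs, axis=0)
        if epochs
        else np.zeros((0, data.shape[0], len(offsets)))
    )
    if baseline is not None and arr.size:
        bmask = (times >= baseline[0]) & (times < baseline[1])
        arr = arr - arr[:, :, bmask].mean(axis=2, keepdims=True)

    if metadata is None:
        metadata = pd.DataFrame(index=range(len(event_times_s)))
    md = metadata.iloc[keep_rows].reset_index(drop=True)
    return EpochSet(arr, times, fs, alignment, md)
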