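"""Continuous-EEG signal conditioning.

Pipeline contract: input sampled at >= 160 Hz; output downsampled to 256 Hz,
re-referenced to the mean of the two designated mastoid channels, 50 Hz
notch filtered and 0.1-80 Hz bandpass filtered (zero-phase FIR, Hamming
window, default transition widths).  The filter family and parameters are
recorded in a provenance dictionary returned alongside the data.
"""

from __future__ import annotations

import numpy as np

TARGET_FS_HZ = 256.0


def rereference(data: np.ndarray, mastoid_channels: tuple[int, int]) -> np.ndarray:
    """Subtract the mean of the two mastoid channels from every channel."""
    ref = data[list(mastoid_channels)].mean(axis=0)
    return data - ref[None, :]


def preprocess_signal(
    data: np.ndarray,
    fs: float,
    mastoid_channels: tuple[int, int] = (62, 63),
    notch_hz: float | None = 50.0,
    band_hz: tuple[float, float] = (0.1, 80.0),
    target_fs: float = TARGET_FS_HZ,
) -> tuple[np.ndarray, float, dict]:
    """Condition a continuous (n_channels, n_samples) recording.

    Returns ``(data, fs, provenance)``.

    Raises
    ------
    ValueError
        If ``fs`` < 160 Hz or the mastoid channel indices are invalid.
    """
    import mne  # deferred: mne import is slow

    if fs < 160:
        raise ValueError("sampling rate must be >= 160 Hz")
    n_ch = data.shape[0]
    if any(m < 0 or m >= n_ch for m in mastoid_channels):
        raise ValueError(
            f"mastoid channels {mastoid_channels} not present in {n_ch}-channel data"
        )

    data = np.asarray(data, dtype=np.float64)
    provenance: dict = {
        "input_fs": fs,
        "mastoid_channels": list(mastoid_channels),
        "filter_family": "zero-phase FIR (Hamming window, firwin)",
    }

    if fs > target_fs:
        data = mne.filter.resample(data, down=fs / target_fs, verbose="error")
        fs = target_fs
    provenance["fs"] = fs

    data = rereference(data, mastoid_channels)

    if notch_hz is not None:
        data = mne.filter.notch_filter(
            data, fs, freqs=notch_hz, method="fir", phase="zero", verbose="error"
        )
        provenance["notch_hz"] = notch_hz

    data = mne.filter.filter_data(
        data,
        fs,
        l_freq=band_hz[0],
        h_freq=band_hz[1],
        method="fir",
        phase="zero",
        verbose="error",
    )
    provenance["band_hz"] = list(band_hz)
    return data, fs, provenance
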