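"""EEG preprocessing: filtering, resampling, referencing, epoching,
automated artifact rejection, and baseline correction.

The canonical order is filter -> resample -> average reference -> epoch ->
reject -> baseline. Filtering is zero-phase (forward-backward IIR) so ERP
component latencies are not distorted; "order 8" refers to the design order
of the bandpass (a 4th-order Butterworth prototype applied as a bandpass).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal

from .epochs import EEGEpochs

__all__ = [
    "filter_signal",
    "resample_signal",
    "average_reference",
    "epoch_continuous",
    "reject_artifacts",
    "baseline_correct",
    "preprocess_epochs",
    "read_brainvision",
    "read_edf",
    "PreprocessConfig",
]


@dataclass
class PreprocessConfig:
    band: tuple = (0.5, 40.0)  # Hz
    filter_order: int = 8
    notch: float | None = 50.0  # Hz
    target_srate: float = 256.0
    amp_limit: float = 100.0  # uV
    flat_limit: float = 0.5  # uV peak-to-peak
    flat_dur: float = 100.0  # ms
    check_window: tuple = (-200.0, 200.0)  # ms
    baseline_window: tuple = (-200.0, 0.0)  # ms


def filter_signal(
    data: np.ndarray,
    srate: float,
    band: tuple = (0.5, 40.0),
    order: int = 8,
    notch: float | None = 50.0,
) -> np.ndarray:
    """Zero-phase bandpass (+ optional notch) along the last axis.

    ``order`` is the order of the resulting bandpass; the Butterworth
    prototype therefore has order ``order // 2``.
    """
    nyq = srate / 2.0
    if not 0 < band[0] < band[1] < nyq:
        raise ValueError(f"band edges {band} must lie inside (0, {nyq}) Hz")
    sos = signal.butter(order // 2, band, btype="bandpass", fs=srate, output="sos")
    out = signal.sosfiltfilt(sos, np.asarray(data, dtype=float), axis=-1)
    if notch is not None:
        if not 0 < notch < nyq:
            raise ValueError(f"notch frequency {notch} outside (0, {nyq}) Hz")
        b, a = signal.iirnotch(notch, Q=30.0, fs=srate)
        out = signal.filtfilt(b, a, out, axis=-1)
    return out


def resample_signal(data: np.ndarray, srate_in: float, srate_out: float = 256.0) -> np.ndarray:
    """Polyphase anti-aliased resampling along the last axis (downsampling only)."""
    if srate_out > srate_in:
        raise ValueError("upsampling is not supported; srate_out must be <= srate_in")
    if srate_out == srate_in:
        return np.asarray(data, dtype=float).copy()
    frac = Fraction(srate_out / srate_in).limit_denominator(1000)
    return signal.resample_poly(np.asarray(data, dtype=float), frac.numerator, frac.denominator, axis=-1)


def average_reference(data: np.ndarray, channel_axis: int = -2) -> np.ndarray:
    """Re-reference to the common average: subtract the across-channel mean
    at every sample."""
    data = np.asarray(data, dtype=float)
    return data - data.mean(axis=channel_axis, keepdims=True)


def epoch_continuous(
    data: np.ndarray,
    srate: float,
    onset_samples: np.ndarray,
    span_ms: tuple = (-2000.0, 2000.0),
    channel_labels: list | None = None,
    metadata=None,
) -> EEGEpochs:
    """Cut (channels, samples) continuous data into epochs around onsets."""
    import pandas as pd

    data = np.asarray(data, dtype=float)
    lo = int(round(span_ms[0] / 1000.0 * srate))
    n = int(round((span_ms[1] - span_ms[0]) / 1000.0 * srate))
    times = span_ms[0] + np.arange(n) * 1000.0 / srate
    cubes = []
    for onset in onset_samples:
        start = int(onset) + lo
        if start < 0 or start + n > data.shape[-1]:
            raise ValueError(f"epoch around sample {onset} falls outside the recording")
        cubes.append(data[:, start : start + n])
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(data.shape[0])]
    if metadata is None:
        metadata = pd.DataFrame({"trial_index": np.arange(len(onset_samples))})
    return EEGEpochs(
        data=np.stack(cubes) if cubes else np.empty((0, data.shape[0], n)),
        srate=srate,
        times=times,
        channel_labels=list(channel_labels),
        metadata=metadata,
    )


def reject_artifacts(
    epochs: EEGEpochs,
    amp_limit: float = 100.0,
    flat_limit: float = 0.5,
    flat_dur: float = 100.0,
    check_window: tuple = (-200.0, 200.0),
) -> EEGEpochs:
    """Flag trials with amplitude or flatline artifacts around the target.

    Within ``check_window``, a trial is rejected when any channel has a sample
    strictly exceeding +/-``amp_limit`` uV, or a contiguous stretch of at
    least ``flat_dur`` ms whose peak-to-peak amplitude is strictly below
    ``flat_limit`` uV. Data are never modified; only ``kept_mask`` changes.
    """
    from scipy.ndimage import maximum_filter1d, minimum_filter1d

    out = epochs.copy()
    idx = out.time_indices(check_window)
    if idx.size == 0:
        raise ValueError("check_window lies outside the epoch span")
    seg = out.data[:, :, idx]

    bad_amp = (np.abs(seg) > amp_limit).any(axis=(1, 2))

    flat_n = int(round(flat_dur / 1000.0 * out.srate))
    bad_flat = np.zeros(out.n_trials, dtype=bool)
    if 0 < flat_n <= seg.shape[-1]:
        # peak-to-peak over every contiguous stretch of flat_n samples
        mx = maximum_filter1d(seg, size=flat_n, axis=-1, mode="nearest")
        mn = minimum_filter1d(seg, size=flat_n, axis=-1, mode="nearest")
        half = flat_n // 2
        valid = slice(half, seg.shape[-1] - (flat_n - 1 - half))
        ptp = (mx - mn)[:, :, valid]
        if ptp.shape[-1] > 0:
            bad_flat = (ptp < flat_limit).any(axis=(1, 2))

    out.kept_mask = out.kept_mask & ~(bad_amp | bad_flat)
    return out


def baseline_correct(epochs: EEGEpochs, window: tuple = (-200.0, 0.0)) -> EEGEpochs:
    """Subtract the per-trial, per-channel mean over ``window`` (idempotent)."""
    out = epochs.copy()
    idx = out.time_indices(window)
    if idx.size == 0:
        raise ValueError("baseline window lies outside the epoch span")
    out.data -= out.data[:, :, idx].mean(axis=-1, keepdims=True)
    return out


def preprocess_epochs(epochs: EEGEpochs, config: PreprocessConfig | None = None) -> EEGEpochs:
    """Epoch-level tail of the pipeline: average reference -> artifact
    rejection -> baseline correction.

    Filtering and resampling belong on the continuous recording (before
    epoching); synthetic epochs are generated band-limited at the target rate,
    so the chain starts at re-referencing. An independent-component artifact
    step would slot in before rejection for real recordings with ocular
    sources; the synthetic generator produces none, so no such step exists
    here.
    """
    cfg = config or PreprocessConfig()
    out = epochs.copy()
    out.data = average_reference(out.data)
    out = reject_artifacts(
        out,
        amp_limit=cfg.amp_limit,
        flat_limit=cfg.flat_limit,
        flat_dur=cfg.flat_dur,
        check_window=cfg.check_window,
    )
    return baseline_correct(out, window=cfg.baseline_window)


# -- real-data entry points -------------------------------------------------


def read_brainvision(vhdr_path) -> tuple:
    """Read a BrainVision (.vhdr/.vmrk/.eeg) recording.

    Returns (data uV as channels x samples, srate, channel_labels).
    """
    import mne

    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    return raw.get_data() * 1e6, raw.info["sfreq"], list(raw.ch_names)


def read_edf(edf_path) -> tuple:
    """Read an EDF+ recording. Returns (data uV, srate, channel_labels)."""
    import mne

    raw = mne.io.read_raw_edf(edf_path, preload=True, verbose="error")
    return raw.get_data() * 1e6, raw.info["sfreq"], list(raw.ch_names)
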