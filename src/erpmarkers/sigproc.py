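"""Filtering, epoching, artifact rejection and baseline correction.

All amplitudes are in microvolts (μV) throughout the package. Filters are
zero-phase (forward-backward) recursive designs so that ERP component
latencies are not shifted by filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

__all__ = [
    "Recording",
    "EpochSet",
    "bandpass",
    "notch",
    "segment_resting",
    "segment_events",
]

#: channels that are never scored for artifact rejection
NON_EEG_LABELS = frozenset({"VEOG", "HEOG", "EOG", "EKG", "ECG", "EMG", "REF", "GND"})


@dataclass
class Recording:
    """A raw multichannel EEG recording with event markers.

    Parameters
    ----------
    subject_id : str
        Cohort-unique subject identifier.
    paradigm : {"resting", "ldaep", "mmn"}
        Which acquisition protocol produced the recording.
    channel_labels : list of str
        Ordered extended 10-20 channel names; one per data row.
    sampling_rate : float
        Samples per second (Hz).
    data : ndarray, shape (n_channels, n_samples)
        Signal in μV.
    events : list of (int, str)
        ``(sample_index, code)`` stimulus markers. Codes are intensity
        strings (``"60"``..``"100"``) for LDAEP and ``"standard"`` /
        ``"deviant"`` for the oddball paradigm.
    meta : dict
        Free-form provenance (filters applied, generator ground truth, ...).
    """

    subject_id: str
    paradigm: str
    channel_labels: list
    sampling_rate: float
    data: np.ndarray
    events: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} data rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if self.paradigm not in {"resting", "ldaep", "mmn"}:
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        n = self.data.shape[1]
        for idx, code in self.events:
            if not 0 <= idx < n:
                raise ValueError(f"event sample {idx} outside recording of {n} samples")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def eeg_channels(self) -> list:
        """Scored channel labels: the montage minus non-EEG channels."""
        return [c for c in self.channel_labels if c.upper() not in NON_EEG_LABELS]


@dataclass
class EpochSet:
    """Fixed-length signal windows cut from a :class:`Recording`.

    ``data`` is epochs x channels x samples (μV). ``window`` is in ms
    relative to the event (event-locked) or to the segment origin
    (resting). Epochs are half-open ``[start, end)`` in samples.
    """

    data: np.ndarray
    channel_labels: list
    sampling_rate: float
    window: tuple
    baseline_window: tuple = None
    condition_codes: list = field(default_factory=list)
    n_rejected: int = 0
    rejection_threshold: float = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (epochs x channels x samples)")
        if self.window[0] >= self.window[1]:
            raise ValueError("window start must precede end")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Per-sample time axis in ms relative to the window origin."""
        n = self.data.shape[2]
        step = 1000.0 / self.sampling_rate
        return self.window[0] + step * np.arange(n)

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in epoch set") from None

    def select(self, condition) -> "EpochSet":
        """Subset of epochs whose condition code equals ``condition``."""
        mask = np.array([c == condition for c in self.condition_codes])
        if not mask.any():
            raise ValueError(f"no epochs with condition {condition!r}")
        return replace(
            self,
            data=self.data[mask],
            condition_codes=[c for c, m in zip(self.condition_codes, mask) if m],
        )


def _validate_band(low, high, fs):
    nyq = fs / 2.0
    if not (0 < low < high < nyq):
        raise ValueError(
            f"invalid band ({low}, {high}) Hz for sampling rate {fs} Hz "
            f"(need 0 < low < high < {nyq})"
        )


def bandpass(rec: Recording, low: float, high: float, order: int = 4) -> Recording:
    """Zero-phase Butterworth band-pass, applied per channel.

    Realized as a cascade of an ``order``-th high-pass and low-pass
    section (numerically robust for very wide bands such as 0.1-100 Hz);
    the effective order is doubled by the forward-backward pass. The band
    is recorded in ``meta["filters"]``.
    """
    _validate_band(low, high, rec.sampling_rate)
    sos = np.vstack([
        signal.butter(order, low, btype="highpass", output="sos",
                      fs=rec.sampling_rate),
        signal.butter(order, high, btype="lowpass", output="sos",
                      fs=rec.sampling_rate),
    ])
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    meta = dict(rec.meta)
    meta.setdefault("filters", []).append(
        {"type": "bandpass", "band_hz": [low, high], "order": order,
         "design": "butterworth sosfiltfilt"})
    return replace(rec, data=filtered, meta=meta)


def notch(rec: Recording, freq: float, quality: float = 30.0) -> Recording:
    """Zero-phase IIR notch (quality factor 30 by default) at ``freq`` Hz."""
    nyq = rec.sampling_rate / 2.0
    if not 0 < freq < nyq:
        raise ValueError(f"notch frequency {freq} Hz outside (0, {nyq})")
    b, a = signal.iirnotch(freq, quality, fs=rec.sampling_rate)
    filtered = signal.filtfilt(b, a, rec.data, axis=1)
    meta = dict(rec.meta)
    meta.setdefault("filters", []).append(
        {"type": "notch", "freq_hz": freq, "quality": quality})
    return replace(rec, data=filtered, meta=meta)


def _scored_rows(rec_labels, scored_channels):
    idx = [i for i, c in enumerate(rec_labels) if c in scored_channels]
    if not idx:
        raise ValueError("no scored channels present in recording")
    return idx


def segment_resting(rec: Recording, epoch_s: float = 2.048, reject_uV: float = 100.0,
                    max_epochs: int = 30, scored_channels=None) -> EpochSet:
    """Cut consecutive non-overlapping resting epochs and reject on amplitude.

    Epochs whose absolute amplitude exceeds ``reject_uV`` on any scored
    channel are dropped; the first ``max_epochs`` clean epochs (temporal
    order) are retained. 2.048 s at 1000 Hz gives exactly 2048 samples.
    """
    if rec.paradigm != "resting":
        raise ValueError(f"expected a resting recording, got {rec.paradigm!r}")
    n_per = int(round(epoch_s * rec.sampling_rate))
    n_candidate = rec.n_samples // n_per
    if scored_channels is None:
        scored_channels = rec.eeg_channels()
    rows = _scored_rows(rec.channel_labels, scored_channels)

    kept, n_seen_clean, n_rejected = [], 0, 0
    for k in range(n_candidate):
        seg = rec.data[:, k * n_per:(k + 1) * n_per]
        if np.abs(seg[rows]).max() > reject_uV:
            n_rejected += 1
            continue
        if n_seen_clean < max_epochs:
            kept.append(seg)
        n_seen_clean += 1
    if len(kept) < max_epochs:
        need_s = max_epochs * epoch_s
        raise ValueError(
            f"only {len(kept)} clean epochs of {n_candidate} candidates "
            f"({n_rejected} rejected); {max_epochs} required — need at least "
            f"{need_s:.1f} s of clean data")
    return EpochSet(
        data=np.stack(kept),
        channel_labels=list(rec.channel_labels),
        sampling_rate=rec.sampling_rate,
        window=(0.0, epoch_s * 1000.0),
        baseline_window=None,
        condition_codes=["resting"] * len(kept),
        n_rejected=n_rejected,
        rejection_threshold=reject_uV,
        meta={"subject_id": rec.subject_id, "paradigm": rec.paradigm,
              "epoch_s": epoch_s, "max_epochs": max_epochs},
    )


def segment_events(rec: Recording, pre_ms: float = 100.0, post_ms: float = None,
                   reject_uV: float = 75.0, scored_channels=None) -> EpochSet:
    """Event-locked epochs with pre-stimulus baseline correction.

    Each epoch spans ``[-pre_ms, post_ms)`` around its event; the mean over
    the pre-stimulus interval is subtracted channelwise, then epochs whose
    residual amplitude exceeds ``reject_uV`` on any scored channel are
    rejected (rejection is applied after baseline correction).
    """
    if rec.paradigm not in {"ldaep", "mmn"}:
        raise ValueError(f"expected an event-related recording, got {rec.paradigm!r}")
    if post_ms is None:
        post_ms = 900.0 if rec.paradigm == "ldaep" else 600.0
    fs = rec.sampling_rate
    n_pre = int(round(pre_ms * fs / 1000.0))
    n_post = int(round(post_ms * fs / 1000.0))
    if scored_channels is None:
        scored_channels = rec.eeg_channels()
    rows = _scored_rows(rec.channel_labels, scored_channels)

    kept, codes, n_rejected = [], [], 0
    for sample, code in rec.events:
        start, stop = sample - n_pre, sample + n_post  # half-open [start, stop)
        if start < 0 or stop > rec.n_samples:
            n_rejected += 1  # truncated epochs cannot be scored
            continue
        ep = rec.data[:, start:stop].copy()
        ep -= ep[:, :n_pre].mean(axis=1, keepdims=True)
        if np.abs(ep[rows]).max() > reject_uV:
            n_rejected += 1
            continue
        kept.append(ep)
        codes.append(code)
    if not kept:
        raise ValueError(
            f"no epochs survived rejection at ±{reject_uV} μV "
            f"({n_rejected} candidates rejected)")
    return EpochSet(
        data=np.stack(kept),
        channel_labels=list(rec.channel_labels),
        sampling_rate=fs,
        window=(-pre_ms, post_ms),
        baseline_window=(-pre_ms, 0.0),
        condition_codes=codes,
        n_rejected=n_rejected,
        rejection_threshold=reject_uV,
        meta={"subject_id": rec.subject_id, "paradigm": rec.paradigm},
    )
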