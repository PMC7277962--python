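"""Averaged evoked responses, N1/P2 peaks, LDAEP slope and MMN amplitude.

LDAEP (loudness dependence of the auditory evoked potential) is the slope
of the N1/P2 peak-to-peak amplitude at Cz against tone intensity, in μV
per 10 dB, over tones at 60-100 dB SPL. MMN (mismatch negativity) is the
mean of the deviant-minus-standard difference wave over 130-280 ms,
averaged over nine frontocentral sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .sigproc import EpochSet

__all__ = ["Erp", "PeakMeasure", "LdaepResult", "MmnResult",
           "average_erp", "detect_peak", "ldaep", "mmn",
           "LDAEP_INTENSITIES", "MMN_SITES", "MMN_WINDOW",
           "N1_WINDOW", "P2_WINDOW"]

LDAEP_INTENSITIES = (60, 70, 80, 90, 100)  # dB SPL
MMN_SITES = ("F3", "Fz", "F4", "FC3", "FCz", "FC4", "C3", "Cz", "C4")
MMN_WINDOW = (130.0, 280.0)  # ms, closed
N1_WINDOW = (50.0, 200.0)  # ms, closed; most negative peak
P2_WINDOW = (150.0, 300.0)  # ms, closed; most positive peak


@dataclass
class Erp:
    """Trial-averaged evoked response: channels x samples in μV."""

    condition: str
    channel_labels: list
    waveform: np.ndarray
    times: np.ndarray  # ms relative to stimulus
    n_trials: int

    def __post_init__(self):
        self.waveform = np.asarray(self.waveform, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.n_trials < 1:
            raise ValueError("an ERP requires at least one trial")
        if self.waveform.shape != (len(self.channel_labels), len(self.times)):
            raise ValueError("waveform shape inconsistent with labels/times")

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.waveform[self.channel_labels.index(label)]
        except ValueError:
            raise KeyError(f"channel {label!r} not in ERP") from None


@dataclass(frozen=True)
class PeakMeasure:
    component: str  # "N1" or "P2"
    latency: float  # ms
    amplitude: float  # μV
    window: tuple  # ms search window


@dataclass(frozen=True)
class LdaepResult:
    intensities: tuple
    n1p2_amplitudes: dict  # intensity -> μV
    slope: float  # μV per 10 dB
    intercept: float  # μV


@dataclass
class MmnResult:
    difference: Erp  # deviant - standard
    site_amplitudes: dict  # site -> mean μV over window
    composite: float  # μV, unweighted mean of the nine sites
    window: tuple = MMN_WINDOW


def average_erp(epochs: EpochSet, condition=None) -> Erp:
    """Pointwise mean across retained epochs of one condition."""
    if condition is not None:
        epochs = epochs.select(condition)
        label = str(condition)
    else:
        codes = set(epochs.condition_codes)
        label = codes.pop() if len(codes) == 1 else "all"
    if epochs.n_epochs < 1:
        raise ValueError("cannot average an empty epoch set")
    return Erp(condition=label,
               channel_labels=list(epochs.channel_labels),
               waveform=epochs.data.mean(axis=0),
               times=epochs.times,
               n_trials=epochs.n_epochs)


def detect_peak(erp: Erp, channel: str, window_ms: tuple, polarity: str) -> PeakMeasure:
    """Extremum of the stated polarity within a closed latency window.

    ``polarity="negative"`` finds the minimum (N1-type), ``"positive"``
    the maximum (P2-type). Ties are broken by the earliest latency, which
    argmin/argmax guarantee on first occurrence.
    """
    lo, hi = window_ms
    if lo < erp.times[0] or hi > erp.times[-1]:
        raise ValueError(
            f"window {window_ms} ms outside epoch span "
            f"[{erp.times[0]:g}, {erp.times[-1]:g}] ms")
    x = erp.channel(channel)
    mask = (erp.times >= lo) & (erp.times <= hi)
    seg, t = x[mask], erp.times[mask]
    if polarity == "negative":
        i, comp = int(np.argmin(seg)), "N1"
    elif polarity == "positive":
        i, comp = int(np.argmax(seg)), "P2"
    else:
        raise ValueError(f"polarity must be 'negative' or 'positive', got {polarity!r}")
    return PeakMeasure(component=comp, latency=float(t[i]),
                       amplitude=float(seg[i]), window=(float(lo), float(hi)))


def ldaep(epochs: EpochSet, channel: str = "Cz",
          intensities=LDAEP_INTENSITIES) -> LdaepResult:
    """LDAEP slope from N1/P2 peak-to-peak amplitudes at Cz.

    Per intensity: amplitude = P2 peak (150-300 ms max) minus N1 peak
    (50-200 ms min) of the trial average. The slope is the OLS fit of
    amplitude against intensity/10, so its units are μV per 10 dB.
    """
    present = set(epochs.condition_codes)
    amps = {}
    for inten in intensities:
        code = str(inten)
        if code not in present:
            raise ValueError(f"no epochs for intensity {inten} dB")
        avg = average_erp(epochs, code)
        n1 = detect_peak(avg, channel, N1_WINDOW, "negative")
        p2 = detect_peak(avg, channel, P2_WINDOW, "positive")
        amps[inten] = p2.amplitude - n1.amplitude
    x = np.asarray(intensities, dtype=float) / 10.0
    y = np.array([amps[i] for i in intensities])
    fit = stats.linregress(x, y)
    return LdaepResult(intensities=tuple(intensities), n1p2_amplitudes=amps,
                       slope=float(fit.slope), intercept=float(fit.intercept))


def mmn(epochs_std: EpochSet, epochs_dev: EpochSet, sites=MMN_SITES,
        window=MMN_WINDOW) -> MmnResult:
    """Deviant-minus-standard difference wave and its windowed amplitude.

    Per-site amplitude is the mean of the difference wave over samples
    with time in the closed window (default 130-280 ms); the composite is
    the unweighted mean of the nine frontocentral sites.
    """
    avg_std = average_erp(epochs_std)
    avg_dev = average_erp(epochs_dev)
    if avg_std.channel_labels != avg_dev.channel_labels:
        raise ValueError("standard and deviant epochs have different montages")
    if not np.array_equal(avg_std.times, avg_dev.times):
        raise ValueError("standard and deviant epochs have different time axes")
    for s in sites:
        if s not in avg_std.channel_labels:
            raise ValueError(f"MMN site {s!r} missing from montage")
    diff = Erp(condition="deviant-standard",
               channel_labels=avg_std.channel_labels,
               waveform=avg_dev.waveform - avg_std.waveform,
               times=avg_std.times,
               n_trials=min(avg_std.n_trials, avg_dev.n_trials))
    mask = (diff.times >= window[0]) & (diff.times <= window[1])
    site_amps = {s: float(diff.channel(s)[mask].mean()) for s in sites}
    composite = float(np.mean([site_amps[s] for s in sites]))
    return MmnResult(difference=diff, site_amplitudes=site_amps,
                     composite=composite, window=tuple(window))
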