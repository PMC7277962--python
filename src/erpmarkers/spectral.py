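"""Low-alpha band power and the frontal alpha asymmetry (FAA) index.

FAA compares absolute alpha-band power between homologous left/right
frontal channels:

    A = (P_left - P_right) / (P_left + P_right) * 100

A positive index means more alpha power (lower cortical activity) on the
left. The primary band is low alpha, 8-10 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .sigproc import EpochSet, Recording, segment_resting

__all__ = ["BandPower", "AsymmetryIndex", "band_power", "asymmetry_index",
           "compute_faa", "FAA_PAIRS", "LOW_ALPHA"]

#: homologous (left, right) frontal channel pairs of interest
FAA_PAIRS = (("F5", "F6"), ("F7", "F8"))
#: low alpha band, Hz, half-open [8, 10)
LOW_ALPHA = (8.0, 10.0)


@dataclass(frozen=True)
class BandPower:
    channel: str
    band: tuple
    power: float  # μV², absolute power

    def __post_init__(self):
        if self.power < 0:
            raise ValueError("band power cannot be negative")


@dataclass(frozen=True)
class AsymmetryIndex:
    pair: str  # e.g. "F5/F6"
    band: tuple
    value: float  # dimensionless, in [-100, 100]


def band_power(epochs: EpochSet, channel: str, band=LOW_ALPHA) -> BandPower:
    """Absolute band power via a Hann-tapered per-epoch periodogram.

    Power is summed over FFT bins whose center frequency lies in the
    half-open interval ``[band[0], band[1])`` Hz and averaged across
    epochs. For a 2048-sample epoch at 1000 Hz the bin spacing is
    ~0.488 Hz.
    """
    fs = epochs.sampling_rate
    if not 0 <= band[0] < band[1] <= fs / 2:
        raise ValueError(f"band {band} outside [0, {fs / 2}] Hz")
    row = epochs.channel_index(channel)
    x = epochs.data[:, row, :]  # epochs x samples
    freqs, pxx = signal.periodogram(x, fs=fs, window="hann", axis=-1,
                                    scaling="density", detrend=False)
    in_band = (freqs >= band[0]) & (freqs < band[1])
    df = freqs[1] - freqs[0]
    per_epoch = pxx[:, in_band].sum(axis=1) * df  # integrate the PSD
    return BandPower(channel=channel, band=tuple(band),
                     power=float(per_epoch.mean()))


def asymmetry_index(p_left: BandPower, p_right: BandPower) -> AsymmetryIndex:
    """A = (P_left - P_right)/(P_left + P_right) * 100; sign convention:
    positive = greater alpha on the left."""
    total = p_left.power + p_right.power
    if total == 0:
        raise ValueError(
            f"asymmetry undefined: zero total power for {p_left.channel}/"
            f"{p_right.channel}")
    if p_left.band != p_right.band:
        raise ValueError("band mismatch between left and right powers")
    a = (p_left.power - p_right.power) / total * 100.0
    return AsymmetryIndex(pair=f"{p_left.channel}/{p_right.channel}",
                          band=p_left.band, value=float(a))


def compute_faa(rec: Recording, band=LOW_ALPHA, pairs=FAA_PAIRS,
                epoch_s: float = 2.048, reject_uV: float = 100.0,
                max_epochs: int = 30) -> dict:
    """Resting recording -> {"F5/F6": AsymmetryIndex, "F7/F8": ...}.

    Chains resting segmentation (amplitude rejection, first 30 clean
    epochs), per-channel band power in the low alpha band, and the
    asymmetry index for each configured pair.
    """
    for left, right in pairs:
        for ch in (left, right):
            if ch not in rec.channel_labels:
                raise KeyError(f"montage lacks channel {ch!r} required for FAA")
    epochs = segment_resting(rec, epoch_s=epoch_s, reject_uV=reject_uV,
                             max_epochs=max_epochs)
    out = {}
    for left, right in pairs:
        a = asymmetry_index(band_power(epochs, left, band),
                            band_power(epochs, right, band))
        out[a.pair] = a
    return out
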