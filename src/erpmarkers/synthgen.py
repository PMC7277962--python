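"""Synthetic EEG recordings and clinical cohorts with known ground truth.

The signal model is deliberately minimal but makes every downstream
extractor identifiable:

* resting EEG: pink (1/f) background noise plus a band-limited alpha
  oscillation whose left/right power ratio at each configured frontal pair
  realizes a target asymmetry index;
* auditory evoked trials: pink noise plus event-locked Gaussian-windowed
  N1 (negative, ~100 ms) and P2 (positive, ~200 ms) components whose
  peak-to-peak distance grows linearly with tone intensity;
* oddball trials: a common evoked response for standards and deviants,
  with an extra negative Hann-windowed deflection over 130-280 ms on
  deviants whose window mean equals the target MMN amplitude;
* clinical cohort: integer HAM-D trajectories over weeks 0/2/4/8 whose
  fractional recovery depends on the subject's (true) frontal alpha
  asymmetry group, plus demographics and a CORE score correlated with the
  true F7/F8 asymmetry.

Everything is driven by one integer seed; identical configurations yield
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .clinstats import ClinicalRecord
from .sigproc import Recording

__all__ = ["SimulationConfig", "GroundTruth", "gen_resting_eeg",
           "gen_ldaep_recording", "gen_mmn_recording", "gen_clinical_cohort",
           "draw_ground_truth", "DEFAULT_MONTAGE"]

DEFAULT_MONTAGE = ("F5", "F6", "F7", "F8", "F3", "Fz", "F4",
                   "FC3", "FCz", "FC4", "C3", "Cz", "C4")
REQUIRED_CHANNELS = frozenset(DEFAULT_MONTAGE)

_PARADIGM_STREAM = {"truth": 0, "resting": 1, "ldaep": 2, "mmn": 3, "clinical": 4}


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one simulated study.

    Biomarker distribution defaults (means/SDs for asymmetry, LDAEP slope,
    MMN amplitude, HAM-D, age, CORE) mirror a published depression cohort
    of n = 52 and are realistic settings, not a claim to reproduce that
    cohort.
    """

    seed: int = 0
    n_subjects: int = 52
    sampling_rate: float = 1000.0
    montage: tuple = DEFAULT_MONTAGE
    # --- resting / alpha ---
    resting_duration: float = 70.0  # s; >= 30 clean 2.048-s epochs
    alpha_asym_target: float = 0.0  # index units, open interval (-100, 100)
    alpha_center_freq: float = 9.0  # Hz, in [8, 10)
    alpha_amp: float = 10.0  # μV RMS-defining amplitude of the oscillation
    # --- LDAEP ---
    ldaep_slope_true: float = 1.55  # μV per 10 dB
    n1_base: float = 2.0  # μV, N1 share of peak-to-peak at 80 dB
    p2_base: float = 2.0  # μV, P2 share
    trials_per_intensity: int = 60
    ldaep_isi_range: tuple = (0.5, 0.9)  # s, uniform
    # --- MMN ---
    mmn_amp_true: float = -2.97  # μV (negative for a genuine MMN)
    mmn_n_stimuli: int = 750
    mmn_deviant_prob: float = 0.10
    mmn_isi: float = 0.5  # s (configurable; see methods note)
    # --- noise ---
    noise_sd: float = 5.0  # μV, pink background
    # --- cohort biomarker distributions (mean, sd) ---
    faa_f5f6_dist: tuple = (0.03, 14.13)
    faa_f7f8_dist: tuple = (-1.73, 15.81)
    ldaep_dist: tuple = (1.55, 2.85)
    mmn_dist: tuple = (-2.97, 1.34)
    # --- clinical trajectory model ---
    hamd_baseline_dist: tuple = (26.13, 6.80)
    recovery_mean: float = 0.675  # pooled mean fraction of baseline recovered by wk 8
    recovery_sd: float = 0.22
    group_effect: float = 0.27  # low-FAA minus high-FAA recovery fraction
    week_fraction: dict = field(default_factory=lambda: {0: 0.0, 2: 0.45, 4: 0.75, 8: 1.0})
    hamd_noise_sd: float = 1.5  # measurement noise on non-baseline weeks
    age_dist: tuple = (45.87, 11.69)
    female_prob: float = 0.923
    vortioxetine_prob: float = 0.5
    core_dist: tuple = (4.35, 5.98)
    core_faa_corr: float = 0.34  # CORE vs true FAA F7/F8
    hama_baseline_dist: tuple = (25.13, 6.02)

    def __post_init__(self):
        if not -100 < self.alpha_asym_target < 100:
            raise ValueError("alpha_asym_target must lie in the open interval (-100, 100)")
        if not 8.0 <= self.alpha_center_freq < 10.0:
            raise ValueError("alpha_center_freq must lie in [8, 10) Hz")
        if self.trials_per_intensity <= 0 or self.mmn_n_stimuli <= 0:
            raise ValueError("trial counts must be positive")
        if not 0 < self.mmn_deviant_prob < 1:
            raise ValueError("deviant probability must lie in (0, 1)")
        missing = REQUIRED_CHANNELS - set(self.montage)
        if missing:
            raise ValueError(f"montage lacks required channels {sorted(missing)}")

    def rng(self, stream: str, subject_index: int = 0) -> np.random.Generator:
        """Independent, reproducible stream per (paradigm, subject)."""
        key = _PARADIGM_STREAM[stream]
        return np.random.default_rng(
            np.random.SeedSequence([int(self.seed), key, int(subject_index)]))


@dataclass
class GroundTruth:
    """Per-subject true parameter values used by the generators."""

    subject_ids: list
    faa_f5f6: np.ndarray
    faa_f7f8: np.ndarray
    ldaep_slope: np.ndarray
    mmn_amp: np.ndarray
    group: list = None  # low/high FAA F5/F6 label driving the outcome model
    recovery: np.ndarray = None  # fractional HAM-D recovery by week 8

    def to_dict(self) -> dict:
        return {
            "subject_ids": list(self.subject_ids),
            "faa_f5f6": self.faa_f5f6.tolist(),
            "faa_f7f8": self.faa_f7f8.tolist(),
            "ldaep_slope": self.ldaep_slope.tolist(),
            "mmn_amp": self.mmn_amp.tolist(),
            "group": list(self.group) if self.group is not None else None,
            "recovery": self.recovery.tolist() if self.recovery is not None else None,
        }


def _clip_open(x, lo, hi, margin=1e-6):
    return np.clip(x, lo + margin, hi - margin)


def draw_ground_truth(cfg: SimulationConfig) -> GroundTruth:
    """Draw per-subject true biomarker values from the cohort distributions."""
    rng = cfg.rng("truth")
    n = cfg.n_subjects
    ids = [f"S{i + 1:03d}" for i in range(n)]
    faa56 = _clip_open(rng.normal(*cfg.faa_f5f6_dist, size=n), -100, 100, 1.0)
    faa78 = _clip_open(rng.normal(*cfg.faa_f7f8_dist, size=n), -100, 100, 1.0)
    slopes = rng.normal(*cfg.ldaep_dist, size=n)
    mmns = rng.normal(*cfg.mmn_dist, size=n)
    med = np.median(faa56)
    group = ["low" if v <= med else "high" for v in faa56]
    return GroundTruth(subject_ids=ids, faa_f5f6=faa56, faa_f7f8=faa78,
                       ldaep_slope=slopes, mmn_amp=mmns, group=group)


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                sd: float, fs: float) -> np.ndarray:
    """1/f-shaped Gaussian noise, per channel, scaled to the target SD."""
    n_f = n_samples // 2 + 1
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros(n_f)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])  # amplitude ~ f^{-1/2} => power ~ 1/f
    spec = (rng.standard_normal((n_channels, n_f))
            + 1j * rng.standard_normal((n_channels, n_f))) * shape
    x = np.fft.irfft(spec, n=n_samples, axis=1)
    std = x.std(axis=1, keepdims=True)
    std[std == 0] = 1.0
    return x / std * sd


def _pair_amplitudes(base_amp: float, asym: float) -> tuple:
    """Left/right oscillation amplitudes realizing asymmetry ``asym``.

    With power ratio P_l/P_r = (100 + A)/(100 - A), the index
    (P_l - P_r)/(P_l + P_r) * 100 equals A exactly. Mean pair power is
    kept at base_amp**2 / 2.
    """
    ratio = (100.0 + asym) / (100.0 - asym)
    a_r = base_amp * np.sqrt(2.0 / (1.0 + ratio))
    a_l = a_r * np.sqrt(ratio)
    return a_l, a_r


def gen_resting_eeg(cfg: SimulationConfig, subject_id: str = "S001",
                    subject_index: int = 0, asym_targets: dict = None) -> Recording:
    """Resting EEG whose frontal alpha asymmetry matches the target index.

    ``asym_targets`` maps pair tuples (left, right) to target indices; by
    default both F5/F6 and F7/F8 get ``cfg.alpha_asym_target``. Channels
    outside the pairs carry the symmetric base alpha amplitude.
    """
    min_dur = 30 * 2.048
    if cfg.resting_duration < min_dur:
        raise ValueError(
            f"resting_duration {cfg.resting_duration} s too short: need at least "
            f"{min_dur:.2f} s for 30 clean 2.048-s epochs")
    if asym_targets is None:
        asym_targets = {("F5", "F6"): cfg.alpha_asym_target,
                        ("F7", "F8"): cfg.alpha_asym_target}
    rng = cfg.rng("resting", subject_index)
    fs = cfg.sampling_rate
    n = int(round(cfg.resting_duration * fs))
    labels = list(cfg.montage)
    data = _pink_noise(rng, len(labels), n, cfg.noise_sd, fs)

    t = np.arange(n) / fs
    amp = {lab: cfg.alpha_amp for lab in labels}
    for (left, right), target in asym_targets.items():
        a_l, a_r = _pair_amplitudes(cfg.alpha_amp, target)
        amp[left], amp[right] = a_l, a_r
    for i, lab in enumerate(labels):
        phase = rng.uniform(0, 2 * np.pi)
        data[i] += amp[lab] * np.sin(2 * np.pi * cfg.alpha_center_freq * t + phase)

    return Recording(subject_id=subject_id, paradigm="resting",
                     channel_labels=labels, sampling_rate=fs, data=data,
                     meta={"ground_truth_asym": {f"{l}/{r}": v for (l, r), v
                                                 in asym_targets.items()},
                           "generator": "synthgen.gen_resting_eeg"})


def _gaussian_bump(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _add_component(data: np.ndarray, onset_sample: int, waveform: np.ndarray,
                   channel_gains: np.ndarray):
    stop = min(onset_sample + len(waveform), data.shape[1])
    seg = waveform[: stop - onset_sample]
    data[:, onset_sample:stop] += channel_gains[:, None] * seg


def gen_ldaep_recording(cfg: SimulationConfig, subject_id: str = "S001",
                        subject_index: int = 0, slope: float = None) -> Recording:
    """Auditory intensity-series recording for the LDAEP paradigm.

    Tones at 60/70/80/90/100 dB SPL in randomized order, inter-stimulus
    interval uniform in ``cfg.ldaep_isi_range``. Each tone evokes a
    negative N1 (~100 ms) and positive P2 (~200 ms) Gaussian component at
    Cz whose peak-to-peak amplitude is
    ``n1_base + p2_base + slope * (intensity - 80)/10``; frontocentral
    neighbours carry the same response at reduced gain.
    """
    if slope is None:
        slope = cfg.ldaep_slope_true
    rng = cfg.rng("ldaep", subject_index)
    fs = cfg.sampling_rate
    intensities = np.repeat([60, 70, 80, 90, 100], cfg.trials_per_intensity)
    rng.shuffle(intensities)
    isis = rng.uniform(*cfg.ldaep_isi_range, size=len(intensities))
    onsets_s = 1.0 + np.concatenate([[0.0], np.cumsum(isis[:-1])])
    n = int(round((onsets_s[-1] + 1.5) * fs))
    labels = list(cfg.montage)
    data = _pink_noise(rng, len(labels), n, cfg.noise_sd, fs)

    # component template on a 0..400 ms support
    t = np.arange(0, 0.4, 1.0 / fs)
    n1_shape = _gaussian_bump(t, 0.100, 0.020)
    p2_shape = _gaussian_bump(t, 0.200, 0.030)
    gains = np.array([0.7 if lab != "Cz" else 1.0 for lab in labels])

    events = []
    for onset, inten in zip(onsets_s, intensities):
        # peak-to-peak cannot go negative for an N1/P2 morphology: extreme
        # slope draws saturate at a small positive floor
        p2p = max(cfg.n1_base + cfg.p2_base + slope * (inten - 80) / 10.0, 0.25)
        wave = -0.5 * p2p * n1_shape + 0.5 * p2p * p2_shape
        samp = int(round(onset * fs))
        _add_component(data, samp, wave, gains)
        events.append((samp, str(int(inten))))

    return Recording(subject_id=subject_id, paradigm="ldaep",
                     channel_labels=labels, sampling_rate=fs, data=data,
                     events=events,
                     meta={"ground_truth_slope": float(slope),
                           "generator": "synthgen.gen_ldaep_recording"})


def gen_mmn_recording(cfg: SimulationConfig, subject_id: str = "S001",
                      subject_index: int = 0, mmn_amp: float = None) -> Recording:
    """Auditory oddball recording for the MMN paradigm.

    ``mmn_n_stimuli`` tones (deviants at ``mmn_deviant_prob``, exact count,
    randomized order) at a fixed inter-stimulus interval. Standards and
    deviants share a common N1/P2 response; deviants additionally carry a
    negative Hann-windowed deflection over 130-280 ms at the nine
    frontocentral sites whose window mean equals ``mmn_amp``.
    """
    if mmn_amp is None:
        mmn_amp = cfg.mmn_amp_true
    rng = cfg.rng("mmn", subject_index)
    fs = cfg.sampling_rate
    n_dev = int(round(cfg.mmn_n_stimuli * cfg.mmn_deviant_prob))
    codes = np.array(["standard"] * (cfg.mmn_n_stimuli - n_dev) + ["deviant"] * n_dev)
    rng.shuffle(codes)
    onsets_s = 1.0 + cfg.mmn_isi * np.arange(cfg.mmn_n_stimuli)
    n = int(round((onsets_s[-1] + 1.0) * fs))
    labels = list(cfg.montage)
    data = _pink_noise(rng, len(labels), n, cfg.noise_sd, fs)

    t = np.arange(0, 0.4, 1.0 / fs)
    common = -1.5 * _gaussian_bump(t, 0.100, 0.020) + 2.0 * _gaussian_bump(t, 0.180, 0.030)
    # Hann bump over exactly 130-280 ms: window mean = peak / 2
    in_win = (t >= 0.130) & (t <= 0.280)
    hann = np.zeros_like(t)
    tw = t[in_win]
    hann[in_win] = 0.5 * (1 - np.cos(2 * np.pi * (tw - 0.130) / (0.280 - 0.130)))
    mmn_shape = 2.0 * mmn_amp * hann

    mmn_sites = {"F3", "Fz", "F4", "FC3", "FCz", "FC4", "C3", "Cz", "C4"}
    gains = np.ones(len(labels))
    mmn_gains = np.array([1.0 if lab in mmn_sites else 0.5 for lab in labels])

    events = []
    for onset, code in zip(onsets_s, codes):
        samp = int(round(onset * fs))
        _add_component(data, samp, common, gains)
        if code == "deviant":
            _add_component(data, samp, mmn_shape, mmn_gains)
        events.append((samp, str(code)))

    return Recording(subject_id=subject_id, paradigm="mmn",
                     channel_labels=labels, sampling_rate=fs, data=data,
                     events=events,
                     meta={"ground_truth_mmn": float(mmn_amp),
                           "generator": "synthgen.gen_mmn_recording"})


def gen_clinical_cohort(cfg: SimulationConfig, truth: GroundTruth = None):
    """Clinical records whose HAM-D decline depends on the FAA group.

    Returns ``(records, truth)``. HAM-D trajectories follow
    ``hamd_w = baseline * (1 - recovery * week_fraction(w)) + noise``,
    rounded and truncated at 0, where each subject's fractional recovery
    is Gaussian around the pooled mean plus/minus half the group effect
    (low-FAA group recovers more when ``group_effect > 0``). CORE is a
    rounded truncated Gaussian correlated with the true F7/F8 asymmetry at
    ``cfg.core_faa_corr``.
    """
    if cfg.n_subjects < 8:
        raise ValueError("cohort generation needs n_subjects >= 8")
    if truth is None:
        truth = draw_ground_truth(cfg)
    rng = cfg.rng("clinical")
    n = cfg.n_subjects

    baseline = np.maximum(np.round(rng.normal(*cfg.hamd_baseline_dist, size=n)), 8)
    shift = np.where(np.array(truth.group) == "low",
                     cfg.group_effect / 2.0, -cfg.group_effect / 2.0)
    recovery = np.clip(rng.normal(cfg.recovery_mean + shift, cfg.recovery_sd),
                       -0.2, 1.0)

    z78 = (truth.faa_f7f8 - np.mean(truth.faa_f7f8)) / np.std(truth.faa_f7f8)
    rho = cfg.core_faa_corr
    z_core = rho * z78 + np.sqrt(max(0.0, 1 - rho ** 2)) * rng.standard_normal(n)
    core = np.maximum(np.round(cfg.core_dist[0] + cfg.core_dist[1] * z_core), 0)

    ages = np.clip(np.round(rng.normal(*cfg.age_dist, size=n)), 18, 85)
    sexes = np.where(rng.uniform(size=n) < cfg.female_prob, "female", "male")
    meds = np.where(rng.uniform(size=n) < cfg.vortioxetine_prob,
                    "vortioxetine", "escitalopram")
    hama0 = np.maximum(np.round(rng.normal(*cfg.hama_baseline_dist, size=n)), 0)

    records = []
    for i, sid in enumerate(truth.subject_ids):
        hamd = {}
        for w, frac in sorted(cfg.week_fraction.items()):
            noise = 0.0 if w == 0 else rng.normal(0, cfg.hamd_noise_sd)
            hamd[w] = int(max(round(baseline[i] * (1 - recovery[i] * frac) + noise), 0))
        hama8 = int(max(round(hama0[i] * (1 - 0.8 * recovery[i])
                              + rng.normal(0, cfg.hamd_noise_sd)), 0))
        records.append(ClinicalRecord(
            subject_id=sid, age=float(ages[i]), sex=str(sexes[i]),
            medication=str(meds[i]), hamd=hamd,
            hama_baseline=int(hama0[i]), hama_week8=hama8, core=int(core[i])))
    truth = replace(truth, recovery=recovery)
    return records, truth
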