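"""Seeded synthetic multichannel physiological recordings with fatigue structure.

Real multi-level fatigue recordings are private clinical data, so this module
generates surrogate recordings whose class structure mirrors the physiological
signatures of progressive driver fatigue:

* occipital EEG (O1/O2) loses alpha (8-13 Hz) power and gains theta (4-8 Hz)
  power as fatigue deepens;
* frontal channels (Fp1/Fp2) show fewer blink transients;
* heart rate falls (ECG), steering-related EMG bursts thin out, and the
  respiration waveform clips as breaths become shallow.

The signal model is deliberately simple and fully measurable: band-limited
stochastic oscillators (filtered white noise) plus deterministic event
templates, all driven by one ``numpy`` generator so that identical
``(config, seed)`` pairs reproduce bit-identical arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import hashlib
import json

import numpy as np
from scipy import signal as sps

EEG_FS = 250.0
POLY_FS = 120.0

EEG_CHANNELS = ("Fp1", "Fp2", "O1", "O2", "C3", "P4")
POLY_CHANNELS = ("ECG", "EMG", "RESP")
ALL_CHANNELS = EEG_CHANNELS + POLY_CHANNELS

FATIGUE_LEVELS = (0, 1, 2, 3, 4)
LEVEL_NAMES = (
    "Normal",
    "Onset of Fatigue",
    "Mid Fatigue",
    "Warning of Fatigue",
    "Complete Fatigue",
)


@dataclass(frozen=True)
class SynthConfig:
    """Schedules (indexed by fatigue level 0..4) and band definitions.

    Amplitudes are in microvolts for EEG channels.  Each schedule has exactly
    five entries; alpha amplitude and blink/heart/EMG rates decrease with
    level while theta amplitude and respiration clipping increase, mirroring
    how fatigue manifests across modalities.  Magnitudes are calibration
    choices: adjacent levels overlap through the stochastic oscillator
    variance while extreme levels separate cleanly.
    """

    alpha_band: tuple[float, float] = (8.0, 13.0)
    theta_band: tuple[float, float] = (4.0, 8.0)
    alpha_amp_uv: tuple[float, ...] = (30.0, 25.0, 20.0, 15.0, 10.0)
    theta_amp_uv: tuple[float, ...] = (8.0, 14.0, 20.0, 26.0, 32.0)
    blink_rate_per_min: tuple[float, ...] = (18.0, 14.0, 10.0, 6.0, 2.0)
    heart_rate_bpm: tuple[float, ...] = (72.0, 66.0, 60.0, 54.0, 48.0)
    emg_burst_rate_per_min: tuple[float, ...] = (30.0, 24.0, 18.0, 12.0, 6.0)
    resp_clip_fraction: tuple[float, ...] = (0.0, 0.1, 0.2, 0.35, 0.5)
    noise_sd_uv: float = 6.0
    blink_amp_uv: float = 90.0
    parietal_weight: float = 0.7  # alpha/theta schedule weight on P4/C3
    frontal_osc_weight: float = 0.3
    resp_rate_hz: float = 0.25

    def __post_init__(self) -> None:
        for name in (
            "alpha_amp_uv",
            "theta_amp_uv",
            "blink_rate_per_min",
            "heart_rate_bpm",
            "emg_burst_rate_per_min",
            "resp_clip_fraction",
        ):
            if len(getattr(self, name)) != 5:
                raise ValueError(f"{name} must have exactly 5 entries (levels 0-4)")
        decreasing = ("alpha_amp_uv", "blink_rate_per_min", "heart_rate_bpm",
                      "emg_burst_rate_per_min")
        for name in decreasing:
            v = getattr(self, name)
            if any(a < b for a, b in zip(v, v[1:])):
                raise ValueError(f"{name} must be non-increasing with fatigue level")
        for name in ("theta_amp_uv", "resp_clip_fraction"):
            v = getattr(self, name)
            if any(a > b for a, b in zip(v, v[1:])):
                raise ValueError(f"{name} must be non-decreasing with fatigue level")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class Recording:
    """One labeled multichannel recording.

    EEG channels are sampled at 250 Hz; ECG/EMG/respiration at 120 Hz.
    """

    channels: dict[str, np.ndarray]
    fs: dict[str, float]
    duration_s: float
    fatigue_level: int
    subject_id: str = "synthetic"
    seed: int | None = None

    def channel_fs(self, label: str) -> float:
        return self.fs["eeg"] if label in EEG_CHANNELS else self.fs["poly"]

    def validate(self) -> None:
        if self.fatigue_level not in FATIGUE_LEVELS:
            raise ValueError(f"fatigue_level must be in {FATIGUE_LEVELS}")
        for label, x in self.channels.items():
            expected = int(round(self.duration_s * self.channel_fs(label)))
            if x.shape != (expected,):
                raise ValueError(
                    f"channel {label}: expected {expected} samples, got {x.shape}"
                )


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                band: tuple[float, float], sd: float) -> np.ndarray:
    """Gaussian noise band-limited to ``band`` and rescaled to std ``sd``."""
    white = rng.standard_normal(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white)
    s = x.std()
    return x * (sd / s) if s > 0 else x


def blink_template(fs: float, width_s: float = 0.35) -> np.ndarray:
    """Smooth biphasic blink transient (positive lobe then shallow undershoot)."""
    n = int(round(width_s * fs))
    t = np.linspace(-1.0, 1.0, n)
    main = np.exp(-(t / 0.35) ** 2)
    under = -0.3 * np.exp(-((t - 0.55) / 0.3) ** 2)
    w = main + under
    return w / np.abs(w).max()


def _event_train(rng: np.random.Generator, n: int, fs: float,
                 rate_per_min: float, template: np.ndarray,
                 jitter: float = 0.25) -> np.ndarray:
    """Superpose ``template`` at jittered-regular event times."""
    out = np.zeros(n)
    if rate_per_min <= 0:
        return out
    period = 60.0 / rate_per_min * fs
    pos = 0.6 * period
    while pos < n:
        i = int(round(pos))
        seg = template[: n - i]
        out[i: i + len(seg)] += seg
        pos += period * (1.0 + jitter * (rng.random() - 0.5) * 2)
    return out


def _qrs_template(fs: float) -> np.ndarray:
    n = int(round(0.12 * fs))
    t = np.linspace(-1, 1, n)
    return np.exp(-(t / 0.22) ** 2) - 0.25 * np.exp(-((t + 0.55) / 0.25) ** 2)


def generate_recording(level: int, duration_s: float, config: SynthConfig | None = None,
                       seed: int = 0, subject_id: str = "synthetic") -> Recording:
    """Generate one multichannel recording at the given fatigue level.

    Parameters
    ----------
    level : int
        Fatigue level 0 (normal) .. 4 (complete fatigue).
    duration_s : float
        Recording length in seconds (> 0).
    config : SynthConfig, optional
        Schedules; defaults describe the standard study conditions.
    seed : int
        Any identical (level, duration_s, config, seed) call reproduces
        bit-identical arrays.
    """
    if level not in FATIGUE_LEVELS:
        raise ValueError(f"level must be one of {FATIGUE_LEVELS}, got {level!r}")
    if not duration_s > 0:
        raise ValueError(f"duration_s must be positive, got {duration_s}")
    config = config or SynthConfig()

    n_eeg = int(round(duration_s * EEG_FS))
    n_poly = int(round(duration_s * POLY_FS))
    # one child stream per channel so content is order-independent
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(level,))
    streams = {name: np.random.default_rng(child)
               for name, child in zip(ALL_CHANNELS, ss.spawn(len(ALL_CHANNELS)))}

    a_amp = config.alpha_amp_uv[level]
    t_amp = config.theta_amp_uv[level]
    channels: dict[str, np.ndarray] = {}

    tmpl = blink_template(EEG_FS) * config.blink_amp_uv
    for name in EEG_CHANNELS:
        rng = streams[name]
        if name in ("O1", "O2"):
            w = 1.0
        elif name in ("P4", "C3"):
            w = config.parietal_weight
        else:
            w = config.frontal_osc_weight
        x = (_band_noise(rng, n_eeg, EEG_FS, config.alpha_band, w * a_amp)
             + _band_noise(rng, n_eeg, EEG_FS, config.theta_band, w * t_amp)
             + rng.standard_normal(n_eeg) * config.noise_sd_uv)
        if name in ("Fp1", "Fp2"):
            x = x + _event_train(rng, n_eeg, EEG_FS,
                                 config.blink_rate_per_min[level], tmpl)
        channels[name] = x

    rng = streams["ECG"]
    qrs = _qrs_template(POLY_FS) * 1000.0  # ~1 mV R peaks
    ecg = _event_train(rng, n_poly, POLY_FS, config.heart_rate_bpm[level], qrs,
                       jitter=0.05)
    channels["ECG"] = ecg + rng.standard_normal(n_poly) * 15.0

    rng = streams["EMG"]
    burst_len = int(round(0.2 * POLY_FS))
    emg = np.zeros(n_poly)
    rate = config.emg_burst_rate_per_min[level]
    if rate > 0:
        period = 60.0 / rate * POLY_FS
        pos = 0.4 * period
        while pos < n_poly:
            i = int(round(pos))
            seg = rng.standard_normal(min(burst_len, n_poly - i)) * 120.0
            env = np.hanning(burst_len)[: len(seg)]
            emg[i: i + len(seg)] += seg * env
            pos += period * (1.0 + 0.3 * (rng.random() - 0.5) * 2)
    channels["EMG"] = emg + rng.standard_normal(n_poly) * 10.0

    rng = streams["RESP"]
    t = np.arange(n_poly) / POLY_FS
    phase = rng.uniform(0, 2 * np.pi)
    resp = np.sin(2 * np.pi * config.resp_rate_hz * t + phase)
    clip = config.resp_clip_fraction[level]
    lim = 1.0 - clip
    resp = np.clip(resp, -lim, lim)
    channels["RESP"] = resp * 100.0 + rng.standard_normal(n_poly) * 2.0

    rec = Recording(
        channels=channels,
        fs={"eeg": EEG_FS, "poly": POLY_FS},
        duration_s=float(duration_s),
        fatigue_level=level,
        subject_id=subject_id,
        seed=seed,
    )
    rec.validate()
    return rec


@dataclass
class LabeledRecordings:
    """A class-balanced collection of short recordings with fatigue labels."""

    recordings: list[Recording]
    labels: np.ndarray
    config: SynthConfig = field(default_factory=SynthConfig)
    seed: int | None = None

    def __len__(self) -> int:
        return len(self.recordings)

    def __iter__(self):
        return iter(zip(self.recordings, self.labels))


def generate_dataset(n_per_class: int, levels=FATIGUE_LEVELS,
                     epoch_len_s: float = 15.0,
                     config: SynthConfig | None = None,
                     seed: int = 0) -> LabeledRecordings:
    """Generate ``len(levels) * n_per_class`` epoch-length recordings.

    Each recording is ``epoch_len_s`` long (default 15 s, i.e. 3750 samples
    per EEG channel), so the collection is directly consumable by the
    preprocessing pipeline whose middle-window stage is then the identity.
    """
    levels = tuple(sorted(set(int(v) for v in levels)))
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not levels:
        raise ValueError("levels must be a non-empty subset of {0..4}")
    for lv in levels:
        if lv not in FATIGUE_LEVELS:
            raise ValueError(f"invalid fatigue level {lv}")
    config = config or SynthConfig()

    recs: list[Recording] = []
    labels: list[int] = []
    for lv in levels:
        for i in range(n_per_class):
            # distinct per-epoch seed, deterministic in (seed, level, index)
            epoch_seed = (seed * 100003 + lv * 1009 + i) % (2**31 - 1)
            recs.append(generate_recording(lv, epoch_len_s, config,
                                           seed=epoch_seed,
                                           subject_id=f"S{lv}-{i:04d}"))
            labels.append(lv)
    return LabeledRecordings(recs, np.asarray(labels, dtype=np.int64),
                             config=config, seed=seed)


def band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Integral of the Welch power spectral density over ``band`` (Hz).

    For a unit-amplitude sinusoid inside the band this approaches its mean
    power of 0.5.
    """
    lo, hi = band
    if not (0 < lo < hi < fs / 2):
        raise ValueError(f"band {band} must lie within (0, {fs / 2}) Hz")
    x = np.asarray(x, dtype=float)
    nperseg = int(min(len(x), 4 * fs))
    f, psd = sps.welch(x, fs=fs, nperseg=nperseg)
    mask = (f >= lo) & (f <= hi)
    if mask.sum() < 2:
        return 0.0
    return float(np.trapezoid(psd[mask], f[mask]))


def theta_alpha_ratio(x: np.ndarray, fs: float = EEG_FS,
                      config: SynthConfig | None = None) -> float:
    """Theta/alpha band-power ratio, the workhorse fatigue index."""
    config = config or SynthConfig()
    a = band_power(x, fs, config.alpha_band)
    t = band_power(x, fs, config.theta_band)
    return t / a if a > 0 else np.inf


def count_blinks(x: np.ndarray, fs: float = EEG_FS, threshold_uv: float = 45.0,
                 refractory_s: float = 0.3) -> int:
    """Count blink-like transients by thresholding with a refractory period."""
    above = x > threshold_uv
    count = 0
    i = 0
    refractory = int(refractory_s * fs)
    n = len(x)
    while i < n:
        if above[i]:
            count += 1
            i += refractory
        else:
            i += 1
    return count
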