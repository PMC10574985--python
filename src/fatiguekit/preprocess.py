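"""Preprocessing chain: raw recordings to normalized EEG epochs.

Five deterministic stages, applied in order:

1. middle-window extraction (15 s from the centre of the recording),
2. 50 Hz mains notch,
3. first-order Butterworth band-pass 0.05-60 Hz,
4. blink suppression using the frontal channels as reference,
5. per-channel min-max normalization to [0, 1].

Filters run forward-backward (zero phase) so event morphology is not
skewed.  Blink suppression is template subtraction: supra-threshold slow
transients detected on the frontal channels (threshold k * MAD, k = 6) are
low-pass modelled and regressed out of every channel over the detected
window, leaving non-blink segments untouched.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator, TransformerMixin

from .io import EpochDataset
from .synth import EEG_CHANNELS, EEG_FS, LabeledRecordings, Recording

DEFAULT_CHANNELS = ("P4", "C3", "O1", "O2")
FRONTAL_CHANNELS = ("Fp1", "Fp2")

PIPELINE_STEPS = ("middle_window", "notch", "bandpass_butterworth",
                  "remove_blinks", "minmax01")


@dataclass
class Epoch:
    """One preprocessed classifier example: channels x samples in [0, 1]."""

    data: np.ndarray
    fs: float
    label: int
    channel_names: tuple[str, ...]
    provenance: tuple[str, ...] = ()


def select_middle_window(recording: Recording, window_s: float = 15.0,
                         channels=None) -> dict[str, np.ndarray]:
    """Extract the centred ``window_s`` seconds from each EEG channel.

    Returns a label -> samples dict.  For a 300 s recording at 250 Hz the
    half-open sample window is [35625, 39375).
    """
    if recording.duration_s + 1e-9 < window_s:
        raise ValueError(
            f"recording of {recording.duration_s} s is shorter than the "
            f"{window_s} s window")
    channels = tuple(channels) if channels is not None else tuple(
        c for c in recording.channels if c in EEG_CHANNELS)
    out = {}
    for c in channels:
        x = recording.channels[c]
        fs = recording.channel_fs(c)
        n_win = int(round(window_s * fs))
        start = int(round((recording.duration_s - window_s) / 2 * fs))
        out[c] = x[start: start + n_win].copy()
    return out


def notch(x: np.ndarray, fs: float = EEG_FS, freq: float = 50.0,
          quality_factor: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch at the mains frequency (default 50 Hz)."""
    if fs <= 2 * freq:
        raise ValueError(f"fs={fs} too low to notch {freq} Hz (needs fs > {2*freq})")
    b, a = sps.iirnotch(freq, quality_factor, fs=fs)
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        return x
    return sps.filtfilt(b, a, x, axis=-1)


def notch_50(x: np.ndarray, fs: float = EEG_FS,
             quality_factor: float = 30.0) -> np.ndarray:
    return notch(x, fs, 50.0, quality_factor)


def bandpass_butterworth(x: np.ndarray, fs: float = EEG_FS,
                         low: float = 0.05, high: float = 60.0,
                         order: int = 1) -> np.ndarray:
    """Zero-phase Butterworth band-pass (default first order, 0.05-60 Hz)."""
    if not (0 < low < high < fs / 2):
        raise ValueError(f"band ({low}, {high}) must satisfy 0 < low < high < fs/2")
    sos = sps.butter(order, (low, high), btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(x, dtype=float), axis=-1)


def _lowpass(x: np.ndarray, fs: float, cutoff: float = 8.0) -> np.ndarray:
    sos = sps.butter(4, cutoff, btype="lowpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def detect_blink_windows(frontal: np.ndarray, fs: float = EEG_FS,
                         k_mad: float = 6.0,
                         half_width_s: float = 0.3) -> list[tuple[int, int]]:
    """Find supra-threshold slow transients on a frontal reference trace."""
    slow = _lowpass(frontal, fs)
    mad = np.median(np.abs(slow - np.median(slow)))
    thresh = k_mad * 1.4826 * mad
    if thresh <= 0:
        return []
    above = np.abs(slow) > thresh
    windows: list[tuple[int, int]] = []
    half = int(half_width_s * fs)
    i, n = 0, len(frontal)
    while i < n:
        if above[i]:
            peak = i + int(np.argmax(np.abs(slow[i: i + 2 * half])))
            lo, hi = max(0, peak - half), min(n, peak + half)
            if windows and lo <= windows[-1][1]:
                windows[-1] = (windows[-1][0], hi)
            else:
                windows.append((lo, hi))
            i = hi
        else:
            i += 1
    return windows


def remove_blinks(data: dict[str, np.ndarray] | np.ndarray,
                  channel_names=None, fs: float = EEG_FS,
                  frontal_reference_channels=FRONTAL_CHANNELS,
                  k_mad: float = 6.0):
    """Suppress blink transients via frontal-referenced template subtraction.

    The blink waveform is the low-passed frontal mean over each detected
    window (baseline removed); every channel has its least-squares-scaled
    copy of that waveform subtracted over the window only.  Channels with no
    blink leakage get a near-zero scale and are left essentially unchanged.
    """
    if isinstance(data, dict):
        names = tuple(data)
        arr = np.stack([data[c] for c in names])
    else:
        arr = np.asarray(data, dtype=float)
        names = tuple(channel_names) if channel_names is not None else ()
        if arr.ndim == 1:
            arr = arr[None, :]
    frontal_idx = [i for i, c in enumerate(names)
                   if c in frontal_reference_channels]
    if not frontal_idx:
        raise ValueError(
            "blink removal needs at least one frontal reference channel "
            f"({', '.join(frontal_reference_channels)}) in the epoch")
    out = arr.astype(float).copy()
    ref = arr[frontal_idx].mean(axis=0)
    for lo, hi in detect_blink_windows(ref, fs, k_mad=k_mad):
        b = _lowpass(ref, fs)[lo:hi]
        b = b - np.linspace(b[0], b[-1], len(b))  # detrend the window
        denom = float(b @ b)
        if denom <= 0:
            continue
        for ch in range(out.shape[0]):
            seg = out[ch, lo:hi]
            beta = float(seg @ b) / denom
            out[ch, lo:hi] = seg - beta * b
    if isinstance(data, dict):
        return {c: out[i] for i, c in enumerate(names)}
    return out if np.asarray(data).ndim > 1 else out[0]


def minmax01(x: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1] along the last axis.

    Constant input maps to all zeros (documented convention).
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("minmax01 requires a non-empty signal")
    lo = x.min(axis=-1, keepdims=True)
    hi = x.max(axis=-1, keepdims=True)
    span = hi - lo
    out = np.zeros_like(x)
    np.divide(x - lo, span, out=out, where=span > 0)
    return out


class EpochPreprocessor(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer running the full preprocessing chain.

    Parameters
    ----------
    channels : tuple of str
        EEG channels kept for classification (default P4, C3, O1, O2).
    window_s : float
        Middle-window length in seconds.
    mains_freq, notch_q : float
        Mains notch frequency (default 50 Hz) and quality factor.
    band, butter_order : filter band (Hz) and Butterworth order.
    blink_removal : bool
        Whether to run frontal-referenced blink suppression.
    per_channel_norm : bool
        Min-max normalize each channel separately (default) rather than
        over the whole epoch.
    """

    def __init__(self, channels=DEFAULT_CHANNELS, window_s: float = 15.0,
                 mains_freq: float = 50.0, notch_q: float = 30.0,
                 band=(0.05, 60.0), butter_order: int = 1,
                 blink_removal: bool = True, per_channel_norm: bool = True,
                 frontal_reference=FRONTAL_CHANNELS):
        self.channels = channels
        self.window_s = window_s
        self.mains_freq = mains_freq
        self.notch_q = notch_q
        self.band = band
        self.butter_order = butter_order
        self.blink_removal = blink_removal
        self.per_channel_norm = per_channel_norm
        self.frontal_reference = frontal_reference

    def fit(self, X, y=None):
        self.n_features_in_ = len(self.channels)
        return self

    def transform_recording(self, recording: Recording,
                            label: int | None = None) -> Epoch:
        keep = tuple(self.channels)
        ref = tuple(c for c in self.frontal_reference
                    if c in recording.channels) if self.blink_removal else ()
        win = select_middle_window(recording, self.window_s, keep + ref)
        names = tuple(win)
        arr = np.stack([win[c] for c in names])
        fs = EEG_FS
        arr = notch(arr, fs, self.mains_freq, self.notch_q)
        arr = bandpass_butterworth(arr, fs, self.band[0], self.band[1],
                                   self.butter_order)
        steps = ["middle_window", "notch", "bandpass_butterworth"]
        if self.blink_removal:
            arr = remove_blinks(arr, names, fs, self.frontal_reference)
            steps.append("remove_blinks")
        sel = [names.index(c) for c in keep]
        arr = arr[sel]
        if self.per_channel_norm:
            arr = minmax01(arr)
        else:
            arr = minmax01(arr.reshape(1, -1)).reshape(arr.shape)
        steps.append("minmax01")
        return Epoch(arr, fs,
                     recording.fatigue_level if label is None else label,
                     keep, tuple(steps))

    def transform_epochs(self, ds: EpochDataset) -> EpochDataset:
        """Run the filtering/normalization stages on an already-epoched
        dataset (the middle-window stage is the identity here)."""
        names = ds.channel_names
        keep = tuple(self.channels)
        missing = [c for c in keep if c not in names]
        if missing:
            raise ValueError(f"dataset lacks channels {missing}")
        out = []
        steps = ["middle_window", "notch", "bandpass_butterworth"]
        for arr in ds.epochs:
            a = notch(arr, ds.fs, self.mains_freq, self.notch_q)
            a = bandpass_butterworth(a, ds.fs, self.band[0], self.band[1],
                                     self.butter_order)
            if self.blink_removal:
                a = remove_blinks(a, names, ds.fs, self.frontal_reference)
            a = a[[names.index(c) for c in keep]]
            out.append(minmax01(a) if self.per_channel_norm
                       else minmax01(a.reshape(1, -1)).reshape(a.shape))
        if self.blink_removal:
            steps.append("remove_blinks")
        steps.append("minmax01")
        return EpochDataset(np.stack(out), ds.labels, keep, ds.fs,
                            tuple(steps), ds.synthetic, ds.seed,
                            ds.config_hash)

    def transform(self, X) -> EpochDataset:
        """Preprocess recordings into an EpochDataset.

        ``X`` is a LabeledRecordings collection or an iterable of Recording.
        """
        if isinstance(X, LabeledRecordings):
            pairs = list(X)
            seed, cfg_hash = X.seed, X.config.hash()
        else:
            pairs = [(r, r.fatigue_level) for r in X]
            seed, cfg_hash = None, ""
        epochs, labels, prov = [], [], ()
        for rec, label in pairs:
            ep = self.transform_recording(rec, label)
            epochs.append(ep.data)
            labels.append(ep.label)
            prov = ep.provenance
        return EpochDataset(np.stack(epochs), np.asarray(labels),
                            tuple(self.channels), EEG_FS, prov,
                            seed=seed, config_hash=cfg_hash)


def preprocess_pipeline(recording: Recording, config: EpochPreprocessor | None = None) -> Epoch:
    """Run the five-stage chain on one recording (module-level convenience)."""
    pre = config or EpochPreprocessor()
    return pre.transform_recording(recording)
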