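"""On-disk interchange: EDF for recordings, HDF5 for epoch datasets.

EDF (European Data Format) is the standard interchange format for
polygraphic biosignal recordings: a fixed-layout ASCII header followed by
one-second data records of little-endian 16-bit integers, with per-signal
physical/digital calibration ranges.  Both writer and reader are implemented
here; samples survive a round trip to within the format's 16-bit
quantization of each channel's physical range.

Epoch datasets (n_epochs x channels x samples plus labels and provenance)
are stored in a single HDF5 file via h5py.
"""

from __future__ import annotations

from dataclasses import dataclass
import datetime as _dt
import json

import h5py
import numpy as np

from .synth import EEG_CHANNELS, EEG_FS, POLY_FS, Recording

_HDR = 256  # bytes of the fixed header and of each per-signal block


def _pad(value: str, width: int) -> bytes:
    b = str(value).encode("ascii")
    if len(b) > width:
        b = b[:width]
    return b.ljust(width)


def write_edf(path, recording: Recording) -> None:
    """Write a Recording to an EDF file (one-second data records).

    The recording duration must be a whole number of seconds so that every
    channel fills its records exactly.
    """
    dur = recording.duration_s
    n_records = int(round(dur))
    if abs(dur - n_records) > 1e-9:
        raise ValueError("EDF export requires an integer number of seconds")

    labels = list(recording.channels)
    samples_per_record = [int(round(recording.channel_fs(c))) for c in labels]
    ns = len(labels)

    phys_min, phys_max, scaled = [], [], []
    dig_min, dig_max = -32767, 32767
    for c in labels:
        x = np.asarray(recording.channels[c], dtype=float)
        lo, hi = float(x.min()), float(x.max())
        if hi - lo < 1e-9:  # constant channel: widen to a valid range
            lo, hi = lo - 1.0, hi + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        gain = (dig_max - dig_min) / (hi - lo)
        d = np.round((x - lo) * gain + dig_min).astype("<i2")
        scaled.append(d)

    now = _dt.datetime(2000, 1, 1)
    meta = json.dumps({"level": recording.fatigue_level,
                       "subject": recording.subject_id,
                       "seed": recording.seed})
    header = b"".join([
        _pad("0", 8),
        _pad(recording.subject_id, 80),
        _pad(meta, 80),
        _pad(now.strftime("%d.%m.%y"), 8),
        _pad(now.strftime("%H.%M.%S"), 8),
        _pad(str(_HDR * (1 + ns)), 8),
        _pad("", 44),
        _pad(str(n_records), 8),
        _pad("1", 8),
        _pad(str(ns), 4),
    ])
    fields = [
        [_pad(c, 16) for c in labels],
        [_pad("AgAgCl electrode", 80)] * ns,
        [_pad("uV", 8)] * ns,
        [_pad(f"{v:.6g}"[:8], 8) for v in phys_min],
        [_pad(f"{v:.6g}"[:8], 8) for v in phys_max],
        [_pad(str(dig_min), 8)] * ns,
        [_pad(str(dig_max), 8)] * ns,
        [_pad("", 80)] * ns,
        [_pad(str(spr), 8) for spr in samples_per_record],
        [_pad("", 32)] * ns,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for group in fields:
            fh.write(b"".join(group))
        for r in range(n_records):
            for d, spr in zip(scaled, samples_per_record):
                fh.write(d[r * spr: (r + 1) * spr].tobytes())


def read_edf(path) -> Recording:
    """Read an EDF file written by :func:`write_edf` back into a Recording."""
    with open(path, "rb") as fh:
        raw = fh.read()

    def f(offset: int, width: int) -> str:
        return raw[offset: offset + width].decode("ascii", "replace").strip()

    subject = f(8, 80)
    try:
        meta = json.loads(f(88, 80))
    except json.JSONDecodeError:
        meta = {}
    header_bytes = int(f(184, 8))
    n_records = int(f(236, 8))
    record_dur = float(f(244, 8))
    ns = int(f(252, 4))

    def sig_field(base: int, width: int):
        out = []
        off = _HDR + base * ns
        for i in range(ns):
            out.append(raw[off + i * width: off + (i + 1) * width]
                       .decode("ascii", "replace").strip())
        return out

    # per-signal blocks are stored field-major; compute byte offsets
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    offsets = np.concatenate([[0], np.cumsum(widths)[:-1]])
    labels = sig_field(int(offsets[0]), 16)
    phys_min = [float(v) for v in sig_field(int(offsets[3]), 8)]
    phys_max = [float(v) for v in sig_field(int(offsets[4]), 8)]
    dig_min = [int(v) for v in sig_field(int(offsets[5]), 8)]
    dig_max = [int(v) for v in sig_field(int(offsets[6]), 8)]
    spr = [int(v) for v in sig_field(int(offsets[8]), 8)]

    data = np.frombuffer(raw[header_bytes:], dtype="<i2")
    per_record = sum(spr)
    channels: dict[str, np.ndarray] = {c: [] for c in labels}
    for r in range(n_records):
        rec = data[r * per_record: (r + 1) * per_record]
        pos = 0
        for c, n in zip(labels, spr):
            channels[c].append(rec[pos: pos + n])
            pos += n
    out: dict[str, np.ndarray] = {}
    for i, c in enumerate(labels):
        d = np.concatenate(channels[c]).astype(float)
        gain = (phys_max[i] - phys_min[i]) / (dig_max[i] - dig_min[i])
        out[c] = (d - dig_min[i]) * gain + phys_min[i]

    rec = Recording(
        channels=out,
        fs={"eeg": EEG_FS, "poly": POLY_FS},
        duration_s=n_records * record_dur,
        fatigue_level=int(meta.get("level", 0)),
        subject_id=meta.get("subject", subject),
        seed=meta.get("seed"),
    )
    return rec


def epochs_from_recordings(collection, channels=EEG_CHANNELS) -> "EpochDataset":
    """Stack the EEG channels of equal-length recordings into an EpochDataset."""
    recs = getattr(collection, "recordings", collection)
    labels = getattr(collection, "labels",
                     np.asarray([r.fatigue_level for r in recs]))
    config = getattr(collection, "config", None)
    epochs = np.stack([[r.channels[c] for c in channels] for r in recs])
    return EpochDataset(
        epochs, labels, tuple(channels), EEG_FS, ("synth",),
        seed=getattr(collection, "seed", None),
        config_hash=config.hash() if config is not None else "")


@dataclass
class EpochDataset:
    """In-memory epoch container: ``epochs`` (n, channels, samples) + labels.

    ``synthetic`` flags GAN-generated epochs; ``provenance`` records the
    ordered preprocessing steps applied to all epochs.
    """

    epochs: np.ndarray
    labels: np.ndarray
    channel_names: tuple[str, ...]
    fs: float = EEG_FS
    provenance: tuple[str, ...] = ()
    synthetic: np.ndarray | None = None
    seed: int | None = None
    config_hash: str = ""

    def __post_init__(self):
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n, channels, samples)")
        if len(self.labels) != len(self.epochs):
            raise ValueError("labels length must match epochs")
        if self.synthetic is None:
            self.synthetic = np.zeros(len(self.labels), dtype=bool)
        self.synthetic = np.asarray(self.synthetic, dtype=bool)

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_samples(self) -> int:
        return self.epochs.shape[2]

    def subset(self, idx) -> "EpochDataset":
        idx = np.asarray(idx)
        return EpochDataset(self.epochs[idx], self.labels[idx],
                            self.channel_names, self.fs, self.provenance,
                            self.synthetic[idx], self.seed, self.config_hash)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("epochs", data=self.epochs)
            fh.create_dataset("labels", data=self.labels)
            fh.create_dataset("synthetic", data=self.synthetic)
            fh.attrs["fs"] = self.fs
            fh.attrs["channel_names"] = json.dumps(list(self.channel_names))
            fh.attrs["provenance"] = json.dumps(list(self.provenance))
            fh.attrs["epoch_len_s"] = self.n_samples / self.fs
            fh.attrs["seed"] = -1 if self.seed is None else int(self.seed)
            fh.attrs["config_hash"] = self.config_hash

    @classmethod
    def from_hdf5(cls, path) -> "EpochDataset":
        with h5py.File(path, "r") as fh:
            seed = int(fh.attrs["seed"])
            return cls(
                epochs=fh["epochs"][...],
                labels=fh["labels"][...],
                channel_names=tuple(json.loads(fh.attrs["channel_names"])),
                fs=float(fh.attrs["fs"]),
                provenance=tuple(json.loads(fh.attrs["provenance"])),
                synthetic=fh["synthetic"][...],
                seed=None if seed < 0 else seed,
                config_hash=str(fh.attrs["config_hash"]),
            )
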