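"""Recording container, EDF/CSV input-output, and the preprocessing chain.

The chain applied to every channel, in order: min-max normalization to [0, 1],
a 50 Hz notch to remove mains interference, then a 1-30 Hz Butterworth
band-pass. All filtering is zero-phase (forward-backward application).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import _edf
from .errors import ChannelError, ConfigurationError
from .montage import CHANNELS_1020

logger = logging.getLogger(__name__)


@dataclass
class Recording:
    """One subject's labelled multichannel EEG."""

    subject_id: str
    samples: np.ndarray            # channels x time
    fs: float
    channel_labels: tuple = CHANNELS_1020
    group: str | None = None
    preprocessed: bool = False

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ConfigurationError("samples must be 2-D (channels x time)")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ChannelError(
                f"{self.samples.shape[0]} sample rows but "
                f"{len(self.channel_labels)} channel labels")
        if not self.fs > 0:
            raise ConfigurationError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ConfigurationError("samples contain non-finite values")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class FilterSpec:
    """Settings of the preprocessing chain.

    The band edges and notch frequency are the method's constants; the filter
    order and notch quality factor are implementation choices (order-4
    Butterworth, Q=30) that meet the stated attenuation contracts.
    """

    notch_hz: float = 50.0
    bandpass_lo_hz: float = 1.0
    bandpass_hi_hz: float = 30.0
    butter_order: int = 4
    notch_q: float = 30.0

    def validate(self, fs: float) -> None:
        if not (0 < self.bandpass_lo_hz < self.bandpass_hi_hz < fs / 2):
            raise ConfigurationError(
                f"band edges ({self.bandpass_lo_hz}, {self.bandpass_hi_hz}) Hz "
                f"must satisfy 0 < lo < hi < fs/2 = {fs / 2} Hz")
        if self.butter_order < 1:
            raise ConfigurationError("butter_order must be >= 1")
        if fs <= 2 * self.notch_hz:
            raise ConfigurationError(
                f"fs={fs} Hz too low for a {self.notch_hz} Hz notch")


# ---------------------------------------------------------------------------
# input / output

def save_recording(rec: Recording, path, format: str = "edf") -> None:
    """Write *rec* to disk as EDF or CSV (columns = channel labels)."""
    path = Path(path)
    if format == "edf":
        _edf.write_edf(path, rec.samples, rec.fs, rec.channel_labels,
                       patient_id=rec.subject_id)
    elif format == "csv":
        df = pd.DataFrame(rec.samples.T, columns=list(rec.channel_labels))
        df.to_csv(path, index=False, float_format="%.8g")
    else:
        raise ConfigurationError(f"unknown format {format!r}")


def load_recording(path, format: str | None = None, fs: float | None = None,
                   subject_id: str | None = None,
                   group: str | None = None) -> Recording:
    """Load a Recording from an EDF or CSV file.

    Channels are reordered to the canonical 10-20 montage order when all 19
    labels are present. For CSV input the sampling rate must be supplied.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv"
    if format == "edf":
        import mne
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        labels = list(raw.ch_names)
        data = raw.get_data() * 1e6       # MNE loads EEG in volts; data is uV
        rate = float(raw.info["sfreq"])
    elif format == "csv":
        if fs is None:
            raise ConfigurationError("fs is required when loading CSV")
        df = pd.read_csv(path)
        bad = df.columns[df.dtypes == object]
        if len(bad):
            for col in bad:
                idx = df[pd.to_numeric(df[col], errors="coerce").isna()].index
                raise ConfigurationError(
                    f"non-numeric cell in column {col!r} at row "
                    f"{int(idx[0]) if len(idx) else '?'}")
        labels = list(df.columns)
        data = df.to_numpy(dtype=float).T
        rate = float(fs)
    else:
        raise ConfigurationError(f"unknown format {format!r}")

    if set(labels) >= set(CHANNELS_1020):
        order = [labels.index(ch) for ch in CHANNELS_1020]
        data = data[order]
        labels = list(CHANNELS_1020)
    elif set(labels) & set(CHANNELS_1020):
        missing = sorted(set(CHANNELS_1020) - set(labels))
        raise ChannelError(f"missing 10-20 channels: {', '.join(missing)}")
    if data.size == 0 or data.shape[0] < 1:
        raise ChannelError("file contains no channels")
    return Recording(subject_id=subject_id or path.stem, samples=data,
                     fs=rate, channel_labels=tuple(labels), group=group)


# ---------------------------------------------------------------------------
# preprocessing chain

def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Map a channel vector onto [0, 1]; a constant channel maps to all 0.5."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ConfigurationError("cannot normalize an empty vector")
    lo, hi = x.min(), x.max()
    if hi == lo:
        logger.warning("degenerate constant channel: normalizing to 0.5")
        return np.full_like(x, 0.5)
    return (x - lo) / (hi - lo)


def apply_notch(samples: np.ndarray, fs: float,
                spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Zero-phase IIR notch at ``spec.notch_hz`` applied along the last axis."""
    spec.validate(fs)
    b, a = sps.iirnotch(spec.notch_hz, spec.notch_q, fs=fs)
    return sps.filtfilt(b, a, np.asarray(samples, dtype=float), axis=-1)


def apply_bandpass(samples: np.ndarray, fs: float,
                   spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Zero-phase Butterworth band-pass applied along the last axis."""
    spec.validate(fs)
    sos = sps.butter(spec.butter_order,
                     [spec.bandpass_lo_hz, spec.bandpass_hi_hz],
                     btype="bandpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(samples, dtype=float), axis=-1)


def preprocess(rec: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Normalize each channel to [0, 1], notch out mains, band-pass 1-30 Hz."""
    if rec.preprocessed:
        raise ConfigurationError(
            f"recording {rec.subject_id!r} is already preprocessed")
    spec.validate(rec.fs)
    x = np.vstack([minmax_normalize(ch) for ch in rec.samples])
    x = apply_notch(x, rec.fs, spec)
    x = apply_bandpass(x, rec.fs, spec)
    return replace(rec, samples=x, preprocessed=True)
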