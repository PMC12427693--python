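"""Minimal European Data Format (EDF) writer.

Writes uncompressed 16-bit EDF files with one-second data records, enough for
round-tripping multichannel EEG through standard readers (``mne.io.read_raw_edf``
reads these files). Physical units are recorded as microvolts. This is a
writer only; reading goes through MNE.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

from .errors import ConfigurationError

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def _fmt_phys(v: float) -> str:
    """Format a physical-range bound into <= 8 ASCII chars, round-trippable."""
    for p in (6, 5, 4, 3, 2, 1):
        s = f"{v:.{p}g}"
        if len(s) <= 8:
            return s
    return f"{v:.0e}"[:8]


def write_edf(path, samples: np.ndarray, fs: float, channel_labels,
              patient_id: str = "X", recording_id: str = "eegdx") -> None:
    """Write a channels x time array to *path* as 16-bit EDF.

    Samples are interpreted as microvolts. The total duration must be a whole
    number of seconds (one-second data records are used).
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2:
        raise ConfigurationError("samples must be a 2-D channels x time array")
    n_ch, n_samp = samples.shape
    if len(channel_labels) != n_ch:
        raise ConfigurationError(
            f"channel_labels length {len(channel_labels)} != {n_ch} rows")
    fs_int = int(round(fs))
    if abs(fs - fs_int) > 1e-9 or fs_int <= 0:
        raise ConfigurationError("EDF writer requires an integer sampling rate")
    if n_samp % fs_int != 0:
        raise ConfigurationError(
            "EDF writer requires a whole number of seconds "
            f"({n_samp} samples at {fs_int} Hz)")
    n_records = n_samp // fs_int

    # per-channel symmetric physical range; quantization below reuses the
    # parsed header strings so writer and any reader agree exactly
    amp = np.abs(samples).max(axis=1)
    amp = np.where(amp <= 0, 1.0, amp) * (1 + 1e-4)
    smax = [_fmt_phys(a) for a in amp]
    smin = [_fmt_phys(-a) for a in amp]
    phys_max = np.array([float(s) for s in smax])
    phys_min = np.array([float(s) for s in smin])
    for i in range(n_ch):
        lo, hi = samples[i].min(), samples[i].max()
        while phys_max[i] < hi or phys_min[i] > lo:
            smax[i] = _fmt_phys(float(smax[i]) * 1.01 + 1e-9)
            smin[i] = _fmt_phys(float(smin[i]) * 1.01 - 1e-9)
            phys_max[i] = float(smax[i])
            phys_min[i] = float(smin[i])

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _field("0", 8),
        _field(patient_id, 80),
        _field(recording_id, 80),
        _field(now.strftime("%d.%m.%y"), 8),
        _field(now.strftime("%H.%M.%S"), 8),
        _field(str(256 * (1 + n_ch)), 8),
        _field("", 44),
        _field(str(n_records), 8),
        _field("1", 8),
        _field(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(_field(lbl, 16) for lbl in channel_labels),
        b"".join(_field("", 80) for _ in range(n_ch)),
        b"".join(_field("uV", 8) for _ in range(n_ch)),
        b"".join(_field(s, 8) for s in smin),
        b"".join(_field(s, 8) for s in smax),
        b"".join(_field(str(_DIG_MIN), 8) for _ in range(n_ch)),
        b"".join(_field(str(_DIG_MAX), 8) for _ in range(n_ch)),
        b"".join(_field("", 80) for _ in range(n_ch)),
        b"".join(_field(str(fs_int), 8) for _ in range(n_ch)),
        b"".join(_field("", 32) for _ in range(n_ch)),
    ])

    gain = (_DIG_MAX - _DIG_MIN) / (phys_max - phys_min)
    digital = np.rint((samples - phys_min[:, None]) * gain[:, None] + _DIG_MIN)
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for rec in range(n_records):
            chunk = digital[:, rec * fs_int:(rec + 1) * fs_int]
            fh.write(chunk.tobytes())
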