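"""The per-channel EEG feature battery and its assembly into a feature matrix.

Each of the 19 montage channels contributes 34 features under the default
``paper34`` layout:

* 2 full-signal spectral summaries (``freqmax``, ``powmax``);
* 15 measures computed on non-overlapping 2-s windows and aggregated as the
  mean and the variance across windows (30 values): spectral edge frequency,
  approximate entropy, log-energy entropy, permutation entropy, Tsallis and
  Renyi entropies, spectral entropy, dyadic-band spectral entropy, the three
  Hjorth parameters, kurtosis, skewness, Lempel-Ziv phrase count and its
  Kaspar-Schuster normalization;
* kurtosis and skewness means over non-overlapping 60-s windows (2 values).

That is 19 x 34 = 646 features per subject. Feature names follow the
``channel__feature__stat`` convention (``F7__ApEn__mean``), with the two
full-signal spectral summaries named ``channel__feature``.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import (ChannelError, ConfigurationError, DegenerateInputError,
                     SignalTooShortError)
from .montage import CHANNELS_1020
from .preprocess import Recording

logger = logging.getLogger(__name__)

#: dyadic (octave) bands inside the 1-30 Hz passband, in Hz
DYADIC_BANDS = ((1.0, 2.0), (2.0, 4.0), (4.0, 8.0), (8.0, 16.0), (16.0, 30.0))

#: features computed per 2-s window and aggregated as mean and variance
WINDOWED_FEATURES = (
    "spedge", "ApEn", "logenergy", "PermEn", "tsallis", "renyi",
    "spentropy", "spentropDyd", "activity", "mobility", "complexity",
    "kurt", "skew", "lempel", "kolmogorov",
)


@dataclass(frozen=True)
class FeatureParams:
    """Every estimator constant of the feature battery in one place.

    Defaults are the method's operating point: ApEn with m=2 and
    r = 0.25 x SD, permutation entropy with order 6 and lag 1, Renyi order 2,
    Tsallis q=2 on 1000-sample windows, Welch segments of 512 samples, 50%
    spectral edge, 2-s (1000-sample) and 60-s (30000-sample) windows at
    500 Hz, 32 amplitude-histogram bins for the probability-based entropies.
    """

    apen_m: int = 2
    apen_r_coeff: float = 0.25
    perm_m: int = 6
    perm_tau: int = 1
    renyi_alpha: float = 2.0
    tsallis_q: float = 2.0
    tsallis_k: int = 1000
    psd_nperseg: int = 512
    sef_fraction: float = 0.5
    window_2s_samples: int = 1000
    window_60s_samples: int = 30000
    hist_bins: int = 32
    eps_log: float = 1e-12
    band_lo_hz: float = 1.0
    band_hi_hz: float = 30.0

    def __post_init__(self):
        checks = [
            (self.apen_m >= 1, "apen_m must be >= 1"),
            (self.perm_m >= 2, "perm_m must be >= 2"),
            (self.perm_tau >= 1, "perm_tau must be >= 1"),
            (self.renyi_alpha != 1, "renyi_alpha must differ from 1"),
            (self.tsallis_q != 1, "tsallis_q must differ from 1"),
            (self.window_2s_samples > 0, "window_2s_samples must be positive"),
            (self.window_60s_samples > 0, "window_60s_samples must be positive"),
            (self.hist_bins >= 2, "hist_bins must be >= 2"),
            (self.eps_log > 0, "eps_log must be positive"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConfigurationError(msg)


@dataclass(frozen=True)
class Spectrum:
    """A one-sided power spectral density estimate."""

    freqs: np.ndarray
    power: np.ndarray

    def __post_init__(self):
        f = np.asarray(self.freqs, float)
        p = np.asarray(self.power, float)
        if f.shape != p.shape:
            raise ConfigurationError("freqs and power must have equal length")
        if f.size > 1 and not np.all(np.diff(f) > 0):
            raise ConfigurationError("freqs must be strictly increasing")
        if np.any(p < 0):
            raise ConfigurationError("power must be nonnegative")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "power", p)


@dataclass
class FeatureRow:
    """One subject's named feature vector."""

    subject_id: str
    group: str | None
    values: dict
    layout_id: str = "paper34"


@dataclass
class FeatureMatrix:
    """Subjects x features table with group labels."""

    rows: list
    feature_names: list = field(default_factory=list)

    def __post_init__(self):
        if self.rows and not self.feature_names:
            self.feature_names = list(self.rows[0].values.keys())
        for r in self.rows:
            if list(r.values.keys()) != self.feature_names:
                raise ConfigurationError(
                    f"row {r.subject_id!r} does not share the feature lexicon")

    @property
    def labels(self):
        return [r.group for r in self.rows]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([r.values for r in self.rows],
                          columns=self.feature_names)
        df.insert(0, "subject_id", [r.subject_id for r in self.rows])
        df.insert(1, "group", [r.group for r in self.rows])
        return df

    def to_csv(self, path, params: FeatureParams | None = None) -> None:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        if params is not None:
            sidecar = path.with_suffix(".params.json")
            meta = {"layout_id": self.rows[0].layout_id if self.rows else None,
                    "params": asdict(params)}
            sidecar.write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       layout_id: str = "paper34") -> "FeatureMatrix":
        names = [c for c in df.columns if c not in ("subject_id", "group")]
        rows = [FeatureRow(subject_id=str(rec.get("subject_id", i)),
                           group=rec.get("group"),
                           values={k: rec[k] for k in names},
                           layout_id=layout_id)
                for i, rec in df.to_dict("index").items()]
        return cls(rows=rows, feature_names=names)


# ---------------------------------------------------------------------------
# windowing and spectra

def segment(x: np.ndarray, win: int, hop: int) -> np.ndarray:
    """Cut *x* into windows of length *win* advanced by *hop* samples.

    The trailing partial window is discarded; raises when even one full
    window does not fit.
    """
    x = np.asarray(x, float)
    if hop < 1:
        raise ConfigurationError("hop must be >= 1")
    if win > x.size:
        raise SignalTooShortError(
            f"signal of length {x.size} shorter than window {win}")
    n_win = (x.size - win) // hop + 1
    idx = np.arange(win)[None, :] + hop * np.arange(n_win)[:, None]
    return x[idx]


def welch_psd(x: np.ndarray, fs: float,
              params: FeatureParams = FeatureParams()) -> Spectrum:
    """Welch PSD with 512-sample tapered segments and 50% overlap."""
    x = np.asarray(x, float)
    nperseg = params.psd_nperseg
    if x.size < nperseg:
        warnings.warn("input shorter than psd_nperseg; using a single-segment "
                      "periodogram", stacklevel=2)
        nperseg = x.size
    freqs, power = sps.welch(x, fs=fs, nperseg=nperseg,
                             noverlap=nperseg // 2)
    return Spectrum(freqs=freqs, power=power)


def spectral_summary(spec: Spectrum) -> tuple[float, float]:
    """(peak frequency, peak power); ties resolve to the lower frequency."""
    if spec.power.sum() <= 0:
        raise DegenerateInputError("all-zero spectrum has no peak")
    i = int(np.argmax(spec.power))        # first max = lowest frequency
    return float(spec.freqs[i]), float(spec.power[i])


def _band_mask(spec: Spectrum, band) -> np.ndarray:
    lo, hi = band
    if lo >= hi:
        raise ConfigurationError(f"empty band [{lo}, {hi}] Hz")
    return (spec.freqs >= lo) & (spec.freqs <= hi)


def spectral_edge(spec: Spectrum, fraction: float = 0.5,
                  band=(1.0, 30.0)) -> float:
    """Smallest frequency below which *fraction* of in-band power lies."""
    mask = _band_mask(spec, band)
    p = spec.power[mask]
    f = spec.freqs[mask]
    total = p.sum()
    if p.size == 0 or total <= 0:
        raise DegenerateInputError("no spectral mass inside the band")
    cum = np.cumsum(p)
    i = int(np.searchsorted(cum, fraction * total))
    return float(f[min(i, f.size - 1)])


def spectral_entropy(spec: Spectrum, band=(1.0, 30.0),
                     eps: float = 1e-12) -> float:
    """Shannon entropy (natural log) of the normalized in-band PSD."""
    mask = _band_mask(spec, band)
    p = spec.power[mask]
    total = p.sum()
    if p.size == 0 or total <= 0:
        raise DegenerateInputError("no spectral mass inside the band")
    F = p / total
    return float(-np.sum(F * np.log(F + eps)))


def _dyadic_entropy_from_spectrum(spec: Spectrum, eps: float = 1e-12) -> float:
    energies = np.array([spec.power[_band_mask(spec, b)].sum()
                         for b in DYADIC_BANDS])
    total = energies.sum()
    if total <= 0:
        raise DegenerateInputError("no spectral mass in the dyadic bands")
    F = energies / total
    return float(-np.sum(F * np.log(F + eps)))


def dyadic_spectral_entropy(x: np.ndarray, fs: float,
                            params: FeatureParams = FeatureParams()) -> float:
    """Shannon entropy of band energies over the five octave bands in 1-30 Hz."""
    return _dyadic_entropy_from_spectrum(welch_psd(x, fs, params),
                                         eps=params.eps_log)


# ---------------------------------------------------------------------------
# entropies

def approximate_entropy(x: np.ndarray,
                        params: FeatureParams = FeatureParams(),
                        m: int | None = None,
                        r: float | None = None) -> float:
    """Approximate entropy ApEn(m, r) in the classic formulation.

    Self-matches are included, pattern similarity is a Chebyshev ball of
    radius r = 0.25 x sample SD by default, and
    ApEn = Phi_m - Phi_{m+1} with Phi_m the mean log match fraction.
    """
    x = np.asarray(x, float)
    m = params.apen_m if m is None else m
    if x.size <= m + 1:
        raise SignalTooShortError(f"ApEn needs more than {m + 1} samples")
    if r is None:
        sd = x.std(ddof=1)
        if sd == 0:
            logger.warning("constant input to ApEn; returning 0")
            return 0.0
        r = params.apen_r_coeff * sd
    D = np.abs(x[:, None] - x[None, :]) <= r

    # B after step mm holds Chebyshev-ball matches of mm-length templates;
    # the accumulation is shared between Phi_m and Phi_{m+1}
    B = D
    phi_m = 0.0
    for mm in range(2, m + 2):
        B = B[:-1, :-1] & D[mm - 1:, mm - 1:]
        if mm == m:
            phi_m = float(np.mean(np.log(B.mean(axis=1))))
    if m == 1:
        phi_m = float(np.mean(np.log(D.mean(axis=1))))
    phi_m1 = float(np.mean(np.log(B.mean(axis=1))))
    return phi_m - phi_m1


def log_energy_entropy(x: np.ndarray,
                       params: FeatureParams = FeatureParams()) -> float:
    """Sum of ln(x_i^2), with a small epsilon guarding exact zeros."""
    x = np.asarray(x, float)
    if x.size == 0:
        raise ConfigurationError("empty input")
    return float(np.sum(np.log(x * x + params.eps_log)))


def permutation_entropy(x: np.ndarray,
                        params: FeatureParams = FeatureParams(),
                        m: int | None = None,
                        tau: int | None = None) -> float:
    """Normalized permutation entropy in [0, 1].

    Ordinal patterns of order m at lag tau (ties broken by index order via a
    stable sort); Shannon entropy of the pattern frequencies in bits,
    normalized by log2(m!) so equiprobable patterns give exactly 1.
    """
    x = np.asarray(x, float)
    m = params.perm_m if m is None else m
    tau = params.perm_tau if tau is None else tau
    n_motifs = x.size - (m - 1) * tau
    if n_motifs < 2:
        raise SignalTooShortError(
            f"permutation entropy with m={m}, tau={tau} needs at least "
            f"{(m - 1) * tau + 2} samples")
    idx = np.arange(m)[None, :] * tau + np.arange(n_motifs)[:, None]
    patterns = np.argsort(x[idx], axis=1, kind="stable")
    # encode each pattern as an integer in factorial base-free form
    codes = np.zeros(n_motifs, dtype=np.int64)
    for j in range(m):
        codes = codes * m + patterns[:, j]
    _, counts = np.unique(codes, return_counts=True)
    p = counts / n_motifs
    H = -np.sum(p * np.log2(p))
    return float(H / math.log2(math.factorial(m)))


def _check_probabilities(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, float)
    if np.any(p < 0):
        raise ConfigurationError("probabilities must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"probabilities sum to {p.sum()}, not 1")
    return p


def renyi_entropy(p: np.ndarray, alpha: float = 2.0) -> float:
    """Renyi entropy (1/(1-alpha)) log2 sum p^alpha, in bits."""
    if alpha == 1:
        raise ConfigurationError(
            "alpha=1 is the Shannon limit; use a Shannon entropy instead")
    p = _check_probabilities(p)
    p = p[p > 0]
    return float(np.log2(np.sum(p ** alpha)) / (1.0 - alpha))


def tsallis_entropy(p: np.ndarray, q: float = 2.0) -> float:
    """Tsallis entropy sum (p - p^q)/(q - 1)."""
    if q == 1:
        raise ConfigurationError("q=1 is the Shannon limit")
    p = _check_probabilities(p)
    return float(np.sum(p - p ** q) / (q - 1.0))


def amplitude_probabilities(x: np.ndarray, bins: int = 32) -> np.ndarray:
    """Amplitude-histogram probability estimate used by Renyi/Tsallis."""
    x = np.asarray(x, float)
    counts, _ = np.histogram(x, bins=bins)
    total = counts.sum()
    if total == 0:
        raise ConfigurationError("empty input")
    return counts / total


# ---------------------------------------------------------------------------
# Hjorth, complexity, moments

def hjorth(x: np.ndarray) -> tuple[float, float, float]:
    """Hjorth (activity, mobility, complexity) via first differences.

    A pure sinusoid gives complexity exactly 1 (the reference signal for the
    parameter); degenerate variances yield zeros by convention.
    """
    x = np.asarray(x, float)
    if x.size < 3:
        raise SignalTooShortError("Hjorth parameters need >= 3 samples")
    var0 = np.var(x)
    if var0 == 0:
        return 0.0, 0.0, 0.0
    d1 = np.diff(x)
    var1 = np.var(d1)
    mobility = math.sqrt(var1 / var0)
    if var1 == 0:
        return float(var0), mobility, 0.0
    d2 = np.diff(d1)
    var2 = np.var(d2)
    mobility_d = math.sqrt(var2 / var1)
    return float(var0), mobility, mobility_d / mobility


def _binarize_median(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    return (x > np.median(x)).astype(np.uint8)


def lz76_phrase_count(s: np.ndarray) -> int:
    """LZ76 exhaustive-history phrase count c(n) of a binary sequence.

    A new phrase starts whenever the current substring cannot be copied from
    the prior history; a final incomplete phrase counts as one.
    """
    s = np.asarray(s).astype(np.uint8)
    n = s.size
    if n == 0:
        raise SignalTooShortError("empty sequence")
    b = s.tobytes()
    c = 1
    i = 1          # start of the current phrase
    while i < n:
        k = 1
        # longest prefix of the remainder reproducible from history b[:i+k-1]
        while i + k <= n and b.find(b[i:i + k], 0, i + k - 1) != -1:
            k += 1
        c += 1
        i += k
    return c


def lempel_ziv(x: np.ndarray) -> float:
    """Raw LZ76 phrase count of the median-binarized signal."""
    x = np.asarray(x, float)
    if x.size < 2:
        raise SignalTooShortError("Lempel-Ziv needs >= 2 samples")
    return float(lz76_phrase_count(_binarize_median(x)))


def kolmogorov(x: np.ndarray) -> float:
    """Kaspar-Schuster-normalized LZ76 complexity, c(n) log2(n) / n.

    An algorithmic-complexity proxy: near 1 for random binary strings and
    tending to 0 for highly regular ones.
    """
    x = np.asarray(x, float)
    if x.size < 2:
        raise SignalTooShortError("Kolmogorov proxy needs >= 2 samples")
    n = x.size
    return lz76_phrase_count(_binarize_median(x)) * math.log2(n) / n


def moments(x: np.ndarray) -> tuple[float, float]:
    """(kurtosis, skewness): standardized fourth and third central moments.

    Kurtosis is the Pearson (non-excess) form; both are 0 by convention for
    zero-variance input.
    """
    x = np.asarray(x, float)
    if x.size < 4:
        raise SignalTooShortError("moments need >= 4 samples")
    d = x - x.mean()
    m2 = np.mean(d * d)
    if m2 == 0:
        return 0.0, 0.0
    m3 = np.mean(d ** 3)
    m4 = np.mean(d ** 4)
    return float(m4 / (m2 * m2)), float(m3 / m2 ** 1.5)


# ---------------------------------------------------------------------------
# per-recording extraction

LAYOUTS = ("paper34", "extended")


def _window_features(w: np.ndarray, fs: float, params: FeatureParams) -> dict:
    spec = welch_psd(w, fs, params)
    band = (params.band_lo_hz, params.band_hi_hz)
    act, mob, comp = hjorth(w)
    kur, skw = moments(w)
    p_hist = amplitude_probabilities(w, params.hist_bins)
    c = lz76_phrase_count(_binarize_median(w))
    return {
        "spedge": spectral_edge(spec, params.sef_fraction, band),
        "ApEn": approximate_entropy(w, params),
        "logenergy": log_energy_entropy(w, params),
        "PermEn": permutation_entropy(w, params),
        "tsallis": tsallis_entropy(p_hist, params.tsallis_q),
        "renyi": renyi_entropy(p_hist, params.renyi_alpha),
        "spentropy": spectral_entropy(spec, band, params.eps_log),
        "spentropDyd": _dyadic_entropy_from_spectrum(spec, params.eps_log),
        "activity": act,
        "mobility": mob,
        "complexity": comp,
        "kurt": kur,
        "skew": skw,
        "lempel": float(c),
        "kolmogorov": c * math.log2(w.size) / w.size,
    }


def feature_names(layout: str = "paper34",
                  channels=CHANNELS_1020) -> list[str]:
    """The ordered feature-name lexicon of a layout."""
    if layout not in LAYOUTS:
        raise ConfigurationError(f"unknown layout {layout!r}")
    names = []
    for ch in channels:
        names.append(f"{ch}__freqmax")
        names.append(f"{ch}__powmax")
        for feat in WINDOWED_FEATURES:
            names.append(f"{ch}__{feat}__mean")
            names.append(f"{ch}__{feat}__var")
        names.append(f"{ch}__kurt__mean60")
        names.append(f"{ch}__skew__mean60")
        if layout == "extended":
            names.append(f"{ch}__activity__whole")
            names.append(f"{ch}__mobility__whole")
            names.append(f"{ch}__complexity__whole")
    return names


def extract_features(rec: Recording,
                     params: FeatureParams = FeatureParams(),
                     layout: str = "paper34") -> FeatureRow:
    """Compute the full per-channel battery for one preprocessed recording."""
    if layout not in LAYOUTS:
        raise ConfigurationError(f"unknown layout {layout!r}")
    if not rec.preprocessed:
        raise ConfigurationError(
            f"recording {rec.subject_id!r} must be preprocessed first")
    need = max(params.window_60s_samples, params.window_2s_samples)
    if rec.n_samples < need:
        raise SignalTooShortError(
            f"recording {rec.subject_id!r} has {rec.n_samples} samples; "
            f"the layout needs >= {need}")
    values: dict[str, float] = {}
    for ch_i, ch in enumerate(rec.channel_labels):
        x = rec.samples[ch_i]
        fmax, pmax = spectral_summary(welch_psd(x, rec.fs, params))
        values[f"{ch}__freqmax"] = fmax
        values[f"{ch}__powmax"] = pmax
        wins = segment(x, params.window_2s_samples, params.window_2s_samples)
        table = np.array([[feat for feat in _window_features(w, rec.fs,
                                                             params).values()]
                          for w in wins])
        means = table.mean(axis=0)
        variances = table.var(axis=0)
        for j, feat in enumerate(WINDOWED_FEATURES):
            values[f"{ch}__{feat}__mean"] = float(means[j])
            values[f"{ch}__{feat}__var"] = float(variances[j])
        wins60 = segment(x, params.window_60s_samples,
                         params.window_60s_samples)
        kurts, skews = zip(*(moments(w) for w in wins60))
        values[f"{ch}__kurt__mean60"] = float(np.mean(kurts))
        values[f"{ch}__skew__mean60"] = float(np.mean(skews))
        if layout == "extended":
            act, mob, comp = hjorth(x)
            values[f"{ch}__activity__whole"] = act
            values[f"{ch}__mobility__whole"] = mob
            values[f"{ch}__complexity__whole"] = comp
    bad = [k for k, v in values.items() if not np.isfinite(v)]
    if bad:
        raise DegenerateInputError(
            f"non-finite feature values for {rec.subject_id!r}: {bad[:5]}")
    return FeatureRow(subject_id=rec.subject_id, group=rec.group,
                      values=values, layout_id=layout)


def build_matrix(cohort, params: FeatureParams = FeatureParams(),
                 layout: str = "paper34") -> FeatureMatrix:
    """Extract features for every recording and stack them into a matrix."""
    cohort = list(cohort)
    if not cohort:
        raise ConfigurationError("empty cohort")
    ref = set(cohort[0].channel_labels)
    for rec in cohort[1:]:
        if set(rec.channel_labels) != ref:
            diff = sorted(ref ^ set(rec.channel_labels))
            raise ChannelError(
                f"heterogeneous channel sets; symmetric difference: {diff}")
    rows = [extract_features(rec, params, layout) for rec in cohort]
    return FeatureMatrix(rows=rows)
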