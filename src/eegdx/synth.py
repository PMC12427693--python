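"""Synthetic resting-EEG cohorts with controllable group structure.

Each subject's channel signal is a sum of three sources:

* narrow-band oscillators (center frequency, relative amplitude, target
  channels) with per-subject random phases — the rhythmic EEG component;
* Gaussian background noise shaped in the frequency domain to a 1/f^a
  magnitude profile, scaled by an ``irregularity`` knob — the aperiodic
  component whose slope and level differ between diagnostic groups;
* a 50 Hz mains sinusoid so the notch stage of the preprocessing chain is
  exercised.

Group profiles are calibration knobs that make every downstream stage
testable, not estimates of any clinical cohort. The default five-group
cohort mirrors the group sizes of the study population (43 controls, 28
depression, 40 Alzheimer, 42 schizophrenia, 28 MCI) with stylized spectral
differences: slowed and attenuated posterior alpha plus a steeper 1/f slope
and reduced irregularity in the dementia groups, frontal alpha excess in
depression, flattened slope and raised irregularity in schizophrenia.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .montage import CHANNELS_1020
from .preprocess import Recording, save_recording

POSTERIOR = ("P3", "P4", "O1", "O2", "T5", "T6", "Pz")
FRONTAL = ("Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz")


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters of one diagnostic group."""

    name: str
    n_subjects: int
    #: (center frequency Hz, relative amplitude, target channel labels or None=all)
    osc_components: tuple = ()
    one_over_f_exponent: float = 1.0
    irregularity: float = 1.0
    mains_amplitude: float = 0.0

    def validate(self, fs: float) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError(
                f"profile {self.name!r}: n_subjects must be >= 1")
        for freq, amp, targets in self.osc_components:
            if not 0 < freq < fs / 2:
                raise ConfigurationError(
                    f"profile {self.name!r}: oscillator frequency {freq} Hz "
                    f"outside (0, {fs / 2}) Hz")
            if amp < 0:
                raise ConfigurationError(
                    f"profile {self.name!r}: negative oscillator amplitude")
            if targets is not None:
                bad = set(targets) - set(CHANNELS_1020)
                if bad:
                    raise ConfigurationError(
                        f"profile {self.name!r}: unknown target channels {bad}")
        if self.irregularity < 0:
            raise ConfigurationError(
                f"profile {self.name!r}: irregularity must be >= 0")
        if self.mains_amplitude < 0:
            raise ConfigurationError(
                f"profile {self.name!r}: mains_amplitude must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """A whole synthetic cohort: group profiles plus recording geometry."""

    profiles: tuple
    duration_s: float = 120.0
    fs: float = 500.0
    channel_labels: tuple = CHANNELS_1020
    seed: int = 0

    def validate(self) -> None:
        if len(self.channel_labels) != 19 or \
                len(set(self.channel_labels)) != 19:
            raise ConfigurationError(
                "channel_labels must be the 19 unique 10-20 labels")
        if set(self.channel_labels) != set(CHANNELS_1020):
            raise ConfigurationError(
                "channel_labels must match the 10-20 montage")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9 or n < 2000:
            raise ConfigurationError(
                "duration_s x fs must be an integer >= 2000 samples "
                "(two 2-s windows)")
        for p in self.profiles:
            p.validate(self.fs)

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


def _one_over_f_noise(rng: np.random.Generator, n: int, fs: float,
                      exponent: float) -> np.ndarray:
    """Unit-SD Gaussian noise with a 1/f^exponent power spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)   # amplitude for 1/f^a power
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_recording(profile: GroupProfile, spec: CohortSpec,
                       subject_seed: int,
                       subject_id: str | None = None) -> Recording:
    """Synthesize one subject's 19-channel recording; bit-deterministic."""
    spec.validate()
    profile.validate(spec.fs)
    rng = np.random.default_rng(np.random.SeedSequence(subject_seed))
    n = spec.n_samples
    t = np.arange(n) / spec.fs
    data = np.zeros((len(spec.channel_labels), n))

    for freq, amp, targets in profile.osc_components:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        wave = amp * np.sin(2.0 * np.pi * freq * t + phase)
        labels = spec.channel_labels if targets is None else targets
        for ch in labels:
            data[spec.channel_labels.index(ch)] += wave

    if profile.irregularity > 0:
        for i in range(len(spec.channel_labels)):
            data[i] += profile.irregularity * _one_over_f_noise(
                rng, n, spec.fs, profile.one_over_f_exponent)

    if profile.mains_amplitude > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        data += profile.mains_amplitude * np.sin(
            2.0 * np.pi * 50.0 * t + phase)

    return Recording(subject_id=subject_id or f"{profile.name}-{subject_seed}",
                     samples=data, fs=spec.fs,
                     channel_labels=tuple(spec.channel_labels),
                     group=profile.name)


def subject_seeds(spec: CohortSpec) -> list:
    """Reproducible per-subject integer seeds derived from ``spec.seed``."""
    total = sum(p.n_subjects for p in spec.profiles)
    root = np.random.SeedSequence(spec.seed)
    return [int(s.generate_state(1)[0] & 0x7FFFFFFF)
            for s in root.spawn(total)]


def generate_cohort(spec: CohortSpec) -> list:
    """Generate every subject of the cohort, group labels attached."""
    spec.validate()
    seeds = subject_seeds(spec)
    recordings = []
    k = 0
    for profile in spec.profiles:
        for j in range(profile.n_subjects):
            recordings.append(generate_recording(
                profile, spec, seeds[k],
                subject_id=f"{profile.name}-{j:03d}"))
            k += 1
    return recordings


def write_cohort(recordings, outdir, format: str = "csv") -> Path:
    """Write each recording plus a cohort manifest CSV; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "cohort_manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subject_id", "group", "path", "fs"])
        for rec in recordings:
            fname = f"{rec.subject_id}.{format}"
            save_recording(rec, outdir / fname, format=format)
            writer.writerow([rec.subject_id, rec.group, fname, rec.fs])
    return manifest


# ---------------------------------------------------------------------------
# default study-condition profiles

def default_profiles() -> tuple:
    """Stylized five-group profiles mirroring the study's group sizes."""
    return (
        GroupProfile("control", 43,
                     osc_components=((10.0, 1.0, POSTERIOR),
                                     (20.0, 0.3, FRONTAL)),
                     one_over_f_exponent=1.0, irregularity=1.0,
                     mains_amplitude=0.2),
        GroupProfile("depression", 28,
                     osc_components=((10.0, 0.8, POSTERIOR),
                                     (10.0, 0.6, FRONTAL)),
                     one_over_f_exponent=1.1, irregularity=1.1,
                     mains_amplitude=0.2),
        GroupProfile("alzheimer", 40,
                     osc_components=((7.5, 1.0, POSTERIOR),
                                     (5.0, 0.7, None)),
                     one_over_f_exponent=1.4, irregularity=0.6,
                     mains_amplitude=0.2),
        GroupProfile("schizophrenia", 42,
                     osc_components=((10.0, 0.5, POSTERIOR),),
                     one_over_f_exponent=0.8, irregularity=1.4,
                     mains_amplitude=0.2),
        GroupProfile("mci", 28,
                     osc_components=((8.5, 1.0, POSTERIOR),
                                     (5.0, 0.35, None)),
                     one_over_f_exponent=1.2, irregularity=0.8,
                     mains_amplitude=0.2),
    )


def default_cohort_spec(seed: int = 0, duration_s: float = 120.0,
                        groups=None, n_subjects=None) -> CohortSpec:
    """The default five-group cohort, optionally restricted or resized.

    ``groups`` selects a subset of group names; ``n_subjects`` overrides the
    per-group size (one integer for all groups).
    """
    profiles = default_profiles()
    if groups is not None:
        known = {p.name for p in profiles}
        bad = set(groups) - known
        if bad:
            raise ConfigurationError(f"unknown group names: {sorted(bad)}")
        profiles = tuple(p for p in profiles if p.name in groups)
    if n_subjects is not None:
        profiles = tuple(
            GroupProfile(p.name, int(n_subjects), p.osc_components,
                         p.one_over_f_exponent, p.irregularity,
                         p.mains_amplitude) for p in profiles)
    return CohortSpec(profiles=profiles, duration_s=duration_s, seed=seed)
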