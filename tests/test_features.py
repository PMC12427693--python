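"""Feature battery: oracle equivalence, closed-form examples, invariances."""

import math

import numpy as np
import pytest

import eegdx
from eegdx.errors import (ConfigurationError, DegenerateInputError,
                          SignalTooShortError)
from eegdx.features import (FeatureParams, Spectrum, amplitude_probabilities,
                            approximate_entropy, build_matrix,
                            dyadic_spectral_entropy, extract_features,
                            hjorth, kolmogorov, lempel_ziv, log_energy_entropy,
                            lz76_phrase_count, moments, permutation_entropy,
                            renyi_entropy, segment, spectral_edge,
                            spectral_entropy, spectral_summary,
                            tsallis_entropy, welch_psd)

from _oracles import apen_bruteforce, lz76_bruteforce, permen_bruteforce


def _sine(freq=10.0, fs=500.0, seconds=2.0, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


# ---------------------------------------------------------------------------
# windowing and spectra

class TestSegment:
    @pytest.mark.parametrize("n, win, hop, expected", [
        (3000, 1000, 1000, 3),
        (3500, 1000, 1000, 3),     # trailing 500 samples dropped
        (1000, 1000, 1000, 1),
        (2500, 1000, 500, 4),
    ])
    def test_window_counts(self, n, win, hop, expected):
        wins = segment(np.arange(n, dtype=float), win, hop)
        assert wins.shape == (expected, win)

    def test_too_short_names_required_length(self):
        with pytest.raises(SignalTooShortError, match="1000"):
            segment(np.zeros(999), 1000, 1000)


class TestWelchPsd:
    def test_sine_peak_within_one_bin(self):
        spec = welch_psd(_sine(seconds=10.0), 500.0)
        fmax, _ = spectral_summary(spec)
        assert abs(fmax - 10.0) <= 500.0 / 512

    def test_white_noise_no_dominant_bin(self, rng):
        x = rng.standard_normal(50_000)
        spec = welch_psd(x, 500.0)
        assert spec.power.max() <= 5 * np.median(spec.power)

    def test_zero_input_all_zero_power(self):
        spec = welch_psd(np.zeros(2000), 500.0)
        assert np.all(spec.power == 0)

    def test_short_input_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="periodogram"):
            welch_psd(np.ones(100), 500.0)


class TestSpectralSummary:
    def test_tie_breaks_toward_lower_frequency(self):
        spec = Spectrum(freqs=np.array([8.0, 10.0, 12.0]),
                        power=np.array([3.0, 1.0, 3.0]))
        fmax, pmax = spectral_summary(spec)
        assert fmax == 8.0 and pmax == 3.0

    def test_power_scales_with_amplitude_squared(self):
        _, p1 = spectral_summary(welch_psd(_sine(amp=1.0, seconds=10.0), 500.0))
        _, p2 = spectral_summary(welch_psd(_sine(amp=2.0, seconds=10.0), 500.0))
        assert p2 == pytest.approx(4 * p1, rel=1e-6)

    def test_zero_spectrum_rejected(self):
        with pytest.raises(DegenerateInputError):
            spectral_summary(Spectrum(freqs=np.array([1.0, 2.0]),
                                      power=np.zeros(2)))


class TestSpectralEdge:
    def test_single_line_returns_line_frequency(self):
        spec = welch_psd(_sine(seconds=10.0), 500.0)
        assert spectral_edge(spec, 0.5, (1, 30)) == pytest.approx(10.0, abs=1.0)

    def test_flat_spectrum_sef50_at_band_midpoint(self):
        freqs = np.arange(0.0, 40.0, 0.1)
        spec = Spectrum(freqs=freqs, power=np.ones_like(freqs))
        assert spectral_edge(spec, 0.5, (1, 30)) == pytest.approx(15.5, abs=0.2)

    def test_fraction_one_returns_highest_inband_bin(self):
        freqs = np.arange(0.0, 40.0, 0.5)
        spec = Spectrum(freqs=freqs, power=np.ones_like(freqs))
        assert spectral_edge(spec, 1.0, (1, 30)) == 30.0

    def test_empty_band_rejected(self):
        spec = welch_psd(_sine(seconds=10.0), 500.0)
        with pytest.raises(ConfigurationError):
            spectral_edge(spec, 0.5, (30, 30))


class TestSpectralEntropies:
    def test_one_bin_spectrum_gives_zero(self):
        spec = Spectrum(freqs=np.array([5.0, 10.0]),
                        power=np.array([0.0, 2.0]))
        assert spectral_entropy(spec, (1, 30)) == pytest.approx(0.0, abs=1e-6)

    def test_uniform_spectrum_gives_log_n(self):
        freqs = np.linspace(1.0, 30.0, 64)
        spec = Spectrum(freqs=freqs, power=np.ones(64))
        assert spectral_entropy(spec, (1, 30)) == pytest.approx(
            math.log(64), abs=1e-4)

    def test_sine_below_white_noise(self, rng):
        n = 5000
        s = spectral_entropy(welch_psd(_sine(seconds=10.0), 500.0))
        w = spectral_entropy(welch_psd(rng.standard_normal(n), 500.0))
        assert s < w

    def test_dyadic_single_band_near_zero(self):
        assert dyadic_spectral_entropy(_sine(10.0, seconds=10.0), 500.0) \
            == pytest.approx(0.0, abs=0.05)

    def test_dyadic_five_equal_bands_near_log5(self):
        x = sum(_sine(f, seconds=20.0) for f in (1.5, 3.0, 6.0, 12.0, 20.0))
        assert dyadic_spectral_entropy(x, 500.0) == pytest.approx(
            math.log(5), abs=0.2)

    def test_dyadic_bounded_by_log5(self, rng):
        x = rng.standard_normal(4000)
        assert dyadic_spectral_entropy(x, 500.0) <= math.log(5) + 1e-9


# ---------------------------------------------------------------------------
# entropies against oracles and closed forms

class TestApproximateEntropy:
    def test_constant_vector_is_zero(self):
        assert approximate_entropy(np.ones(50)) == 0.0

    def test_noise_above_sine(self, rng):
        noise = rng.standard_normal(1000)
        sine = _sine(10.0, 500.0, 2.0)
        assert approximate_entropy(noise) > approximate_entropy(sine)

    @pytest.mark.parametrize("m", [1, 2, 3])
    def test_matches_bruteforce_oracle(self, m, rng):
        x = rng.standard_normal(30)
        r = 0.25 * x.std(ddof=1)
        ours = approximate_entropy(x, m=m, r=r)
        ref = apen_bruteforce(x, m, r)
        assert ours == pytest.approx(ref, abs=1e-12)


class TestLogEnergyEntropy:
    def test_unit_values_give_zero(self):
        assert log_energy_entropy(np.ones(3)) == pytest.approx(0.0, abs=1e-9)

    def test_e_values(self):
        assert log_energy_entropy(np.array([math.e, math.e])) == \
            pytest.approx(4.0, abs=1e-9)

    def test_scaling_adds_n_log_c_squared(self, rng):
        x = rng.standard_normal(100) + 5.0
        c = 3.0
        assert log_energy_entropy(c * x) - log_energy_entropy(x) == \
            pytest.approx(100 * math.log(c * c), abs=1e-6)


class TestPermutationEntropy:
    def test_monotone_series_is_zero(self):
        assert permutation_entropy(np.arange(100.0), m=3, tau=1) == 0.0

    def test_long_uniform_noise_near_one(self, rng):
        x = rng.uniform(size=20_000)
        assert permutation_entropy(x, m=3, tau=1) == pytest.approx(1.0,
                                                                   abs=0.01)

    @pytest.mark.parametrize("tau", [1, 2])
    def test_matches_exhaustive_oracle(self, tau, rng):
        x = rng.standard_normal(12)
        ours = permutation_entropy(x, m=3, tau=tau)
        ref = permen_bruteforce(x, 3, tau)
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_ties_broken_by_index_order(self):
        # plateau then rise: the tie (x0 == x1) counts as "ascending"
        x = np.array([1.0, 1.0, 2.0, 3.0])
        assert permutation_entropy(x, m=2, tau=1) == 0.0

    def test_too_short_input_names_minimum(self):
        with pytest.raises(SignalTooShortError, match="7"):
            permutation_entropy(np.zeros(6), m=6, tau=1)


class TestRenyiTsallis:
    def test_degenerate_distribution(self):
        assert renyi_entropy([1.0], 2.0) == 0.0
        assert tsallis_entropy([1.0], 2.0) == 0.0

    def test_two_point_values(self):
        assert renyi_entropy([0.5, 0.5], 2.0) == pytest.approx(1.0)
        assert tsallis_entropy([0.5, 0.5], 2.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("alpha", [0.5, 2.0, 3.0])
    def test_renyi_uniform_is_log2_n(self, alpha):
        p = np.full(16, 1 / 16)
        assert renyi_entropy(p, alpha) == pytest.approx(4.0, abs=1e-9)

    def test_tsallis_uniform_closed_form(self):
        for n in (4, 32):
            p = np.full(n, 1 / n)
            assert tsallis_entropy(p, 2.0) == pytest.approx(1 - 1 / n)

    def test_alpha_one_rejected(self):
        with pytest.raises(ConfigurationError):
            renyi_entropy([0.5, 0.5], 1.0)
        with pytest.raises(ConfigurationError):
            tsallis_entropy([0.5, 0.5], 1.0)

    def test_histogram_probabilities_sum_to_one(self, rng):
        p = amplitude_probabilities(rng.standard_normal(1000), 32)
        assert p.sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Hjorth, complexity, moments

class TestHjorth:
    def test_pure_sine_complexity_is_one(self):
        _, _, comp = hjorth(_sine(10.0, 500.0, 10.0))
        assert comp == pytest.approx(1.0, abs=0.02)

    def test_constant_vector_convention(self):
        assert hjorth(np.full(100, 2.0)) == (0.0, 0.0, 0.0)

    def test_scaling_identity(self, rng):
        x = rng.standard_normal(500)
        a1, m1, c1 = hjorth(x)
        a2, m2, c2 = hjorth(4.0 * x)
        assert a2 == pytest.approx(16.0 * a1, rel=1e-9)
        assert m2 == pytest.approx(m1, rel=1e-9)
        assert c2 == pytest.approx(c1, rel=1e-9)


class TestLempelZiv:
    def test_classic_hand_parsed_sequence(self):
        # 0001101001000101 parses as 0 | 001 | 10 | 100 | 1000 | 101
        bits = np.array([0, 0, 0, 1, 1, 0, 1, 0, 0, 1, 0, 0, 0, 1, 0, 1])
        assert lz76_phrase_count(bits) == 6
        assert lz76_bruteforce(bits) == 6

    def test_all_zero_sequence_minimal(self):
        # first-symbol phrase plus one reproduction phrase
        assert lz76_phrase_count(np.zeros(64, dtype=int)) == 2

    @pytest.mark.parametrize("n", [17, 33, 50])
    def test_matches_string_parsing_oracle(self, n, rng):
        bits = rng.integers(0, 2, size=n)
        assert lz76_phrase_count(bits) == lz76_bruteforce(bits)

    def test_alternation_simpler_than_random(self, rng):
        n = 512
        alt = np.tile([0.0, 1.0], n // 2)
        rnd = rng.standard_normal(n)
        assert lempel_ziv(alt) <= lempel_ziv(rnd)

    def test_kolmogorov_limits(self, rng):
        assert kolmogorov(np.linspace(0, 1, 2000)) < 0.2
        assert 0.8 <= kolmogorov(rng.standard_normal(2000)) <= 1.3
        ramp = np.linspace(0, 1, 2000)
        assert kolmogorov(ramp) < kolmogorov(rng.standard_normal(2000))


class TestMoments:
    def test_symmetric_vector_zero_skew(self):
        _, skew = moments(np.array([-1.0, 1.0, -1.0, 1.0]))
        assert skew == 0.0

    def test_gaussian_kurtosis_near_three(self, rng):
        kurt, _ = moments(rng.standard_normal(200_000))
        assert kurt == pytest.approx(3.0, abs=0.1)

    def test_exponential_skewness_near_two(self, rng):
        _, skew = moments(rng.exponential(size=200_000))
        assert skew == pytest.approx(2.0, abs=0.1)

    def test_zero_variance_convention(self):
        assert moments(np.full(10, 7.0)) == (0.0, 0.0)


# ---------------------------------------------------------------------------
# cross-cutting invariances

class TestInvariances:
    def test_entropy_ordering_sine_colored_white(self, rng):
        from eegdx.synth import _one_over_f_noise
        n, fs = 1000, 500.0
        sine = _sine(10.0, fs, n / fs)
        colored = _one_over_f_noise(np.random.default_rng(5), n, fs, 2.0)
        white = np.random.default_rng(6).standard_normal(n)
        for fn in (approximate_entropy,
                   lambda x: permutation_entropy(x, m=3, tau=1),
                   lambda x: spectral_entropy(welch_psd(x, fs))):
            assert fn(sine) < fn(colored) < fn(white)

    @pytest.mark.parametrize("fn", [
        lambda x: permutation_entropy(x, m=3, tau=1),
        lempel_ziv,
        kolmogorov,
        lambda x: hjorth(x)[1],
        lambda x: hjorth(x)[2],
        lambda x: moments(x)[0],
        lambda x: moments(x)[1],
    ], ids=["PermEn", "lempel", "kolmogorov", "mobility", "complexity",
            "kurt", "skew"])
    def test_positive_affine_invariance(self, fn, rng):
        x = rng.standard_normal(800)
        assert fn(2.5 * x + 7.0) == pytest.approx(fn(x), rel=1e-9, abs=1e-9)

    def test_aggregate_stability_grows_with_duration(self):
        """For a stationary signal the windowed-mean feature estimate
        stabilizes as the window count grows: its variance across
        independent realizations shrinks monotonically with duration."""
        prof = eegdx.GroupProfile("g", 1, irregularity=1.0)
        spread = []
        for dur in (8.0, 40.0, 200.0):
            spec = eegdx.CohortSpec(profiles=(prof,), duration_s=dur, seed=3)
            means = []
            for s in range(12):
                rec = eegdx.generate_recording(prof, spec, 500 + s)
                wins = segment(rec.samples[0], 1000, 1000)
                means.append(np.mean(
                    [spectral_entropy(welch_psd(w, rec.fs)) for w in wins]))
            spread.append(np.var(means))
        assert spread[0] > spread[1] > spread[2]


# ---------------------------------------------------------------------------
# extraction and matrix assembly

class TestExtraction:
    def test_unpreprocessed_recording_rejected(self, two_group_spec):
        rec = eegdx.generate_cohort(two_group_spec)[0]
        with pytest.raises(ConfigurationError, match="preprocess"):
            extract_features(rec)

    def test_short_recording_rejected(self):
        prof = eegdx.GroupProfile("g", 1, irregularity=1.0)
        spec = eegdx.CohortSpec(profiles=(prof,), duration_s=30.0, seed=0)
        rec = eegdx.preprocess(eegdx.generate_recording(prof, spec, 1))
        with pytest.raises(SignalTooShortError):
            extract_features(rec)

    def test_row_naming_and_determinism(self, three_group_features):
        fm = three_group_features
        row = fm.rows[0]
        assert len(row.values) == 646
        assert "F7__ApEn__mean" in row.values
        assert "O2__powmax" in row.values
        assert "Pz__skew__mean60" in row.values
        # determinism: rebuild one subject from scratch
        spec = eegdx.default_cohort_spec(
            seed=7, duration_s=120.0,
            groups=("control", "alzheimer", "schizophrenia"), n_subjects=10)
        rec = eegdx.generate_cohort(spec)[0]
        again = extract_features(eegdx.preprocess(rec))
        assert again.values == row.values

    def test_matrix_shape_and_labels(self, three_group_features):
        fm = three_group_features
        df = fm.to_dataframe()
        assert df.shape == (30, 648)        # 646 + subject_id + group
        assert len(fm.feature_names) == 646
        assert sorted(set(fm.labels)) == ["alzheimer", "control",
                                          "schizophrenia"]

    def test_empty_cohort_rejected(self):
        with pytest.raises(ConfigurationError):
            build_matrix([])

    def test_heterogeneous_channels_rejected(self, two_group_spec):
        recs = [eegdx.preprocess(r)
                for r in eegdx.generate_cohort(two_group_spec)[:2]]
        bad = eegdx.Recording(subject_id="odd",
                              samples=recs[1].samples.copy(),
                              fs=recs[1].fs,
                              channel_labels=tuple(
                                  list(recs[1].channel_labels[:-1]) + ["XX"]),
                              preprocessed=True)
        with pytest.raises(Exception, match="symmetric difference|XX"):
            build_matrix([recs[0], bad])

    def test_csv_round_trip(self, three_group_features, tmp_path):
        fm = three_group_features
        path = tmp_path / "features.csv"
        fm.to_csv(path, params=FeatureParams())
        assert path.exists() and path.with_suffix(".params.json").exists()
        import pandas as pd
        back = eegdx.FeatureMatrix.from_dataframe(pd.read_csv(path))
        assert back.feature_names == fm.feature_names
        np.testing.assert_allclose(
            back.to_dataframe()[fm.feature_names].to_numpy(),
            fm.to_dataframe()[fm.feature_names].to_numpy(), rtol=1e-10)
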