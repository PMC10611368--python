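import numpy as np
import pytest

from drowsyfuse import preprocess, sigio, synthgen
from drowsyfuse.eeg_features import (
    EntropyConfig,
    approximate_entropy,
    band_power,
    extract_eeg_features,
    fuzzy_entropy,
    sample_entropy,
    spectral_entropy,
)
from drowsyfuse.sigio import EpochSet
from oracles import (
    approximate_entropy_oracle,
    fuzzy_entropy_oracle,
    sample_entropy_oracle,
)

BANDS = synthgen.EEG_BANDS


class TestBandPower:
    def test_pure_alpha_tone_concentrates(self):
        fs = 128.0
        t = np.arange(int(8 * fs)) / fs
        x = np.sin(2 * np.pi * 10.0 * t)
        alpha = band_power(x, fs, BANDS["alpha"])
        for other in ("delta", "theta", "beta"):
            assert alpha >= 50 * band_power(x, fs, BANDS[other])

    def test_white_noise_powers_proportional_to_widths(self):
        fs = 128.0
        ratios = {b: [] for b in BANDS}
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(int(30 * fs))
            for b, (lo, hi) in BANDS.items():
                ratios[b].append(band_power(x, fs, (lo, hi)) / (hi - lo))
        means = {b: np.mean(v) for b, v in ratios.items()}
        ref = np.mean(list(means.values()))
        for b, m in means.items():
            assert abs(m - ref) / ref < 0.25, b

    def test_zero_signal(self):
        assert band_power(np.zeros(256), 128.0, BANDS["alpha"]) == 0.0

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            band_power(np.zeros(256), 128.0, (10.0, 80.0))

    def test_nonnegative_and_sum_bounded(self, rng):
        fs = 128.0
        x = rng.standard_normal(int(10 * fs))
        total = band_power(x, fs, (0.0, 30.0))
        parts = sum(band_power(x, fs, e) for e in BANDS.values())
        assert parts <= total * 1.05


class TestEntropyOracleEquivalence:
    """Dual-route check: vectorized implementations vs brute-force loops."""

    @pytest.mark.parametrize("seed", range(5))
    def test_sample_entropy_matches_oracle(self, seed):
        x = np.random.default_rng(seed).standard_normal(120)
        cfg = EntropyConfig(m=2, r=0.2)
        assert sample_entropy(x, cfg) == pytest.approx(
            sample_entropy_oracle(x, 2, 0.2), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_approximate_entropy_matches_oracle(self, seed):
        x = np.random.default_rng(seed + 100).standard_normal(120)
        cfg = EntropyConfig(m=2, r=0.2)
        assert approximate_entropy(x, cfg) == pytest.approx(
            approximate_entropy_oracle(x, 2, 0.2), abs=1e-12
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_fuzzy_entropy_matches_oracle(self, seed):
        x = np.random.default_rng(seed + 200).standard_normal(120)
        cfg = EntropyConfig(m=2, r=0.2, n_fuzzy=2)
        assert fuzzy_entropy(x, cfg) == pytest.approx(
            fuzzy_entropy_oracle(x, 2, 0.2, 2), abs=1e-12
        )

    def test_m3_also_matches(self):
        x = np.random.default_rng(42).standard_normal(100)
        cfg = EntropyConfig(m=3, r=0.25)
        assert sample_entropy(x, cfg) == pytest.approx(
            sample_entropy_oracle(x, 3, 0.25), abs=1e-12
        )
        assert approximate_entropy(x, cfg) == pytest.approx(
            approximate_entropy_oracle(x, 3, 0.25), abs=1e-12
        )


class TestSampleEntropy:
    def test_periodic_sequence_is_zero(self):
        x = np.array([0.0, 1.0] * 50)
        assert sample_entropy(x, EntropyConfig(m=2, r=0.2)) == 0.0

    def test_noise_exceeds_sinusoid(self):
        cfg = EntropyConfig()
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noise = rng.uniform(-1, 1, 1000)
            t = np.arange(1000)
            sine = np.sin(2 * np.pi * t / 50 + rng.uniform(0, 2 * np.pi))
            wins += sample_entropy(noise, cfg) > sample_entropy(sine, cfg)
        assert wins == 20

    def test_constant_series_undefined(self):
        assert np.isnan(sample_entropy(np.ones(50)))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            sample_entropy(np.array([1.0, 2.0]), EntropyConfig(m=2))

    def test_amplitude_scale_invariance(self, rng):
        x = rng.standard_normal(300)
        a = sample_entropy(x)
        b = sample_entropy(10 * x)
        assert abs(a - b) < 1e-9


class TestApproximateEntropy:
    def test_constant_sequence_is_zero(self):
        assert approximate_entropy(np.full(50, 2.0)) == 0.0

    def test_noise_exceeds_sinusoid(self):
        cfg = EntropyConfig()
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noise = rng.uniform(-1, 1, 1000)
            t = np.arange(1000)
            sine = np.sin(2 * np.pi * t / 50 + rng.uniform(0, 2 * np.pi))
            wins += approximate_entropy(noise, cfg) > approximate_entropy(sine, cfg)
        assert wins == 20

    def test_amplitude_scale_invariance(self, rng):
        x = rng.standard_normal(300)
        assert abs(approximate_entropy(x) - approximate_entropy(10 * x)) < 1e-9


class TestFuzzyEntropy:
    def test_periodic_near_zero(self):
        x = np.array([0.0, 1.0] * 60)
        val = fuzzy_entropy(x, EntropyConfig())
        assert 0 <= abs(val) < 0.05
        # cross-check against the independent oracle
        assert val == pytest.approx(fuzzy_entropy_oracle(x), abs=1e-12)

    def test_monotone_in_noise_amplitude(self):
        cfg = EntropyConfig()
        t = np.arange(500)
        sine = np.sin(2 * np.pi * t / 40)
        increases = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            noise = rng.standard_normal(500)
            vals = [
                fuzzy_entropy(sine + sd * noise, cfg) for sd in (0.0, 0.25, 0.5, 1.0)
            ]
            increases += all(np.diff(vals) > 0)
        assert increases >= 6  # majority order over seeds

    def test_constant_undefined(self):
        assert np.isnan(fuzzy_entropy(np.zeros(50)))

    def test_amplitude_scale_invariance(self, rng):
        x = rng.standard_normal(300)
        assert abs(fuzzy_entropy(x) - fuzzy_entropy(10 * x)) < 1e-9


class TestSpectralEntropy:
    def test_pure_sinusoid_near_zero(self):
        fs = 128.0
        t = np.arange(int(8 * fs)) / fs
        assert spectral_entropy(np.sin(2 * np.pi * 10 * t), fs) <= 0.2

    def test_white_noise_near_one(self):
        fs = 128.0
        vals = [
            spectral_entropy(
                np.random.default_rng(s).standard_normal(4096), fs
            )
            for s in range(10)
        ]
        assert np.mean(vals) >= 0.9

    def test_two_tones_between_one_tone_and_noise(self):
        fs = 128.0
        t = np.arange(4096) / fs
        one = spectral_entropy(np.sin(2 * np.pi * 10 * t), fs)
        two = spectral_entropy(
            np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 20 * t), fs
        )
        noise = spectral_entropy(
            np.random.default_rng(0).standard_normal(4096), fs
        )
        assert one < two < noise

    def test_zero_signal_undefined(self):
        assert np.isnan(spectral_entropy(np.zeros(256), 128.0))


class TestExtractEEGFeatures:
    def test_table_shape(self, eeg_record):
        epochs = sigio.epoch_signal(eeg_record, 5.0)
        table = extract_eeg_features(epochs)
        assert table.values.shape == (epochs.n_epochs, 16)
        assert table.feature_names[0] == "P3_delta"
        assert table.feature_names[-1] == "P4_approx_en"

    def test_preset_groups_separable_in_theta(self):
        from scipy import stats

        powers = {}
        for state, seed in (("alert", 0), ("fatigued", 1)):
            spec = synthgen.eeg_preset(state, duration_s=125.0, seed=seed)
            rec = preprocess.preprocess_eeg(synthgen.gen_eeg(spec, 1))
            epochs = sigio.epoch_signal(rec, 5.0)
            table = extract_eeg_features(epochs)
            idx = table.feature_names.index("P3_theta")
            powers[state] = table.values[:, idx]
        t, p = stats.ttest_ind(powers["alert"], powers["fatigued"])
        assert p < 0.05

    def test_undefined_rows_dropped(self):
        # one constant epoch among valid ones -> dropped
        rng = np.random.default_rng(0)
        good = rng.standard_normal((1, 640))
        flat = np.zeros((1, 640))
        epochs = EpochSet(
            np.stack([good, flat, good]), 5.0, 128.0, ["P3"], "EEG",
            labels=np.array(["a", "b", "a"]),
        )
        table = extract_eeg_features(epochs)
        assert table.n_rows == 2
        assert list(table.labels) == ["a", "a"]

    def test_wrong_modality_rejected(self, ecg_record_with_truth):
        rec, _ = ecg_record_with_truth
        epochs = sigio.epoch_signal(rec, 5.0)
        with pytest.raises(ValueError):
            extract_eeg_features(epochs)

    def test_csv_round_trip(self, eeg_record, tmp_path):
        epochs = sigio.epoch_signal(eeg_record, 5.0)
        table = extract_eeg_features(epochs)
        path = tmp_path / "t.csv"
        table.to_csv(str(path))
        back = sigio.FeatureTable.from_csv(str(path))
        np.testing.assert_allclose(back.values, table.values, rtol=1e-12)

    def test_band_power_invariant_to_50hz_tone_after_preprocess(self):
        fs = 256.0
        spec = synthgen.EEGSynthSpec("alert", 10.0, fs, seed=2)
        rec = synthgen.gen_eeg(spec, 1)
        t = np.arange(rec.n_samples) / fs
        noisy = sigio.SignalRecord(
            rec.data + 2.0 * np.sin(2 * np.pi * 50.0 * t), fs, ["P3"], "EEG"
        )
        clean_p = preprocess.preprocess_eeg(rec)
        noisy_p = preprocess.preprocess_eeg(noisy)
        # filtering precedes epoching, so epochs never include the
        # record-edge transients; compare away from the edges likewise
        trim = slice(int(fs), -int(fs))
        for band in BANDS.values():
            a = band_power(clean_p.data[0, trim], fs, band)
            b = band_power(noisy_p.data[0, trim], fs, band)
            assert abs(a - b) / max(a, 1e-12) <= 0.05
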