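"""Morphological feature definitions, window scalars and aggregation,
checked against hand computations and brute-force oracles."""

import numpy as np
import pytest

from ppgbp import features
from ppgbp.errors import InvalidArgumentError
from ppgbp.signal import BeatFiducials, RPeaks, Signal

FS = 500.0


def synthetic_beat_signal():
    """Piecewise waveform with fully known fiducials: foot at 0, peak at
    100, notch at 250, diastolic bump at 300, next foot at 450."""
    x = np.zeros(500)
    x[:101] = np.linspace(0.0, 1.0, 101)                 # rise
    x[100:251] = np.linspace(1.0, 0.3, 151)              # decline to notch
    x[250:301] = np.linspace(0.3, 0.55, 51)              # diastolic rise
    x[300:451] = np.linspace(0.55, 0.0, 151)             # decay
    return Signal(x, fs=FS)


@pytest.fixture()
def one_beat():
    sig = synthetic_beat_signal()
    beat = BeatFiducials(valley_idx=0, peak_idx=100, next_valley_idx=450,
                         notch_idx=250)
    rpeaks = RPeaks(indices=np.array([0, 341]), fs=FS)  # T_PP = 0.682 s
    return sig, [beat], rpeaks


class TestBeatFeatures:
    def test_amplitudes_and_ratios(self, one_beat):
        sig, beats, rpeaks = one_beat
        bf = features.beat_features(sig, beats, rpeaks)[0]
        assert bf.systolic_amplitude == pytest.approx(1.0)
        assert bf.diastolic_amplitude == pytest.approx(0.55)
        assert bf.augmentation_index == pytest.approx(1.0 / 0.55)
        assert bf.inflection_point_area == pytest.approx(
            bf.systolic_area / bf.diastolic_area)

    def test_times_partition_the_pulse(self, one_beat):
        sig, beats, rpeaks = one_beat
        bf = features.beat_features(sig, beats, rpeaks)[0]
        assert bf.systolic_time == pytest.approx(100 / FS)
        assert bf.diastolic_time == pytest.approx(350 / FS)
        assert bf.systolic_time + bf.diastolic_time == pytest.approx(bf.pulse_interval)
        assert bf.stiffness_index == pytest.approx(1.0 / (350 / FS))
        assert bf.sa_dt_ratio == bf.stiffness_index

    def test_areas_match_trapezoidal_oracle(self, one_beat):
        sig, beats, rpeaks = one_beat
        bf = features.beat_features(sig, beats, rpeaks)[0]
        x = sig.samples

        def trapz_loop(lo, hi):
            total = 0.0
            for i in range(lo, hi):
                total += 0.5 * (x[i] + x[i + 1]) / FS
            return total

        assert bf.systolic_area == pytest.approx(trapz_loop(0, 250), rel=1e-9)
        assert bf.diastolic_area == pytest.approx(trapz_loop(250, 450), rel=1e-9)

    def test_heart_rate_from_enclosing_rr_interval(self, one_beat):
        sig, beats, rpeaks = one_beat
        bf = features.beat_features(sig, beats, rpeaks)[0]
        assert bf.heart_rate == pytest.approx(60.0 / (341 / FS))

    def test_fwhm_at_half_systolic_amplitude(self, one_beat):
        sig, beats, rpeaks = one_beat
        bf = features.beat_features(sig, beats, rpeaks)[0]
        # rising edge hits 0.5 at sample 50; falling edge at 100+150*(0.5/0.7)
        expected = (100 + 150 * (0.5 / 0.7) - 50) / FS
        assert bf.fwhm == pytest.approx(expected, abs=2 / FS)

    def test_no_notch_leaves_notch_features_nan(self, one_beat):
        sig, beats, rpeaks = one_beat
        no_notch = [BeatFiducials(valley_idx=0, peak_idx=100, next_valley_idx=450)]
        bf = features.beat_features(sig, no_notch, rpeaks)[0]
        assert np.isnan(bf.diastolic_amplitude) and np.isnan(bf.augmentation_index)
        assert np.isnan(bf.systolic_area) and np.isnan(bf.inflection_point_area)

    def test_time_rescaling_property(self, one_beat):
        sig, beats, rpeaks = one_beat
        a = features.beat_features(sig, beats, rpeaks)[0]
        half = Signal(sig.samples, fs=2 * FS)
        b = features.beat_features(half, beats, RPeaks(rpeaks.indices, 2 * FS))[0]
        for name in ("systolic_time", "diastolic_time", "pulse_interval", "fwhm"):
            assert getattr(b, name) == pytest.approx(0.5 * getattr(a, name))
        assert b.heart_rate == pytest.approx(2 * a.heart_rate)
        assert b.systolic_amplitude == a.systolic_amplitude

    def test_amplitude_rescaling_property(self, one_beat):
        sig, beats, rpeaks = one_beat
        a = features.beat_features(sig, beats, rpeaks)[0]
        scaled = sig.with_samples(3.0 * sig.samples)
        b = features.beat_features(scaled, beats, rpeaks)[0]
        assert b.systolic_amplitude == pytest.approx(3 * a.systolic_amplitude)
        assert b.systolic_area == pytest.approx(3 * a.systolic_area, rel=1e-12)
        assert b.augmentation_index == pytest.approx(a.augmentation_index)
        assert b.inflection_point_area == pytest.approx(a.inflection_point_area)


class TestZeroCrossingRate:
    def test_positive_signal_is_zero_under_both_semantics(self):
        y = np.abs(np.random.default_rng(0).normal(size=50)) + 0.1
        assert features.zero_crossing_rate(y, "sign_change") == 0.0
        assert features.zero_crossing_rate(y, "negative_fraction") == 0.0

    def test_alternating_signal_hand_count(self):
        y = np.array([1.0, -1.0, 1.0, -1.0])
        assert features.zero_crossing_rate(y, "sign_change") == 1.0
        assert features.zero_crossing_rate(y, "negative_fraction") == 0.5

    def test_sinusoid_analytic_crossing_count(self):
        n, k = 2000, 7
        t = np.linspace(0, 1, n, endpoint=False)
        y = np.sin(2 * np.pi * k * t + 0.37)
        rate = features.zero_crossing_rate(y, "sign_change")
        assert rate == pytest.approx(2 * k / (n - 1), abs=1.5 / n)

    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            y = rng.normal(size=rng.integers(5, 300))
            brute = sum(1 for a, b in zip(y[:-1], y[1:]) if a * b < 0) / (len(y) - 1)
            assert features.zero_crossing_rate(y) == pytest.approx(brute, rel=1e-12, abs=1e-15)

    def test_unknown_semantics_rejected(self):
        with pytest.raises(InvalidArgumentError):
            features.zero_crossing_rate(np.ones(5), "bogus")


class TestShannonEntropy:
    def test_impulse_and_zero_signals(self):
        assert features.shannon_entropy(np.array([1.0, 0, 0, 0])) == 0.0
        assert features.shannon_entropy(np.zeros(16)) == 0.0

    def test_hand_computed_value(self):
        y = np.array([0.5, 0.5])
        assert features.shannon_entropy(y) == pytest.approx(0.25 * np.log(16))

    def test_out_of_range_samples_warn(self):
        with pytest.warns(UserWarning):
            features.shannon_entropy(np.array([2.0, 0.1]))

    def test_matches_brute_force_on_random_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            y = rng.uniform(-1, 1, size=rng.integers(4, 200))
            brute = -sum(v * v * np.log(v * v) for v in y if v != 0.0)
            assert features.shannon_entropy(y) == pytest.approx(brute, rel=1e-9)


class TestAggregate:
    def make_series(self, values):
        n = len(values)
        return [features.BeatFeatures(**{f: float(v) for f in
                                         features.BEAT_FEATURE_NAMES})
                for v in values]

    def scalars(self, preset):
        return {k: 0.5 for k in preset["window_scalars"]}

    def test_constant_series_degenerate_stats(self, cfg):
        preset = features.registry_preset("standard", cfg)
        out = features.aggregate(self.make_series([2.0, 2.0, 2.0, 2.0]),
                                 self.scalars(preset), preset)
        assert out["heart_rate_mean"] == 2.0
        assert out["heart_rate_std"] == 0.0
        assert out["heart_rate_skewness"] == 0.0
        assert out["heart_rate_kurtosis"] == 0.0

    def test_hand_computed_mean_and_std(self, cfg):
        preset = features.registry_preset("standard", cfg)
        out = features.aggregate(self.make_series([1, 2, 3, 4, 5]),
                                 self.scalars(preset), preset)
        assert out["systolic_time_mean"] == pytest.approx(3.0)
        assert out["systolic_time_std"] == pytest.approx(np.sqrt(2.5))

    def test_standard_preset_is_exactly_65_unique_names(self, cfg):
        preset = features.registry_preset("standard", cfg)
        names = features.feature_names(preset)
        assert len(names) == 65 and len(set(names)) == 65
        assert "ptt_p_kurtosis" in names and "entropy_ppg" in names

    def test_too_few_beats_rejected(self, cfg):
        preset = features.registry_preset("standard", cfg)
        with pytest.raises(InvalidArgumentError):
            features.aggregate(self.make_series([1, 2]), self.scalars(preset), preset)

    def test_unknown_preset_rejected(self, cfg):
        with pytest.raises(InvalidArgumentError):
            features.registry_preset("nope", cfg)


def test_pulse_rate_from_ppi():
    # PPI of 0.75 s corresponds to a pulse rate of 80 bpm
    sig = synthetic_beat_signal()
    x = np.concatenate([sig.samples[:375], sig.samples[:375], sig.samples])
    s = Signal(x, fs=FS)
    beats = [
        BeatFiducials(valley_idx=0, peak_idx=100, next_valley_idx=375),
        BeatFiducials(valley_idx=375, peak_idx=475, next_valley_idx=750),
        BeatFiducials(valley_idx=750, peak_idx=850, next_valley_idx=1200),
    ]
    rpeaks = RPeaks(indices=np.array([10, 385, 760]), fs=FS)
    bf = features.beat_features(s, beats, rpeaks)
    assert bf[0].peak_to_peak_interval == pytest.approx(0.75)
    assert bf[0].pulse_rate == pytest.approx(80.0)
    assert bf[0].ptt_p == pytest.approx((100 - 10) / FS)
    assert bf[0].ptt_f == pytest.approx(0.0, abs=1e-12) or np.isnan(bf[0].ptt_f)
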