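import numpy as np
import pandas as pd
import pytest

from qeegpod.features import (
    DEFAULT_CONFIG,
    FeatureConfig,
    PSDEstimate,
    aeeg_gain,
    aeeg_limits,
    extract_features,
    power_spectrum,
    relative_alpha_variability,
    relative_band_powers,
    spectral_edge_frequency,
    spectral_entropy,
)
from qeegpod.preprocessing import segment_epochs
from qeegpod.recording import STANDARD_CHANNELS, EEGRecording

from .conftest import sinusoid_recording


def flat_psd(f_lo=0.0, f_hi=128.0, df=0.125, level=1.0, n_channels=1):
    freqs = np.arange(f_lo, f_hi + df / 2, df)
    power = np.full((n_channels, freqs.size), level)
    return PSDEstimate(
        freqs=freqs,
        power=power,
        channel_labels=tuple(STANDARD_CHANNELS[:n_channels]),
        resolution_hz=df,
        n_epochs_used=1,
    )


def white_noise_recording(sigma=10.0, duration_s=60.0, fs=256.0, n_channels=4, seed=0):
    rng = np.random.default_rng(seed)
    return EEGRecording(
        samples=rng.normal(0.0, sigma, size=(n_channels, int(duration_s * fs))),
        fs=fs,
        channel_labels=tuple(STANDARD_CHANNELS[:n_channels]),
    )


class TestPowerSpectrum:
    def test_sinusoid_peak_at_nearest_bin(self):
        rec = sinusoid_recording(10.0, duration_s=40.0)
        psd = power_spectrum(segment_epochs(rec, 8.0))
        peak = psd.freqs[np.argmax(psd.power[0])]
        assert peak == pytest.approx(10.0, abs=psd.resolution_hz)

    def test_parseval_white_noise(self):
        sigma = 7.0
        rec = white_noise_recording(sigma=sigma, duration_s=120.0)
        psd = power_spectrum(segment_epochs(rec, 8.0))
        integral = np.trapezoid(psd.power, psd.freqs, axis=-1)
        np.testing.assert_allclose(integral, sigma**2, rtol=0.05)

    def test_duplicated_epochs_average_to_the_same_psd(self):
        rec = sinusoid_recording(10.0, duration_s=8.0)
        one = power_spectrum(segment_epochs(rec, 8.0))
        doubled = rec.with_samples(np.concatenate([rec.samples, rec.samples], axis=-1))
        two = power_spectrum(segment_epochs(doubled, 8.0))
        np.testing.assert_allclose(one.power, two.power, rtol=1e-10)

    def test_no_retained_epochs_errors(self):
        rec = sinusoid_recording(10.0, duration_s=8.0)
        ep = segment_epochs(rec, 8.0)
        from dataclasses import replace

        empty = replace(ep, rejection_reasons=("amplitude",) * ep.n_epochs)
        with pytest.raises(ValueError, match="no retained epochs"):
            power_spectrum(empty)


class TestRelativeBandPowers:
    def test_pure_alpha_tone(self):
        rec = sinusoid_recording(10.0, duration_s=40.0)
        psd = power_spectrum(segment_epochs(rec, 8.0))
        bands = relative_band_powers(psd).loc["mean"]
        assert bands["alpha"] > 98.0
        assert bands[["delta", "theta", "beta"]].sum() < 2.0

    def test_flat_spectrum_fractions_equal_bandwidth_ratios(self):
        psd = flat_psd()
        bands = relative_band_powers(
            psd, band_edges=(1.0, 4.0, 8.0, 13.0, 30.0), normalization_range=(1.0, 30.0)
        ).loc["mean"]
        np.testing.assert_allclose(
            bands.to_numpy(),
            [100 * 3 / 29, 100 * 4 / 29, 100 * 5 / 29, 100 * 17 / 29],
            rtol=1e-9,
        )

    def test_fractions_sum_to_100_when_bands_tile_range(self):
        rec = white_noise_recording(seed=5)
        psd = power_spectrum(segment_epochs(rec, 8.0))
        bands = relative_band_powers(psd)
        np.testing.assert_allclose(bands.sum(axis=1), 100.0, atol=0.1)

    def test_zero_power_errors(self):
        psd = flat_psd(level=0.0)
        with pytest.raises(ValueError, match="zero total power"):
            relative_band_powers(psd)


class TestSpectralEntropy:
    def test_pure_tone_low_entropy(self):
        # the Hann taper spreads a tone over ~3 of ~300 bins, bounding
        # its normalized entropy near ln(3)/ln(n_bins), far below noise
        rec = sinusoid_recording(10.0, duration_s=60.0)
        psd = power_spectrum(segment_epochs(rec, 8.0))
        assert spectral_entropy(psd).loc["mean"] < 20.0

    def test_white_noise_high_entropy(self):
        rec = white_noise_recording(seed=2)
        psd = power_spectrum(segment_epochs(rec, 8.0))
        assert spectral_entropy(psd).loc["mean"] > 95.0

    def test_two_equal_bins_closed_form(self):
        freqs = np.arange(0.0, 128.0 + 0.25, 0.5)
        power = np.zeros((1, freqs.size))
        in_range = (freqs >= 0.5) & (freqs <= 40.0)
        n_bins = int(in_range.sum())
        idx = np.nonzero(in_range)[0]
        power[0, idx[3]] = power[0, idx[10]] = 4.2
        psd = PSDEstimate(
            freqs=freqs, power=power, channel_labels=("Fp1",),
            resolution_hz=0.5, n_epochs_used=1,
        )
        se = spectral_entropy(psd).loc["mean"]
        assert se == pytest.approx(100.0 * np.log(2) / np.log(n_bins), rel=1e-9)

    def test_amplitude_invariance(self):
        rec = white_noise_recording(seed=3)
        psd = power_spectrum(segment_epochs(rec, 8.0))
        from dataclasses import replace

        scaled = replace(psd, power=psd.power * 17.0)
        pd.testing.assert_series_equal(spectral_entropy(psd), spectral_entropy(scaled))

    def test_bin_permutation_invariance(self):
        rng = np.random.default_rng(4)
        psd = flat_psd(df=0.5)
        power = rng.random((1, psd.freqs.size))
        in_range = (psd.freqs >= 0.5) & (psd.freqs <= 40.0)
        idx = np.nonzero(in_range)[0]
        permuted = power.copy()
        permuted[0, idx] = power[0, rng.permutation(idx)]
        from dataclasses import replace

        a = spectral_entropy(replace(psd, power=power)).loc["mean"]
        b = spectral_entropy(replace(psd, power=permuted)).loc["mean"]
        assert a == pytest.approx(b, rel=1e-12)


class TestSpectralEdge:
    def test_pure_tone_edge_at_tone(self):
        rec = sinusoid_recording(10.0, duration_s=60.0)
        psd = power_spectrum(segment_epochs(rec, 8.0))
        assert spectral_edge_frequency(psd).loc["mean"] == pytest.approx(10.0, abs=0.3)

    def test_flat_spectrum_analytic_edge(self):
        psd = flat_psd()
        assert spectral_edge_frequency(psd).loc["mean"] == pytest.approx(38.03, abs=0.01)

    def test_monotone_in_quantile(self):
        rec = white_noise_recording(seed=6)
        psd = power_spectrum(segment_epochs(rec, 8.0))
        qs = [0.5, 0.75, 0.9, 0.95, 0.99]
        sefs = [spectral_edge_frequency(psd, q).loc["mean"] for q in qs]
        assert all(a <= b + 1e-12 for a, b in zip(sefs, sefs[1:]))


class TestRAV:
    def test_all_power_inside_extended_alpha_gives_100(self):
        rec = sinusoid_recording(10.0, duration_s=60.0)
        psd = power_spectrum(segment_epochs(rec, 8.0))
        assert relative_alpha_variability(psd).loc["mean"] > 99.0

    def test_flat_spectrum_bandwidth_ratio(self):
        psd = flat_psd()
        assert relative_alpha_variability(psd).loc["mean"] == pytest.approx(
            100 * 8 / 19, rel=1e-9
        )

    def test_psd_not_covering_denominator_errors(self):
        psd = flat_psd(f_lo=2.0, f_hi=18.0)
        with pytest.raises(ValueError, match="outside the PSD grid"):
            relative_alpha_variability(psd)


class TestAEEG:
    def test_zero_signal_gives_zero_limits(self):
        rec = EEGRecording(
            samples=np.zeros((2, 256 * 40)), fs=256.0, channel_labels=("Fp1", "Fp2")
        )
        lower, upper = aeeg_limits(rec)
        assert upper.loc["mean"] == 0.0 and lower.loc["mean"] == 0.0

    def test_stationary_sinusoid_envelope_closed_form(self):
        """A constant-amplitude tone has a constant envelope, so both
        limits equal the peak-to-peak amplitude times the chain gain."""
        amp = 5.0
        rec = sinusoid_recording(10.0, amplitude_uv=amp, duration_s=60.0)
        gain = aeeg_gain(np.array([10.0]))[0]
        assert gain == pytest.approx(1.0, abs=0.1)  # near-unity at reference
        lower, upper = aeeg_limits(rec)
        expected = 2.0 * amp * gain
        assert upper.loc["mean"] == pytest.approx(expected, rel=0.05)
        assert lower.loc["mean"] == pytest.approx(expected, rel=0.05)

    def test_limits_scale_linearly_with_amplitude(self, slow_heavy_profile):
        from dataclasses import replace

        from qeegpod.simulate import synthesize_recording

        rec1 = synthesize_recording(slow_heavy_profile, 40.0, seed=8)
        rec2 = synthesize_recording(
            replace(slow_heavy_profile, amplitude_scale=slow_heavy_profile.amplitude_scale * 3),
            40.0,
            seed=8,
        )
        l1, u1 = aeeg_limits(rec1)
        l2, u2 = aeeg_limits(rec2)
        np.testing.assert_allclose(u2.to_numpy(), 3 * u1.to_numpy(), rtol=1e-9)
        np.testing.assert_allclose(l2.to_numpy(), 3 * l1.to_numpy(), rtol=1e-9)

    def test_upper_at_least_lower(self, short_recording):
        lower, upper = aeeg_limits(short_recording)
        assert (upper.to_numpy() >= lower.to_numpy()).all()

    def test_too_short_recording_errors(self):
        rec = sinusoid_recording(10.0, duration_s=10.0)
        with pytest.raises(ValueError, match="at least 30"):
            aeeg_limits(rec)


class TestExtractFeatures:
    def test_deterministic(self, short_recording):
        a = extract_features(short_recording)
        b = extract_features(short_recording)
        pd.testing.assert_frame_equal(a.per_channel, b.per_channel)

    def test_missing_channels_named_in_error(self, short_recording):
        partial = short_recording.pick(["Fp1", "Fp2", "C3"])
        with pytest.raises(ValueError, match="O1"):
            extract_features(partial)

    def test_slowed_eeg_orders_delta_above_alpha(self, short_recording):
        feats = extract_features(short_recording)
        assert feats.delta_percent > feats.alpha_percent

    def test_white_noise_features(self):
        """White noise: near-maximal entropy and bandwidth-ratio fractions."""
        rec = white_noise_recording(n_channels=8, duration_s=120.0, seed=9)
        feats = extract_features(rec)
        assert feats.spectral_entropy > 95.0
        cfg = DEFAULT_CONFIG
        lo, hi = cfg.normalization_range
        widths = np.diff(cfg.band_edges) / (hi - lo)
        got = np.array(
            [feats.delta_percent, feats.theta_percent, feats.alpha_percent, feats.beta_percent]
        )
        np.testing.assert_allclose(got / 100.0, widths, atol=0.02)

    def test_band_fractions_sum_to_100(self, short_recording):
        feats = extract_features(short_recording)
        total = (
            feats.delta_percent + feats.theta_percent
            + feats.alpha_percent + feats.beta_percent
        )
        assert total == pytest.approx(100.0, abs=0.1)
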