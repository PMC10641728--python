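"""Quantitative EEG features for sedated ICU recordings.

Implements the five biomarker families used to discriminate
postoperative delirium: spectral entropy (SE), amplitude-integrated EEG
limits (aEEG), relative alpha variability (RAV), relative band powers
(delta/theta/alpha/beta) and the 95% spectral edge frequency (SEF95).
All spectral features are computed per channel from an epoch-averaged
tapered periodogram and then averaged across the eight recording
channels, matching how clinical qEEG trends are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .preprocessing import (
    EpochedRecording,
    bandpass,
    reject_artifacts,
    segment_epochs,
)
from .recording import STANDARD_CHANNELS, EEGRecording

FEATURE_NAMES: tuple[str, ...] = (
    "spectral_entropy",
    "aeeg_upper_uv",
    "aeeg_lower_uv",
    "rav_percent",
    "delta_percent",
    "theta_percent",
    "alpha_percent",
    "beta_percent",
    "sef95_hz",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Every tunable constant of the extraction chain.

    The conventional clinical band edges (delta 0.5–4, theta 4–8, alpha
    8–13, beta 13–30 Hz) and the 0.5–40 Hz analysis band-pass are
    defaults; everything is overridable because vendor qEEG packages
    differ in exactly these constants.
    """

    # analysis band-pass
    filter_low_hz: float = 0.5
    filter_high_hz: float = 40.0
    filter_order: int = 4
    # epoching: 8 s Hann windows with 50% overlap give a 0.125 Hz grid,
    # tight enough that taper smearing across band edges stays well below
    # the between-subject spread of the band fractions
    epoch_length_s: float = 8.0
    epoch_overlap_s: float = 4.0
    peak_to_peak_limit_uv: float = 200.0
    flatline_limit_uv: float = 0.1
    # band powers
    band_edges: tuple[float, ...] = (0.5, 4.0, 8.0, 13.0, 30.0)
    normalization_range: tuple[float, float] = (0.5, 30.0)
    # spectral entropy
    se_range: tuple[float, float] = (0.5, 40.0)
    # spectral edge
    sef_quantile: float = 0.95
    sef_range: tuple[float, float] = (0.5, 40.0)
    # relative alpha variability
    rav_numerator: tuple[float, float] = (6.0, 14.0)
    rav_denominator: tuple[float, float] = (1.0, 20.0)
    rav_window_s: float = 120.0
    # aEEG chain
    aeeg_band: tuple[float, float] = (2.0, 15.0)
    aeeg_filter_order: int = 2
    aeeg_reference_hz: float = 10.0
    aeeg_window_s: float = 0.5
    aeeg_smooth_s: float = 15.0
    aeeg_lower_percentile: float = 10.0
    aeeg_upper_percentile: float = 90.0
    # montage
    channels: tuple[str, ...] = STANDARD_CHANNELS

    @property
    def band_names(self) -> tuple[str, ...]:
        return ("delta", "theta", "alpha", "beta")


DEFAULT_CONFIG = FeatureConfig()


@dataclass(frozen=True)
class PSDEstimate:
    """Epoch-averaged per-channel power spectral density (µV²/Hz)."""

    freqs: np.ndarray
    power: np.ndarray  # (n_channels, n_freqs)
    channel_labels: tuple[str, ...]
    resolution_hz: float
    n_epochs_used: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("PSD must be nonnegative")


def power_spectrum(epoched: EpochedRecording) -> PSDEstimate:
    """Hann-tapered periodogram per retained epoch, averaged per channel.

    Each epoch is one taper window (at the default 4 s this gives a
    0.25 Hz grid, enough to resolve the band edges), and the density
    scaling makes the integral of the PSD approximate the signal
    variance (Parseval).
    """
    kept = epoched.retained
    if kept.shape[0] == 0:
        raise ValueError("no retained epochs to estimate a spectrum from")
    freqs, psd = signal.periodogram(
        kept, fs=epoched.fs, window="hann", detrend="constant", axis=-1
    )
    power = psd.mean(axis=0)  # average epochs -> (n_channels, n_freqs)
    return PSDEstimate(
        freqs=freqs,
        power=power,
        channel_labels=epoched.channel_labels,
        resolution_hz=float(freqs[1] - freqs[0]),
        n_epochs_used=int(kept.shape[0]),
    )


def _band_integral(freqs: np.ndarray, power: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Trapezoidal integral of each channel's PSD over [lo, hi].

    Band edges that fall between grid points are handled by linear
    interpolation of the PSD at the edge.
    """
    if lo < freqs[0] - 1e-9 or hi > freqs[-1] + 1e-9:
        raise ValueError(f"band [{lo}, {hi}] Hz outside the PSD grid")
    grid = freqs[(freqs > lo) & (freqs < hi)]
    f = np.concatenate(([lo], grid, [hi]))
    p = np.vstack([np.interp(f, freqs, row) for row in np.atleast_2d(power)])
    return np.trapezoid(p, f, axis=-1)


def relative_band_powers(
    psd: PSDEstimate,
    band_edges: tuple[float, ...] = DEFAULT_CONFIG.band_edges,
    normalization_range: tuple[float, float] = DEFAULT_CONFIG.normalization_range,
) -> pd.DataFrame:
    """Per-channel relative band power in percent, plus the channel mean.

    Each band integral is divided by the integral over
    ``normalization_range`` so the fractions sum to 100% when the bands
    tile the normalization range.
    """
    total = _band_integral(psd.freqs, psd.power, *normalization_range)
    if np.any(total <= 0):
        raise ValueError("zero total power in the normalization range")
    cols = {}
    for name, lo, hi in zip(
        ("delta", "theta", "alpha", "beta"), band_edges[:-1], band_edges[1:]
    ):
        cols[name] = 100.0 * _band_integral(psd.freqs, psd.power, lo, hi) / total
    out = pd.DataFrame(cols, index=list(psd.channel_labels))
    out.loc["mean"] = out.mean(axis=0)
    return out


def _restrict(psd: PSDEstimate, lo: float, hi: float) -> tuple[np.ndarray, np.ndarray]:
    mask = (psd.freqs >= lo - 1e-9) & (psd.freqs <= hi + 1e-9)
    return psd.freqs[mask], psd.power[:, mask]


def spectral_entropy(
    psd: PSDEstimate, se_range: tuple[float, float] = DEFAULT_CONFIG.se_range
) -> pd.Series:
    """Normalized Shannon spectral entropy on a 0–100 scale.

    The PSD bins inside ``se_range`` are normalized to a probability
    distribution per channel; the Shannon entropy is divided by
    ``log(n_bins)`` and scaled by 100, so a pure tone scores near 0 and
    white noise near 100.  This is the standard normalized-entropy
    index; absolute agreement with proprietary monitor entropies is not
    attempted.
    """
    freqs, power = _restrict(psd, *se_range)
    if freqs.size < 2:
        raise ValueError("spectral-entropy range must span at least two PSD bins")
    total = power.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("zero power in the spectral-entropy range")
    p = power / total
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    se = -plogp.sum(axis=-1) / np.log(freqs.size) * 100.0
    out = pd.Series(se, index=list(psd.channel_labels))
    out.loc["mean"] = out.mean()
    return out


def spectral_edge_frequency(
    psd: PSDEstimate,
    quantile: float = DEFAULT_CONFIG.sef_quantile,
    sef_range: tuple[float, float] = DEFAULT_CONFIG.sef_range,
) -> pd.Series:
    """Frequency below which ``quantile`` of the power in range lies.

    The cumulative trapezoidal power is linearly interpolated between
    grid points, which removes the grid-resolution bias of reporting
    the nearest bin.
    """
    if not 0.0 < quantile <= 1.0:
        raise ValueError("quantile must be in (0, 1]")
    freqs, power = _restrict(psd, *sef_range)
    cum = np.concatenate(
        [np.zeros((power.shape[0], 1)), np.cumsum(
            0.5 * (power[:, 1:] + power[:, :-1]) * np.diff(freqs), axis=-1
        )],
        axis=-1,
    )
    totals = cum[:, -1]
    if np.any(totals <= 0):
        raise ValueError("zero power in the spectral-edge range")
    sef = np.array(
        [np.interp(quantile * t, c, freqs) for c, t in zip(cum, totals)]
    )
    out = pd.Series(sef, index=list(psd.channel_labels))
    out.loc["mean"] = out.mean()
    return out


def relative_alpha_variability(
    psd: PSDEstimate,
    numerator: tuple[float, float] = DEFAULT_CONFIG.rav_numerator,
    denominator: tuple[float, float] = DEFAULT_CONFIG.rav_denominator,
) -> pd.Series:
    """Extended-alpha power ratio in percent: 6–14 Hz over 1–20 Hz.

    Despite the clinical name ("relative alpha variability", a
    cerebral-blood-flow surrogate), the quantity is defined as a plain
    band-power ratio over a 2-minute analysis window; the windowing is
    handled by :func:`extract_features`.
    """
    num = _band_integral(psd.freqs, psd.power, *numerator)
    den = _band_integral(psd.freqs, psd.power, *denominator)
    if np.any(den <= 0):
        raise ValueError("zero power in the RAV denominator range")
    out = pd.Series(100.0 * num / den, index=list(psd.channel_labels))
    out.loc["mean"] = out.mean()
    return out


# ---------------------------------------------------------------------------
# amplitude-integrated EEG
# ---------------------------------------------------------------------------

def aeeg_gain(
    freqs: np.ndarray, config: FeatureConfig = DEFAULT_CONFIG, fs: float = 256.0
) -> np.ndarray:
    """Amplitude gain of the aEEG conditioning chain at ``freqs``.

    The chain is a zero-phase Butterworth band-pass over
    ``config.aeeg_band`` followed by a linear-in-frequency weighting
    (the classic ~12 dB/decade rising response of cerebral function
    monitors) normalized to unit gain at ``config.aeeg_reference_hz``.
    """
    lo, hi = config.aeeg_band
    sos = signal.butter(config.aeeg_filter_order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    freqs = np.asarray(freqs, dtype=float)
    _, h = signal.sosfreqz(sos, worN=2.0 * np.pi * freqs / fs)
    return np.abs(h) ** 2 * (freqs / config.aeeg_reference_hz)


def _aeeg_condition(x: np.ndarray, fs: float, config: FeatureConfig) -> np.ndarray:
    lo, hi = config.aeeg_band
    sos = signal.butter(config.aeeg_filter_order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=-1)
    spec = np.fft.rfft(y, axis=-1)
    f = np.fft.rfftfreq(y.shape[-1], d=1.0 / fs)
    return np.fft.irfft(spec * (f / config.aeeg_reference_hz), n=y.shape[-1], axis=-1)


def aeeg_limits(
    recording: EEGRecording, config: FeatureConfig = DEFAULT_CONFIG
) -> tuple[pd.Series, pd.Series]:
    """Lower/upper border amplitudes of the amplitude-integrated EEG.

    Frequency-weighted band-passed signal -> peak-to-peak amplitude per
    0.5 s window -> moving-average smoothing over 15 s -> the 10th and
    90th percentiles of the smoothed envelope are the lower and upper
    aEEG limits, per channel, with the 8-channel mean appended.  The
    exact filter band, weighting, window and percentiles are
    configurable because published aEEG implementations are
    vendor-specific.
    """
    if recording.duration_s < 30.0:
        raise ValueError("aEEG limits need at least 30 s of signal")
    y = _aeeg_condition(recording.samples, recording.fs, config)
    n_win = int(round(config.aeeg_window_s * recording.fs))
    n_full = (y.shape[-1] // n_win) * n_win
    wins = y[:, :n_full].reshape(y.shape[0], -1, n_win)
    env = wins.max(axis=-1) - wins.min(axis=-1)  # (ch, n_windows)
    n_smooth = max(1, int(round(config.aeeg_smooth_s / config.aeeg_window_s)))
    kernel = np.ones(n_smooth)
    counts = np.convolve(np.ones(env.shape[-1]), kernel, mode="same")
    smoothed = np.apply_along_axis(
        lambda e: np.convolve(e, kernel, mode="same") / counts, -1, env
    )
    lower = np.percentile(smoothed, config.aeeg_lower_percentile, axis=-1)
    upper = np.percentile(smoothed, config.aeeg_upper_percentile, axis=-1)
    idx = list(recording.channel_labels)
    lo = pd.Series(lower, index=idx)
    hi = pd.Series(upper, index=idx)
    lo.loc["mean"] = lo.mean()
    hi.loc["mean"] = hi.mean()
    return lo, hi


# ---------------------------------------------------------------------------
# one-call extraction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QEEGFeatures:
    """One subject's qEEG biomarkers: per-channel table plus the mean.

    ``per_channel`` rows are the 8 channels plus a ``"mean"`` row;
    columns follow :data:`FEATURE_NAMES`.
    """

    per_channel: pd.DataFrame
    subject_id: str = ""
    group_label: str = ""

    @property
    def mean(self) -> pd.Series:
        """The 8-channel average of every feature."""
        return self.per_channel.loc["mean"]

    def __getattr__(self, name: str):
        if name in FEATURE_NAMES:
            return float(self.per_channel.loc["mean", name])
        raise AttributeError(name)


def preprocess(recording: EEGRecording, config: FeatureConfig = DEFAULT_CONFIG):
    """Band-pass, epoch and artifact-screen a recording."""
    filtered = bandpass(
        recording, config.filter_low_hz, config.filter_high_hz, config.filter_order
    )
    epoched = segment_epochs(filtered, config.epoch_length_s, config.epoch_overlap_s)
    return filtered, reject_artifacts(
        epoched, config.peak_to_peak_limit_uv, config.flatline_limit_uv
    )


def extract_features(
    recording: EEGRecording, config: FeatureConfig = DEFAULT_CONFIG
) -> QEEGFeatures:
    """Run the full extraction chain on one recording.

    The recording must contain the configured 8 channels; extra
    channels are ignored.  RAV is computed on the first 2 minutes when
    the recording is longer (its clinical definition is tied to a
    2-minute window); every other spectral feature uses all retained
    epochs.  Deterministic given the input.
    """
    missing = [ch for ch in config.channels if ch not in recording.channel_labels]
    if missing:
        raise ValueError(f"recording is missing required channels: {missing}")
    rec = recording.pick(list(config.channels))
    filtered, epoched = preprocess(rec, config)
    psd = power_spectrum(epoched)

    se = spectral_entropy(psd, config.se_range)
    lower, upper = aeeg_limits(filtered, config)
    bands = relative_band_powers(psd, config.band_edges, config.normalization_range)
    sef = spectral_edge_frequency(psd, config.sef_quantile, config.sef_range)

    if rec.duration_s > config.rav_window_s:
        n = int(round(config.rav_window_s * rec.fs))
        _, rav_epoched = preprocess(rec.with_samples(rec.samples[:, :n]), config)
        rav_psd = power_spectrum(rav_epoched)
    else:
        rav_psd = psd
    rav = relative_alpha_variability(rav_psd, config.rav_numerator, config.rav_denominator)

    table = pd.DataFrame(
        {
            "spectral_entropy": se,
            "aeeg_upper_uv": upper,
            "aeeg_lower_uv": lower,
            "rav_percent": rav,
            "delta_percent": bands["delta"],
            "theta_percent": bands["theta"],
            "alpha_percent": bands["alpha"],
            "beta_percent": bands["beta"],
            "sef95_hz": sef,
        }
    )
    return QEEGFeatures(
        per_channel=table,
        subject_id=recording.subject_id,
        group_label=recording.group_label,
    )
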