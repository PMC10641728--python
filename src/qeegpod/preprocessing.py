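"""Raw-EEG conditioning: analysis band-pass, epoching, artifact masking.

The analysis chain mirrors routine ICU qEEG practice: a zero-phase
0.5–40 Hz band-pass, segmentation into fixed-length epochs, and
amplitude-based epoch rejection standing in for the visual artifact
screening a neurophysiologist would perform.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .recording import EEGRecording

#: Reason codes written into the rejection mask.
REASON_OK = ""
REASON_AMPLITUDE = "amplitude"
REASON_FLATLINE = "flatline"

DEFAULT_FILTER_ORDER = 4


def _bandpass_sos(low_hz: float, high_hz: float, fs: float, order: int) -> np.ndarray:
    nyq = fs / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < Nyquist ({nyq} Hz); "
            f"got low={low_hz}, high={high_hz}"
        )
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass(
    recording: EEGRecording,
    low_hz: float = 0.5,
    high_hz: float = 40.0,
    order: int = DEFAULT_FILTER_ORDER,
) -> EEGRecording:
    """Zero-phase Butterworth band-pass of every channel.

    Forward-backward (``sosfiltfilt``) filtering is used so that the
    envelope-based aEEG stage downstream sees no phase distortion; the
    effective magnitude response is the squared Butterworth response.
    In-band sinusoids are preserved to within a few percent and DC is
    removed entirely.
    """
    sos = _bandpass_sos(low_hz, high_hz, recording.fs, order)
    filtered = signal.sosfiltfilt(sos, recording.samples, axis=-1)
    return recording.with_samples(filtered)


def bandpass_power_weight(
    freqs: np.ndarray,
    low_hz: float = 0.5,
    high_hz: float = 40.0,
    fs: float = 256.0,
    order: int = DEFAULT_FILTER_ORDER,
) -> np.ndarray:
    """Power transfer of the zero-phase band-pass at ``freqs`` (Hz).

    Returns the factor by which a power spectral density is multiplied
    after :func:`bandpass`.  Forward-backward filtering applies the
    Butterworth magnitude twice, so the PSD weight is ``|H(f)|**4``.
    Used by profile calibration to model the analysis chain exactly.
    """
    sos = _bandpass_sos(low_hz, high_hz, fs, order)
    freqs = np.asarray(freqs, dtype=float)
    _, h = signal.sosfreqz(sos, worN=2.0 * np.pi * freqs / fs)
    return np.abs(h) ** 4


@dataclass(frozen=True)
class EpochedRecording:
    """Epoch-segmented EEG with a per-epoch rejection mask.

    ``epochs`` has shape ``(n_epochs, n_channels, n_samples)``; epoch
    boundaries are half-open in samples and a trailing partial epoch is
    dropped.  ``rejection_reasons`` holds one reason code per epoch
    (empty string = retained); the samples themselves are never altered
    by rejection.
    """

    epochs: np.ndarray
    fs: float
    epoch_length_s: float
    channel_labels: tuple[str, ...]
    rejection_reasons: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (epoch, channel, time)")
        if len(self.rejection_reasons) != self.epochs.shape[0]:
            raise ValueError("rejection mask length must equal the epoch count")

    @property
    def rejection_mask(self) -> np.ndarray:
        """Boolean array, True where the epoch is rejected."""
        return np.array([r != REASON_OK for r in self.rejection_reasons])

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def retained(self) -> np.ndarray:
        """Only the retained epochs, shape (n_kept, n_channels, n_samples)."""
        return self.epochs[~self.rejection_mask]


def segment_epochs(
    recording: EEGRecording,
    epoch_length_s: float = 4.0,
    overlap_s: float = 0.0,
) -> EpochedRecording:
    """Cut a recording into fixed-length (optionally overlapping) epochs.

    The number of epochs is ``floor((T - L) / (L - O)) + 1`` for
    recording length ``T``, epoch length ``L`` and overlap ``O`` (in
    samples); a recording shorter than one epoch is an error.
    """
    n_len = int(round(epoch_length_s * recording.fs))
    n_hop = n_len - int(round(overlap_s * recording.fs))
    if n_len <= 0 or n_hop <= 0:
        raise ValueError("epoch length must be positive and exceed the overlap")
    n_times = recording.n_times
    if n_times < n_len:
        raise ValueError(
            f"recording of {recording.duration_s:.2f} s is shorter than one "
            f"{epoch_length_s:.2f} s epoch"
        )
    n_epochs = (n_times - n_len) // n_hop + 1
    starts = np.arange(n_epochs) * n_hop
    epochs = np.stack([recording.samples[:, s : s + n_len] for s in starts])
    return EpochedRecording(
        epochs=epochs,
        fs=recording.fs,
        epoch_length_s=n_len / recording.fs,
        channel_labels=recording.channel_labels,
        rejection_reasons=tuple([REASON_OK] * n_epochs),
    )


def reject_artifacts(
    epoched: EpochedRecording,
    peak_to_peak_limit_uv: float = 200.0,
    flatline_limit_uv: float = 0.1,
) -> EpochedRecording:
    """Mask epochs with implausible amplitudes; never modifies samples.

    An epoch is masked as ``"amplitude"`` when any channel's
    peak-to-peak exceeds ``peak_to_peak_limit_uv`` (electrode movement,
    ICU interference) and as ``"flatline"`` when every channel's
    peak-to-peak falls below ``flatline_limit_uv`` (detached leads).
    """
    if peak_to_peak_limit_uv <= 0 or flatline_limit_uv <= 0:
        raise ValueError("rejection limits must be positive")
    p2p = epoched.epochs.max(axis=-1) - epoched.epochs.min(axis=-1)  # (epoch, ch)
    reasons = list(epoched.rejection_reasons)
    for i in range(epoched.n_epochs):
        if reasons[i] != REASON_OK:
            continue
        if np.any(p2p[i] > peak_to_peak_limit_uv):
            reasons[i] = REASON_AMPLITUDE
        elif np.all(p2p[i] < flatline_limit_uv):
            reasons[i] = REASON_FLATLINE
    if all(r != REASON_OK for r in reasons):
        raise ValueError(
            "every epoch was rejected; review the amplitude/flatline thresholds"
        )
    return replace(epoched, rejection_reasons=tuple(reasons))
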