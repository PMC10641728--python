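"""Synthetic sedated-ICU EEG: single recordings and two-arm cohorts.

Recordings are Gaussian noise shaped in the frequency domain to the
piecewise target spectrum of a :class:`~qeegpod.profiles.SpectralProfile`
(equivalent to summing zero-phase band-filtered white-noise components
with exact expected-power control and no inter-band leakage), with the
realized RMS pinned to the profile's amplitude scale.  Channels are
generated independently: the downstream features only ever
channel-average, so spatial covariance is irrelevant to them.

Cohorts draw per-subject profiles around a group mean with
logistic-normal jitter on the band fractions (keeps them on the
simplex) and log-normal, mean-one jitter on the amplitude scale (keeps
it positive), emulating the between-subject spread summarized by the
SEM columns of published group tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .profiles import SpectralProfile
from .recording import STANDARD_CHANNELS, EEGRecording


def synthesize_recording(
    profile: SpectralProfile,
    duration_s: float = 120.0,
    fs: float = 256.0,
    channel_labels: tuple[str, ...] = STANDARD_CHANNELS,
    seed: int = 0,
    subject_id: str = "",
    group_label: str = "",
) -> EEGRecording:
    """One multichannel recording with the profile's target spectrum.

    Each channel is an independent realization of the same spectral
    shaping; the same seed always yields bit-identical samples.
    """
    if duration_s < 4.0:
        raise ValueError("recordings must be at least 4 s long")
    if fs < 128.0:
        raise ValueError("sampling rate must be at least 128 Hz")
    top = max(profile.band_edges[-1], profile.normalization_range[1])
    if fs <= 2.0 * top:
        raise ValueError(
            f"sampling rate {fs} Hz violates Nyquist for content up to {top} Hz"
        )
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.sqrt(profile.density(freqs))
    samples = np.empty((len(channel_labels), n))
    for ch in range(len(channel_labels)):
        white = rng.standard_normal(n)
        spec = np.fft.rfft(white) * shape
        x = np.fft.irfft(spec, n=n)
        rms = np.sqrt(np.mean(x**2))
        samples[ch] = (
            x * (profile.amplitude_scale / rms) if rms > 0 else np.zeros(n)
        )
    return EEGRecording(
        samples=samples,
        fs=fs,
        channel_labels=tuple(channel_labels),
        subject_id=subject_id,
        group_label=group_label,
    )


@dataclass(frozen=True)
class GroupSpec:
    """One study arm: label, size, mean profile and between-subject spread.

    ``fraction_sigma`` is the SD of the Gaussian jitter applied to
    log band fractions before renormalization (logistic-normal);
    ``amplitude_sigma`` the SD of the log-normal, mean-one multiplier
    on the amplitude scale.  Zero dispersion reproduces the mean
    profile for every subject.
    """

    label: str
    n_subjects: int
    profile: SpectralProfile
    fraction_sigma: float = 0.0
    amplitude_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("each group needs at least one subject")
        if self.fraction_sigma < 0 or self.amplitude_sigma < 0:
            raise ValueError("dispersion values must be nonnegative")


@dataclass(frozen=True)
class CohortSpec:
    """A full synthetic study: groups, recording settings and the seed."""

    groups: tuple[GroupSpec, ...]
    duration_s: float = 120.0
    fs: float = 256.0
    channel_labels: tuple[str, ...] = STANDARD_CHANNELS
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort needs at least one group")
        top = max(
            max(g.profile.band_edges[-1], g.profile.normalization_range[1])
            for g in self.groups
        )
        if self.fs <= 2.0 * top:
            raise ValueError(
                f"sampling rate {self.fs} Hz violates Nyquist for content up to {top} Hz"
            )


def subject_seed(cohort_seed: int, group_index: int, subject_index: int) -> int:
    """Stable per-subject seed: SeedSequence(cohort_seed, spawn_key=(g, i)).

    Documented so that a subject's recording can be regenerated in
    isolation and is invariant to the order subjects are synthesized in.
    """
    ss = np.random.SeedSequence(entropy=cohort_seed, spawn_key=(group_index, subject_index))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


def _jitter_profile(
    profile: SpectralProfile,
    fraction_sigma: float,
    amplitude_sigma: float,
    rng: np.random.Generator,
) -> SpectralProfile:
    fracs = np.asarray(profile.band_fractions, dtype=float)
    if fraction_sigma > 0:
        logf = np.log(np.clip(fracs, 1e-12, None))
        logf = logf + rng.normal(0.0, fraction_sigma, size=fracs.shape)
        fracs = np.exp(logf)
        fracs = fracs / fracs.sum()
    amp = profile.amplitude_scale
    if amplitude_sigma > 0:
        # mean-one log-normal multiplier keeps the group mean amplitude unbiased
        amp = amp * rng.lognormal(-0.5 * amplitude_sigma**2, amplitude_sigma)
    return replace(profile, band_fractions=tuple(fracs), amplitude_scale=amp)


def synthesize_cohort(spec: CohortSpec) -> list[EEGRecording]:
    """Synthesize every subject of every group, labels and sizes exact.

    Per-subject randomness (profile jitter and signal noise) derives
    deterministically from the cohort seed via :func:`subject_seed`, so
    an identical spec yields a bit-identical dataset.
    """
    recordings: list[EEGRecording] = []
    for g_idx, group in enumerate(spec.groups):
        for s_idx in range(group.n_subjects):
            seed = subject_seed(spec.seed, g_idx, s_idx)
            rng = np.random.default_rng(seed)
            prof = _jitter_profile(
                group.profile, group.fraction_sigma, group.amplitude_sigma, rng
            )
            rec = synthesize_recording(
                prof,
                duration_s=spec.duration_s,
                fs=spec.fs,
                channel_labels=spec.channel_labels,
                seed=int(rng.integers(0, 2**31 - 1)),
                subject_id=f"{group.label}-{s_idx + 1:02d}",
                group_label=group.label,
            )
            recordings.append(rec)
    return recordings
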