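"""In-memory container for multichannel scalp EEG."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timezone

import numpy as np

#: 8-channel reduced 10/20 montage used by ICU wearable headsets:
#: left/right frontal, central, temporal and occipital electrodes.
STANDARD_CHANNELS: tuple[str, ...] = ("Fp1", "Fp2", "C3", "C4", "T3", "T4", "O1", "O2")

DEFAULT_START_TIME = datetime(2022, 1, 1, 0, 0, 0, tzinfo=timezone.utc)


@dataclass(frozen=True)
class EEGRecording:
    """A multichannel EEG recording in microvolts.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_times)`` in µV.
    fs
        Sampling rate in Hz.
    channel_labels
        One unique label per row of ``samples``.
    start_time
        Recording onset (metadata only).
    subject_id, group_label
        Cohort bookkeeping; empty strings when standalone.
    """

    samples: np.ndarray
    fs: float
    channel_labels: tuple[str, ...] = STANDARD_CHANNELS
    start_time: datetime = DEFAULT_START_TIME
    subject_id: str = ""
    group_label: str = ""

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=np.float64)
        if samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        object.__setattr__(self, "samples", samples)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        labels = tuple(self.channel_labels)
        if len(labels) != samples.shape[0]:
            raise ValueError(
                f"{len(labels)} channel labels for {samples.shape[0]} channel rows"
            )
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        object.__setattr__(self, "channel_labels", labels)

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs

    def with_samples(self, samples: np.ndarray) -> "EEGRecording":
        """Copy of the recording with the data replaced, metadata kept."""
        return replace(self, samples=samples)

    def pick(self, labels: "list[str] | tuple[str, ...]") -> "EEGRecording":
        """Sub-recording restricted to ``labels`` (in the given order)."""
        missing = [lb for lb in labels if lb not in self.channel_labels]
        if missing:
            raise KeyError(f"channels not present in recording: {missing}")
        idx = [self.channel_labels.index(lb) for lb in labels]
        return replace(self, samples=self.samples[idx], channel_labels=tuple(labels))
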