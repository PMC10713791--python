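"""Shared lightweight data containers.

The package operates on bare ``numpy`` arrays wrapped in small dataclasses;
heavier neurophysiology containers (e.g. ``mne.io.Raw``) can be converted by
taking ``raw.get_data()`` and the sampling rate.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EEGRecording:
    """A multi-channel EEG trial.

    Parameters
    ----------
    data:
        ``(n_channels, n_samples)`` array of potentials (arbitrary units).
    sampling_rate:
        Samples per second, > 0.
    channel_labels:
        Optional channel names; defaults to ``ch00, ch01, ...``.
    subject:
        Subject identifier (any hashable; synthetic data uses ints).
    label:
        Class label of the trial (e.g. emotion category index).
    state_labels:
        Optional ground-truth per-sample state sequence (synthetic data only).
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list[str] = field(default_factory=list)
    subject: object = None
    label: object = None
    state_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Trial length in seconds."""
        return self.n_samples / self.sampling_rate

    def average_reference(self) -> "EEGRecording":
        """Return a copy re-referenced to the common average."""
        data = self.data - self.data.mean(axis=0, keepdims=True)
        return EEGRecording(
            data=data,
            sampling_rate=self.sampling_rate,
            channel_labels=list(self.channel_labels),
            subject=self.subject,
            label=self.label,
            state_labels=None if self.state_labels is None else self.state_labels.copy(),
        )
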