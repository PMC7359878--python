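"""Shared lightweight time-series container."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SignalTimeSeries:
    """Uniformly sampled multichannel real-valued signals.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        One row per channel (brain region, neuron population, ...).
    fs : float
        Sampling rate in Hz.
    labels : list of str, optional
        Channel names; defaults to ``ch00, ch01, ...``.
    """

    data: np.ndarray
    fs: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.labels:
            self.labels = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Signal length in seconds."""
        return self.data.shape[1] / self.fs

    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[1]) / self.fs
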