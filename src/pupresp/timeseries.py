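"""Uniformly sampled 1-D signal container used throughout the package."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class TimeSeries:
    """A uniformly sampled signal.

    Parameters
    ----------
    data : ndarray, shape (n_samples,)
        Sample values. May contain NaN for missing samples (e.g. negative
        pupil-area readings) until preprocessing removes them.
    fs : float
        Sampling rate in Hz.
    unit : str
        Free-text unit label.
    annotations : list of (start, stop)
        Artifact intervals as half-open sample-index ranges.
    extras : dict
        Generator-side metadata (e.g. the instantaneous phase of a synthetic
        oscillation); never required by the analysis path.
    """

    data: np.ndarray
    fs: float
    unit: str = "au"
    annotations: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("TimeSeries data must be one-dimensional")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError("sampling rate must be positive and finite")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy(self) -> "TimeSeries":
        return TimeSeries(
            self.data.copy(),
            self.fs,
            self.unit,
            [tuple(iv) for iv in self.annotations],
            dict(self.extras),
        )
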