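"""Shared time-series containers.

All traces are regularly sampled; times are in milliseconds, currents in
picoamperes and voltages in millivolts throughout the package.  Rates are
reported in spike/s (``1000 * n_spikes / duration_ms``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "StimulusParams",
    "CurrentTrace",
    "VoltageTrace",
    "SpikeTrain",
    "Autocorrelation",
]


@dataclass(frozen=True)
class StimulusParams:
    """DC offset and fluctuation amplitude of a noisy current stimulus.

    Attributes
    ----------
    i0 : float
        Mean (DC) current, pA.
    sigma : float
        Standard deviation of the fluctuating component, pA.  Must be
        non-negative.
    """

    i0: float
    sigma: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.i0):
            raise ValueError("i0 must be finite")
        if not np.isfinite(self.sigma) or self.sigma < 0:
            raise ValueError("sigma must be finite and >= 0")


@dataclass
class CurrentTrace:
    """Regularly sampled injected-current waveform.

    Attributes
    ----------
    dt : float
        Sample interval, ms.
    values : ndarray
        Current samples, pA.
    params : StimulusParams, optional
        The (i0, sigma) pair the trace was composed with, if known.
    """

    dt: float
    values: np.ndarray
    params: StimulusParams | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0 or not np.isfinite(self.dt):
            raise ValueError("dt must be positive and finite")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-d array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("current values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Trace duration, ms."""
        return self.values.size * self.dt

    @property
    def times(self) -> np.ndarray:
        """Sample times, ms (starting at 0)."""
        return np.arange(self.values.size) * self.dt


@dataclass
class VoltageTrace:
    """Regularly sampled membrane-potential waveform (mV)."""

    dt: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0 or not np.isfinite(self.dt):
            raise ValueError("dt must be positive and finite")
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-d array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("voltage values must be finite")

    @property
    def n_samples(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.values.size * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt


@dataclass
class SpikeTrain:
    """Ordered action-potential times within a recording of known duration.

    Attributes
    ----------
    times : ndarray
        Strictly increasing spike times, ms, in ``[0, duration)``.
    duration : float
        Duration of the underlying recording, ms.
    """

    times: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-d")
        if self.duration <= 0 or not np.isfinite(self.duration):
            raise ValueError("duration must be positive and finite")
        if self.times.size:
            if not np.all(np.isfinite(self.times)):
                raise ValueError("spike times must be finite")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if self.times[0] < 0 or self.times[-1] >= self.duration:
                raise ValueError("spike times must lie in [0, duration)")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    @property
    def isis(self) -> np.ndarray:
        """Inter-spike intervals, ms."""
        return np.diff(self.times)

    @property
    def mean_rate(self) -> float:
        """Mean firing rate, spike/s."""
        return 1000.0 * self.times.size / self.duration


@dataclass
class Autocorrelation:
    """Sample autocorrelation of a current trace on a symmetric lag grid.

    ``values[lag] == values[-lag]`` by construction and the maximum sits at
    lag 0 (biased estimator).  Units: pA^2, lags in ms.
    """

    lags: np.ndarray
    values: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must have matching shapes")
        if self.lags.size % 2 != 1:
            raise ValueError("lag grid must be symmetric about 0 (odd length)")
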