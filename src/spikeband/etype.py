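"""Electrical phenotype (e-type) classification from step-response ISI patterns.

A cell is typed from the train of action potentials it fires at ~20 spike/s
during a 1-s depolarizing step: the sequence of inter-spike intervals is
summarized by its linear trend, its extremes and its irregularity, and the
five classes of layer-1 interneurons are assigned by rule precedence

    cSTUT -> bNAC -> cAC -> cIR -> cNAC

(structural single-interval criteria before global-trend criteria).  Every
result carries the full diagnostics so alternative orderings can be audited.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import ETYPE_LABELS
from .traces import SpikeTrain

__all__ = [
    "FICurve",
    "ISISequence",
    "ETypeResult",
    "fi_curve",
    "select_reference_train",
    "isi_slope",
    "classify",
]

# Classification constants (ms unless noted): the pause criterion for
# stuttering, the burst criterion for bNAC, the accommodation slope
# criterion (ms per interval index) and the irregularity criterion
# (CV of linearly detrended ISIs, dimensionless).
PAUSE_ISI = 100.0
BURST_ISI = 20.0
SLOPE_CRITERION = 1.0
IRREGULARITY_CRITERION = 0.25


@dataclass
class FICurve:
    """Firing rate (spike/s) per step amplitude (pA)."""

    amplitudes: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if self.amplitudes.shape != self.rates.shape:
            raise ValueError("amplitudes and rates must have equal length")
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")


@dataclass
class ISISequence:
    """Ordered inter-spike intervals of one step response."""

    isis: np.ndarray
    amplitude: float
    mean_rate: float

    def __post_init__(self) -> None:
        self.isis = np.asarray(self.isis, dtype=float)
        if np.any(self.isis <= 0):
            raise ValueError("ISIs must be positive")


@dataclass
class ETypeResult:
    """Assigned label plus the diagnostics the rules were evaluated on."""

    label: str
    isi_slope: float
    max_isi: float
    first_two_isis: tuple[float, ...]
    irregularity: float


def fi_curve(step_responses) -> FICurve:
    """Frequency-current curve from (amplitude, SpikeTrain) step responses."""
    amps, rates = [], []
    for amp, train in step_responses:
        amps.append(amp)
        rates.append(train.mean_rate)
    return FICurve(amplitudes=np.asarray(amps), rates=np.asarray(rates))


def select_reference_train(step_responses, target: float = 20.0) -> ISISequence:
    """ISIs of the step whose rate is nearest the target (default 20 spike/s).

    Steps with fewer than 3 spikes are ignored; ties are broken toward the
    lower amplitude.
    """
    candidates = []
    for amp, train in step_responses:
        if train.n_spikes >= 3:
            candidates.append((abs(train.mean_rate - target), amp, train))
    if not candidates:
        raise ValueError("no step response contains >= 3 spikes")
    candidates.sort(key=lambda c: (c[0], c[1]))
    _, amp, train = candidates[0]
    return ISISequence(isis=train.isis, amplitude=amp, mean_rate=train.mean_rate)


def isi_slope(seq: ISISequence | np.ndarray) -> float:
    """Least-squares slope of ISI value vs interval index (ms per index)."""
    isis = seq.isis if isinstance(seq, ISISequence) else np.asarray(seq, dtype=float)
    if isis.size < 3:
        raise ValueError("need >= 3 ISIs for a slope")
    return float(np.polyfit(np.arange(isis.size), isis, 1)[0])


def _detrended_cv(isis: np.ndarray) -> float:
    idx = np.arange(isis.size, dtype=float)
    trend = np.polyval(np.polyfit(idx, isis, 1), idx)
    return float(np.std(isis - trend) / np.mean(isis))


def classify(seq: ISISequence | np.ndarray) -> ETypeResult:
    """Assign one of the five e-type labels to an ISI sequence.

    Rules, in precedence order:

    1. cSTUT  if any ISI >= 100 ms;
    2. bNAC   if the leading 1-2 ISIs are < 20 ms and the remainder is a
              non-accommodating train (|slope| < 1 ms per index);
    3. cAC    if the overall slope exceeds 1 ms per index;
    4. cIR    if the detrended ISI CV exceeds 0.25 (all ISIs < 100 ms by
              precedence of rule 1);
    5. cNAC   otherwise.
    """
    isis = seq.isis if isinstance(seq, ISISequence) else np.asarray(seq, dtype=float)
    if isis.size < 5:
        raise ValueError("need >= 5 ISIs to classify")
    slope = isi_slope(isis)
    max_isi = float(np.max(isis))
    irregularity = _detrended_cv(isis)
    diag = dict(
        isi_slope=slope,
        max_isi=max_isi,
        first_two_isis=tuple(isis[:2]),
        irregularity=irregularity,
    )

    if max_isi >= PAUSE_ISI:
        return ETypeResult(label="cSTUT", **diag)

    n_lead = 0
    while n_lead < isis.size and isis[n_lead] < BURST_ISI:
        n_lead += 1
    if 1 <= n_lead <= 2 and isis.size - n_lead >= 3:
        if abs(isi_slope(isis[n_lead:])) < SLOPE_CRITERION:
            return ETypeResult(label="bNAC", **diag)

    if slope > SLOPE_CRITERION:
        return ETypeResult(label="cAC", **diag)

    if irregularity > IRREGULARITY_CRITERION:
        return ETypeResult(label="cIR", **diag)

    return ETypeResult(label="cNAC", **diag)
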