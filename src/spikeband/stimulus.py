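"""Ornstein-Uhlenbeck stimulus generation, composition and calibration.

The fluctuating current injected to probe spike-initiation dynamics is

    i(t) = i0 + sigma * eta(t)

where ``eta`` is a zero-mean, unit-variance Ornstein-Uhlenbeck (OU) process
with correlation time ``tau_corr`` (default 5 ms).  The OU process is
generated by the exact stationary update

    eta[k+1] = eta[k] * exp(-dt / tau) + sqrt(1 - exp(-2 dt / tau)) * xi[k]

with ``xi`` i.i.d. standard normal and ``eta[0]`` drawn standard normal, so
the process starts in its stationary distribution and no burn-in is needed.

This module also provides the biased sample autocorrelation used as the
stimulus power-spectral-density estimate downstream, and the bisection
calibrators used to set the DC offset (target firing rate) and the noise
amplitude (target membrane-potential fluctuation SD).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import signal

from .traces import Autocorrelation, CurrentTrace, StimulusParams

__all__ = [
    "OUParams",
    "BracketingError",
    "CalibrationResult",
    "generate_unit_ou",
    "compose_stimulus",
    "make_ou_current",
    "autocorrelation",
    "calibrate_dc",
    "calibrate_sigma",
]


class BracketingError(ValueError):
    """Raised when bisection bounds do not bracket the calibration target."""


@dataclass(frozen=True)
class OUParams:
    """Parameters of the unit-variance Ornstein-Uhlenbeck noise process.

    Attributes
    ----------
    tau_corr : float
        Correlation time, ms.
    dt : float
        Sample interval, ms.  A warning is emitted when ``dt > tau_corr / 5``
        because the discrete process then resolves the correlation structure
        poorly.
    n_samples : int
        Number of samples to generate.
    seed : int
        RNG seed; identical parameters and seed give bit-identical output.
    """

    tau_corr: float
    dt: float
    n_samples: int
    seed: int

    def __post_init__(self) -> None:
        if self.tau_corr <= 0 or not np.isfinite(self.tau_corr):
            raise ValueError("tau_corr must be positive and finite")
        if self.dt <= 0 or not np.isfinite(self.dt):
            raise ValueError("dt must be positive and finite")
        if int(self.n_samples) < 1:
            raise ValueError("n_samples must be >= 1")
        if self.dt > self.tau_corr / 5.0:
            warnings.warn(
                "dt exceeds tau_corr / 5; the OU correlation structure will be "
                "poorly resolved",
                stacklevel=3,
            )


def generate_unit_ou(params: OUParams) -> np.ndarray:
    """Generate a stationary unit-variance OU realization.

    Uses the exact update ``eta[k+1] = a * eta[k] + sqrt(1 - a^2) * xi[k]``
    with ``a = exp(-dt / tau_corr)``, iterated via a linear recursive filter.

    Returns
    -------
    ndarray
        ``n_samples`` values with zero mean and unit variance in expectation.
    """
    rng = np.random.default_rng(params.seed)
    n = int(params.n_samples)
    a = float(np.exp(-params.dt / params.tau_corr))
    noise = rng.standard_normal(n)
    eta0 = noise[0]
    if n == 1:
        return np.array([eta0])
    drive = np.sqrt(1.0 - a * a) * noise[1:]
    # y[k] = drive[k] + a * y[k-1], seeded with y[-1] = eta0.
    rest, _ = signal.lfilter([1.0], [1.0, -a], drive, zi=np.array([a * eta0]))
    return np.concatenate(([eta0], rest))


def compose_stimulus(
    eta: np.ndarray, sp: StimulusParams, dt: float
) -> CurrentTrace:
    """Compose the injected current ``i = i0 + sigma * eta``."""
    eta = np.asarray(eta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("eta must be finite")
    return CurrentTrace(dt=dt, values=sp.i0 + sp.sigma * eta, params=sp)


def make_ou_current(
    i0: float,
    sigma: float,
    duration: float,
    dt: float = 0.05,
    tau_corr: float = 5.0,
    seed: int = 0,
) -> CurrentTrace:
    """Convenience constructor: OU current of given duration (ms)."""
    n = int(round(duration / dt))
    eta = generate_unit_ou(OUParams(tau_corr=tau_corr, dt=dt, n_samples=n, seed=seed))
    return compose_stimulus(eta, StimulusParams(i0=i0, sigma=sigma), dt)


def autocorrelation(
    traces: CurrentTrace | Sequence[CurrentTrace], max_lag: float
) -> Autocorrelation:
    """Biased sample autocorrelation on the symmetric grid [-max_lag, max_lag].

    The estimator is ``c(k) = (1/n) * sum_t (x[t] - xbar)(x[t-k] - xbar)``
    (mean removed per trace, 1/n normalisation) so that its discrete Fourier
    transform — the power-spectral-density estimate used downstream — is
    non-negative.  When several traces are given the per-trace estimates are
    averaged.

    Parameters
    ----------
    traces : CurrentTrace or sequence of CurrentTrace
        Trace(s) with a common sample interval.
    max_lag : float
        Largest lag, ms; must be shorter than every trace.
    """
    if isinstance(traces, CurrentTrace):
        traces = [traces]
    if not traces:
        raise ValueError("at least one trace is required")
    dt = traces[0].dt
    lag_n = int(round(max_lag / dt))
    acc = None
    for tr in traces:
        if not np.isclose(tr.dt, dt):
            raise ValueError("all traces must share the same dt")
        n = tr.values.size
        if lag_n >= n:
            raise ValueError("max_lag must be smaller than the trace duration")
        x = tr.values - tr.values.mean()
        c = signal.fftconvolve(x, x[::-1], mode="full")[n - 1 : n + lag_n] / n
        acc = c if acc is None else acc + c
    pos = acc / len(traces)
    values = np.concatenate([pos[lag_n:0:-1], pos])
    lags = np.arange(-lag_n, lag_n + 1) * dt
    return Autocorrelation(lags=lags, values=values, dt=dt)


@dataclass
class CalibrationResult:
    """Outcome of a bisection calibration.

    Attributes
    ----------
    value : float
        The calibrated parameter (i0 in pA, or sigma in pA).
    achieved : float
        Evaluator output at ``value``.
    converged : bool
        False when the iteration budget ran out; the midpoint is returned.
    n_iter : int
        Evaluator calls spent inside the loop.
    """

    value: float
    achieved: float
    converged: bool
    n_iter: int


def _bisect_monotone(
    evaluator: Callable[[float], float],
    target: float,
    bounds: tuple[float, float],
    tol: float,
    max_iter: int,
) -> CalibrationResult:
    lo, hi = float(bounds[0]), float(bounds[1])
    if not lo < hi:
        raise ValueError("bounds must satisfy lo < hi")
    f_lo = evaluator(lo)
    if abs(f_lo - target) <= tol:
        return CalibrationResult(lo, f_lo, True, 0)
    f_hi = evaluator(hi)
    if abs(f_hi - target) <= tol:
        return CalibrationResult(hi, f_hi, True, 0)
    if not (f_lo < target < f_hi):
        raise BracketingError(
            f"target {target} not bracketed by evaluator range "
            f"[{f_lo}, {f_hi}] over bounds [{lo}, {hi}]"
        )
    f_mid = np.nan
    for i in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = evaluator(mid)
        if abs(f_mid - target) <= tol:
            return CalibrationResult(mid, f_mid, True, i + 1)
        if f_mid < target:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    warnings.warn(
        f"bisection did not reach tolerance {tol} in {max_iter} iterations; "
        "returning the midpoint",
        stacklevel=3,
    )
    return CalibrationResult(mid, float(f_mid), False, max_iter)


def calibrate_dc(
    rate_evaluator: Callable[[float], float],
    target_rate: float,
    bounds: tuple[float, float],
    tol: float = 0.2,
    max_iter: int = 40,
) -> CalibrationResult:
    """Bisect the DC offset so the evaluated firing rate matches the target.

    Parameters
    ----------
    rate_evaluator : callable
        Maps i0 (pA) to a mean firing rate (spike/s); assumed monotone
        non-decreasing over ``bounds``.
    target_rate : float
        Desired mean firing rate, spike/s.
    bounds : (float, float)
        Bracketing interval for i0, pA.
    tol : float
        Acceptable |rate - target| in spike/s.
    """
    return _bisect_monotone(rate_evaluator, target_rate, bounds, tol, max_iter)


def calibrate_sigma(
    vmstd_evaluator: Callable[[float], float],
    target_std: float = 4.0,
    bounds: tuple[float, float] = (1.0, 200.0),
    tol: float = 0.1,
    max_iter: int = 40,
) -> CalibrationResult:
    """Bisect the noise amplitude for a target membrane-potential SD (mV).

    The default target of 4 mV reproduces in-vivo-like subthreshold
    fluctuations.
    """
    return _bisect_monotone(vmstd_evaluator, target_std, bounds, tol, max_iter)
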