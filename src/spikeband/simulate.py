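"""Reduced integrate-and-fire simulators and synthetic fixture generators.

The membrane equation integrated here is the exponential integrate-and-fire
(EIF) model

    tau_m dV/dt = EL - V + delta_T * exp((V - V_T) / delta_T) + R * i(t)

with ``delta_T = 0`` selecting the leaky integrate-and-fire (LIF) limit, in
which the exponential term vanishes and a spike is emitted at the V_T
crossing.  For the EIF a spike is emitted when V reaches the numerical cut
``V_spike`` (or when the exponential argument exceeds ``EXP_CAP``, whichever
comes first); the membrane is then clamped to ``V_reset`` for the absolute
refractory period.

Integration is forward Euler at the stimulus sample interval; the loop is
compiled with numba when available, with an identical pure-Python fallback.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traces import CurrentTrace, SpikeTrain, VoltageTrace

__all__ = [
    "IFModelParams",
    "EXP_CAP",
    "simulate_if",
    "step_protocol",
    "synth_classed_isi",
    "synth_voltage_trace",
    "APTemplateParams",
    "ap_template",
    "ETYPE_LABELS",
]

#: Upper bound on the EIF exponential argument (V - V_T) / delta_T.  When the
#: argument exceeds this bound the membrane is already committed to a spike
#: (the drive exceeds delta_T * e^20 ~ 5e8 mV), so a spike is emitted
#: immediately instead of evaluating the overflowing exponential.
EXP_CAP = 20.0

ETYPE_LABELS = ("cAC", "cNAC", "bNAC", "cSTUT", "cIR")


@dataclass(frozen=True)
class IFModelParams:
    """Parameters of the reduced (E)IF neuron.

    Defaults mimic the passive properties measured in layer-1 interneurons
    (R ~ 184 MOhm, tau_m ~ 36 ms) so that synthetic firing regimes resemble
    recorded ones.

    Attributes
    ----------
    tau_m : float
        Membrane time constant, ms.
    R : float
        Input resistance, MOhm.
    EL : float
        Resting potential, mV.
    V_T : float
        Threshold parameter, mV (the firing threshold in the LIF limit).
    delta_T : float
        Spike slope factor, mV; 0 selects the LIF.
    V_spike : float
        Numerical spike-cut voltage, mV (EIF only).
    V_reset : float
        Post-spike reset potential, mV.
    t_ref : float
        Absolute refractory period, ms.
    """

    tau_m: float = 36.0
    R: float = 184.0
    EL: float = -70.0
    V_T: float = -50.0
    delta_T: float = 0.0
    V_spike: float = 20.0
    V_reset: float = -60.0
    t_ref: float = 2.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.R <= 0:
            raise ValueError("R must be positive")
        if self.delta_T < 0:
            raise ValueError("delta_T must be >= 0")
        if not (self.V_reset < self.V_T < self.V_spike):
            raise ValueError("require V_reset < V_T < V_spike")
        if self.t_ref < 0:
            raise ValueError("t_ref must be >= 0")


def _integrate_py(stim, dt, tau_m, R, EL, V_T, delta_T, V_spike, V_reset,
                  ref_steps, exp_cap):
    n = stim.shape[0]
    V = np.empty(n)
    spikes = np.empty(n // (ref_steps + 1) + 1, dtype=np.int64)
    ns = 0
    if delta_T > 0.0:
        vth_eff = min(V_spike, V_T + exp_cap * delta_T)
        peak_v = V_spike
    else:
        # LIF: emission at the V_T crossing; the trace never exceeds V_T.
        vth_eff = V_T
        peak_v = V_T
    v = EL
    ref = 0
    k = 0
    while k < n:
        if ref > 0:
            V[k] = V_reset
            ref -= 1
            k += 1
            continue
        if v >= vth_eff:
            V[k] = peak_v
            spikes[ns] = k
            ns += 1
            v = V_reset
            ref = ref_steps
            k += 1
            continue
        V[k] = v
        if delta_T > 0.0:
            arg = (v - V_T) / delta_T
            if arg > exp_cap:
                arg = exp_cap
            drive = delta_T * np.exp(arg)
        else:
            drive = 0.0
        v = v + (dt / tau_m) * (EL - v + drive + 1e-3 * R * stim[k])
        k += 1
    return V, spikes[:ns]


try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _integrate = njit(cache=False)(_integrate_py)
except ImportError:  # pragma: no cover
    _integrate = _integrate_py


def simulate_if(
    params: IFModelParams, stim: CurrentTrace
) -> tuple[VoltageTrace, SpikeTrain]:
    """Integrate the (E)IF membrane equation driven by a current trace.

    Forward-Euler at the stimulus dt.  Spike times are assigned at the first
    sample where the emission criterion is met (no sub-step interpolation);
    for the EIF the voltage at that sample is set to ``V_spike`` so the
    action-potential peak is visible to downstream spike detection (for the
    LIF it is held at ``V_T``: the leaky model has no upstroke), then the
    membrane is clamped at ``V_reset`` for ``t_ref``.

    Returns
    -------
    (VoltageTrace, SpikeTrain)
        Deterministic given the stimulus.
    """
    dt = stim.dt
    ref_steps = int(round(params.t_ref / dt))
    V, spike_idx = _integrate(
        stim.values, dt, params.tau_m, params.R, params.EL, params.V_T,
        params.delta_T, params.V_spike, params.V_reset, ref_steps, EXP_CAP,
    )
    duration = stim.n_samples * dt
    return (
        VoltageTrace(dt=dt, values=V),
        SpikeTrain(times=spike_idx * dt, duration=duration),
    )


def step_protocol(
    amplitudes,
    duration: float = 1000.0,
    dt: float = 0.05,
    pre_ms: float = 0.0,
    post_ms: float = 0.0,
    baseline: float = 0.0,
) -> list[CurrentTrace]:
    """Rectangular current steps (one trace per amplitude).

    Each trace holds ``baseline`` for ``pre_ms``, the step amplitude for
    ``duration`` and ``baseline`` again for ``post_ms``.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    if not np.all(np.isfinite(amplitudes)):
        raise ValueError("amplitudes must be finite")
    n_pre = int(round(pre_ms / dt))
    n_step = int(round(duration / dt))
    n_post = int(round(post_ms / dt))
    traces = []
    for amp in amplitudes:
        vals = np.full(n_pre + n_step + n_post, baseline)
        vals[n_pre : n_pre + n_step] = amp
        traces.append(CurrentTrace(dt=dt, values=vals))
    return traces


def synth_classed_isi(
    label: str,
    base_rate: float = 20.0,
    n_isis: int = 20,
    seed: int | None = None,
) -> np.ndarray:
    """Generate an ISI sequence with the signature of one e-type class.

    The five classes follow the rule set used by the classifier:

    - ``cNAC``  flat ISIs (slope ~ 0, low jitter);
    - ``cAC``   linearly accommodating ISIs, slope > 1 ms per index;
    - ``bNAC``  1-2 initial burst ISIs < 20 ms, then a flat train;
    - ``cSTUT`` at least one pause >= 100 ms within an otherwise regular train;
    - ``cIR``   strongly jittered ISIs, all < 100 ms, with zero linear trend.

    Parameters
    ----------
    label : str
        One of cAC, cNAC, bNAC, cSTUT, cIR.
    base_rate : float
        Nominal firing rate of the train, spike/s (mean ISI = 1000/base_rate).
    """
    if label not in ETYPE_LABELS:
        raise ValueError(f"unknown e-type label {label!r}; expected one of {ETYPE_LABELS}")
    rng = np.random.default_rng(seed)
    n = int(n_isis)
    if n < 5:
        raise ValueError("n_isis must be >= 5")
    mean_isi = 1000.0 / base_rate

    if label == "cNAC":
        return mean_isi + rng.normal(0.0, 1.0, n)

    if label == "cAC":
        # Start short, accommodate by ~2 ms per interval.
        return 0.6 * mean_isi + 2.0 * np.arange(n) + rng.normal(0.0, 0.4, n)

    if label == "bNAC":
        k = int(rng.integers(1, 3))
        head = rng.uniform(8.0, 18.0, k)
        tail = mean_isi + rng.normal(0.0, 1.0, n - k)
        return np.concatenate([head, tail])

    if label == "cSTUT":
        isis = 0.8 * mean_isi + rng.normal(0.0, 1.0, n)
        n_pause = int(rng.integers(1, 3))
        pos = rng.choice(n, size=n_pause, replace=False)
        isis[pos] = rng.uniform(105.0, 150.0, n_pause)
        return isis

    # cIR: alternate short/long intervals, then remove the fitted linear
    # trend so the irregularity cannot masquerade as accommodation.
    lo = rng.uniform(25.0, 40.0, (n + 1) // 2)
    hi = rng.uniform(60.0, 90.0, n // 2)
    isis = np.empty(n)
    isis[0::2] = lo
    isis[1::2] = hi
    idx = np.arange(n, dtype=float)
    slope = np.polyfit(idx, isis, 1)[0]
    isis = isis - slope * (idx - idx.mean())
    return np.clip(isis, 22.0, 98.0)


@dataclass(frozen=True)
class APTemplateParams:
    """Stereotyped action-potential template: exponential up- and downstroke.

    The upstroke is ``amp * exp(t / tau_rise)`` for t in [-rise_ms, 0] (peak
    at t = 0), giving a phase-plane (dV/dt vs V) trajectory that is exactly a
    line of slope ``1 / tau_rise`` — the template's ground-truth onset
    rapidness.  The downstroke decays with ``tau_decay``.
    """

    amp: float = 100.0
    tau_rise: float = 0.3
    tau_decay: float = 1.5
    rise_ms: float = 3.0
    decay_ms: float = 6.0

    def __post_init__(self) -> None:
        if min(self.amp, self.tau_rise, self.tau_decay, self.rise_ms, self.decay_ms) <= 0:
            raise ValueError("all template parameters must be positive")

    @property
    def width(self) -> float:
        return self.rise_ms + self.decay_ms


def ap_template(dt: float, params: APTemplateParams | None = None) -> tuple[np.ndarray, int]:
    """Sampled AP template and the index of its peak."""
    p = params or APTemplateParams()
    t_up = np.arange(-int(round(p.rise_ms / dt)), 1) * dt
    t_down = np.arange(1, int(round(p.decay_ms / dt)) + 1) * dt
    up = p.amp * np.exp(t_up / p.tau_rise)
    down = p.amp * np.exp(-t_down / p.tau_decay)
    return np.concatenate([up, down]), t_up.size - 1


def synth_voltage_trace(
    spikes: SpikeTrain,
    waveform: APTemplateParams | None = None,
    baseline: float = -70.0,
    noise_sd: float = 0.0,
    dt: float = 0.05,
    seed: int | None = None,
) -> VoltageTrace:
    """Synthetic voltage trace: baseline + noise + an AP template per spike.

    Spike times mark template peaks.  Raises if consecutive spikes are closer
    than the template width (overlapping templates are not modelled).
    """
    p = waveform or APTemplateParams()
    if spikes.n_spikes > 1 and np.min(spikes.isis) <= p.width:
        raise ValueError(
            "spike separation must exceed the template width "
            f"({p.width} ms); overlapping templates are rejected"
        )
    n = int(round(spikes.duration / dt))
    rng = np.random.default_rng(seed)
    v = np.full(n, float(baseline))
    if noise_sd > 0:
        v += rng.normal(0.0, noise_sd, n)
    tmpl, peak_idx = ap_template(dt, p)
    for t in spikes.times:
        c = int(round(t / dt))
        a = c - peak_idx
        b = a + tmpl.size
        if a < 0 or b > n:
            raise ValueError("spike template extends outside the trace")
        v[a:b] += tmpl
    return VoltageTrace(dt=dt, values=v)
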