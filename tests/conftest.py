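import numpy as np
import pytest

import spikeband as sb


@pytest.fixture(scope="session")
def lif_params():
    """Leaky IF with interneuron-like passives (R 184 MOhm, tau_m 36 ms)."""
    return sb.IFModelParams()


@pytest.fixture(scope="session")
def eif_params():
    """Exponential IF with a physiological spike slope factor."""
    return sb.IFModelParams(delta_T=1.5, V_T=-52.0, V_spike=20.0)


def calibrate_cell(params, target_rate=5.0, tau_corr=5.0, dt=0.05, seed=0):
    """Calibrate (sigma, i0) for 4 mV voltage fluctuations at a target rate."""

    def vm_sd(s):
        cur = sb.make_ou_current(0.0, s, 10000.0, dt=dt, tau_corr=tau_corr,
                                 seed=seed + 20_000)
        v, _ = sb.simulate_if(params, cur)
        skip = int(round(200.0 / dt))
        return float(np.std(v.values[skip:]))

    sigma = sb.calibrate_sigma(vm_sd, 4.0, bounds=(1.0, 2000.0), tol=0.05).value

    def rate_of(i0):
        cur = sb.make_ou_current(i0, sigma, 20000.0, dt=dt, tau_corr=tau_corr,
                                 seed=seed + 10_000)
        _, tr = sb.simulate_if(params, cur)
        return tr.mean_rate

    i0 = sb.calibrate_dc(rate_of, target_rate, bounds=(0.0, 2000.0), tol=0.2).value
    return sigma, i0


def collect_trials(params, i0, sigma, n_spikes, trial_ms=60000.0, dt=0.05,
                   tau_corr=5.0, T=500.0, seed=100, max_trials=100):
    """Repeat 60-s OU trials until `n_spikes` usable (edge-safe) spikes."""
    trials, usable, k = [], 0, 0
    while usable < n_spikes and k < max_trials:
        cur = sb.make_ou_current(i0, sigma, trial_ms, dt=dt, tau_corr=tau_corr,
                                 seed=seed + k)
        _, tr = sb.simulate_if(params, cur)
        trials.append((cur, tr))
        usable += int(np.count_nonzero(
            (tr.times >= T) & (tr.times < trial_ms - T)))
        k += 1
    return trials, usable


@pytest.fixture(scope="session")
def lif_trials_small(lif_params):
    """~1200 usable spikes of a calibrated LIF at ~5 spike/s (fast tier)."""
    sigma, i0 = calibrate_cell(lif_params, target_rate=5.0, seed=0)
    trials, usable = collect_trials(lif_params, i0, sigma, 1200, seed=100)
    return {"trials": trials, "usable": usable, "sigma": sigma, "i0": i0}
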