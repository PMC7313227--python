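# spikeband

Spike-initiation bandwidth analysis for current-clamp electrophysiology.

Cortical neurons do not relay every temporal component of their synaptic
input: the spike-initiation mechanism acts as a filter whose bandwidth can
be measured by driving the cell with an in-vivo-like fluctuating current and
reading out, in the Fourier domain, how strongly each input frequency
modulates the output firing. `spikeband` implements that measurement chain
— the protocol used to characterize layer-1 cortical interneurons and, more
broadly, any cell probed in current clamp with colored-noise stimuli — as a
tested, reusable Python library, together with the reduced
integrate-and-fire simulators needed to validate every stage end-to-end on
synthetic data with known ground truth.

## What it computes

**Stimulus.** The injected current is `i(t) = i0 + σ·η(t)` with `η` a
zero-mean, unit-variance Ornstein–Uhlenbeck process of correlation time
`τ = 5 ms`, generated by the exact update
`η[k+1] = η[k]·e^(−dt/τ) + √(1−e^(−2dt/τ))·ξ[k]`. Bisection calibrators set
`σ` (target membrane-potential SD, 4 mV) and `i0` (target mean rate).

**Transfer function.** From the spike times `t_k`, the spike-triggered
average of the stimulus,

    sta(t) = ⟨ i(t_k − t) ⟩,   t ∈ [−T, T],  T = 500 ms,

is Fourier-transformed and divided by the stimulus power spectral density
(the transform of the sample autocorrelation `iac(τ)`):

    H(f) = STA(f) / PSD(f).

`|H(f)|` is read like an electronic filter: significance is assessed
against 500 surrogate spike trains with shuffled inter-spike intervals
(threshold = surrogate mean + SD); the **cut-off frequency** is where `|H|`
falls to 70% of its value at 1 cycle/s; above the cut-off the decay is fit
as a power law `b·f^−α`, whose exponent distinguishes spike-initiation
dynamics (α ≈ 0.5 for leaky integrate-and-fire under white noise, α ≈ 1
for exponential spike initiation).

**Cell characterization.** Passive properties (input resistance from
hyperpolarizing steps, membrane time constant from a bi-exponential
recovery fit, capacitance `C = τ_m/R_in`); electrical-phenotype
classification (cAC / cNAC / bNAC / cSTUT / cIR) from the inter-spike
interval pattern of a ~20 spike/s step response; AP waveform quantification
(threshold at dV/dt = 20 mV/ms, phase-plane onset rapidness, and the spike
slope factor Δ_T from a dynamic I–V fit).

**Synthetic ground truth.** Leaky (LIF) and exponential (EIF)
integrate-and-fire simulators — `τ_m dV/dt = EL − V + Δ_T·e^((V−V_T)/Δ_T) +
R·i(t)` — with interneuron-like passives (R ≈ 184 MΩ, τ_m ≈ 36 ms), plus
generators for labelled ISI patterns and templated voltage traces, drive
every recovery test.

## Worked example

Calibrate a leaky integrate-and-fire cell to the standard conditions
(4 mV voltage fluctuations, ~5 spike/s), run six 60-s trials and fit the
transfer function:

```python
import numpy as np
import spikeband as sb

lif = sb.IFModelParams()          # tau_m 36 ms, R 184 MOhm, leaky limit

def vm_sd(sigma):
    cur = sb.make_ou_current(0.0, sigma, 10_000.0, seed=20_000)
    v, _ = sb.simulate_if(lif, cur)
    return float(np.std(v.values[4000:]))

sigma = sb.calibrate_sigma(vm_sd, target_std=4.0).value

def rate_of(i0):
    cur = sb.make_ou_current(i0, sigma, 20_000.0, seed=10_000)
    _, train = sb.simulate_if(lif, cur)
    return train.mean_rate

i0 = sb.calibrate_dc(rate_of, target_rate=5.0, bounds=(0.0, 600.0)).value

trials = []
for k in range(6):                 # six 60-s presentations
    cur = sb.make_ou_current(i0, sigma, 60_000.0, seed=k)
    _, train = sb.simulate_if(lif, cur)
    trials.append((cur, train))

res = sb.TransferFunctionModel(trials, T=500.0).fit(n_surrogates=200, seed=1)
print(res.summary())
```

Output:

```
Dynamical transfer function
==========================================
trials                                   6
spikes used (STA)                     1970
mean rate (spike/s)                  5.586
ISI CV                               0.867
|H| at 1 cycle/s                   0.05044
cut-off (cycle/s)                    12.64
power-law alpha                      0.128
power-law prefactor b              0.04246
fit range (cycle/s)            12.6-167.9
==========================================
```

The cell fires irregularly at ~5.6 spike/s (ISI CV 0.87); its encoding
bandwidth (cut-off) is ~13 cycle/s, and above the cut-off the response
magnitude decays with a shallow exponent — the leaky model transmits fast
components of a 5-ms-correlated stimulus more effectively than its
white-noise theory (α = 0.5) suggests; see `docs/methods.md` for why. The
`TransferFunctionResults` object also carries the full STA, the raw and
smoothed `|H(f)|` curves with their significance threshold, and
`to_summary()` for serialization (`spikeband.io`).

Population-level studies (cohorts of simulated cells across firing
regimes, with Pearson and Kruskal–Wallis reports) are driven by
`spikeband.population.run_population_study`; see
`make_lif_population` for a ready-made cohort.

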