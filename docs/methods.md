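# Methods

This note documents the models, estimators and numerical choices behind
`spikeband`, in the spirit of a methods appendix: what is computed, under
which assumptions, with which defaults, and where the genuinely open design
choices were resolved.

## Stimulus model

The injected current is `i(t) = i0 + σ·η(t)` with `η` a stationary
Ornstein–Uhlenbeck (OU) process: zero mean, unit variance, exponential
autocorrelation `e^(−|τ|/τ_corr)` with `τ_corr = 5 ms` by default. The
discrete update is exact at any step size,

    η[k+1] = a·η[k] + √(1 − a²)·ξ[k],   a = e^(−dt/τ_corr),

and `η[0]` is drawn from the stationary distribution, so no burn-in is
discarded. One root seed determines the realization bit-exactly;
experiment drivers derive per-trial streams as `seed + trial_index` and
keep calibration streams on disjoint offsets (`seed + 10000` for the rate
evaluator, `+20000` for the fluctuation evaluator, `+30000` for the
surrogate RNG). A warning is emitted when `dt > τ_corr/5`, where the
discrete process resolves the correlation structure poorly.

Calibration is plain bisection on a monotone evaluator: `σ` targets a
membrane-potential SD of 4 mV (in-vivo-like fluctuations, evaluated on a
10-s zero-DC simulation with the first 200 ms discarded), `i0` targets the
mean firing rate (evaluated on a 20-s simulation, tolerance 0.2 spike/s).
Both return the achieved value, an iteration count and a convergence flag;
exhausting the budget returns the midpoint with a warning rather than
failing. Whether σ is tuned closed-loop or once per cell is left to the
caller — the evaluator abstraction supports both.

## Reduced neuron models

The synthetic data source is the exponential integrate-and-fire membrane

    τ_m dV/dt = EL − V + Δ_T·exp((V − V_T)/Δ_T) + R·i(t),

integrated by forward Euler at the stimulus step (default dt = 0.05 ms,
i.e. 20 kHz; recordings this package targets are sampled at 20–30 kHz).
`Δ_T = 0` selects the leaky (LIF) limit, where the exponential term is
absent and a spike is emitted at the first sample with `V ≥ V_T`; the
recorded voltage at that sample stays at `V_T` (the leaky model has no
upstroke). For `Δ_T > 0` a spike is emitted when `V` reaches the numerical
cut `V_spike` or when the exponential argument `(V − V_T)/Δ_T` exceeds 20
— beyond that bound the membrane is committed to a spike and evaluating
the exponential would overflow — and the spike sample is set to `V_spike`
so downstream peak detection sees the AP. After a spike the membrane is
clamped to `V_reset` for the absolute refractory period. Spike times are
assigned at the emitting sample without sub-step interpolation.

Default parameters mimic the passive properties measured in layer-1
interneurons (R = 184 MΩ, τ_m = 36 ms, EL = −70 mV, V_T = −50 mV,
V_reset = −60 mV, t_ref = 2 ms), so calibrated firing regimes resemble the
recorded ones. The Euler scheme is first-order: the steady-state ISI error
under constant drive shrinks linearly with dt (tested), and the rate
matches the LIF closed form `1000/(t_ref + τ_m·ln((μ−V_reset)/(μ−V_T)))`
within 1% at dt = 0.01 ms.

Convergence of the EIF to the LIF as `Δ_T → 0` holds in the following
operational sense (tested at Δ_T = 0.01 mV): subthreshold trajectories
agree to machine precision (the exponential underflows to zero away from
threshold), and under strong drive spike counts match with per-interval
differences below 0.5 ms. Absolute spike times drift apart over long runs
because the effective EIF threshold sits ~`Δ_T·ln(...)` above `V_T`, a
per-spike delay that accumulates; asserting long-horizon sample-level
trajectory identity would therefore test the wrong thing.

## Spike-triggered average and transfer function

With spike times `t_k` pooled over trials, the STA is the mean of
`i(t_k − t)` over `t ∈ [−T, T]`, `T = 500 ms`; positive lag means current
*preceding* the spike. Spikes whose window crosses a trial boundary are
excluded. The estimator is checked against a naive per-spike loop to
machine precision.

The transfer function is the ratio of discrete Fourier transforms

    H(f) = STA(f) / PSD(f),

where the PSD is the transform of the biased (1/n), per-trace
mean-subtracted sample autocorrelation of the current, averaged over
trials and truncated to the same `[−T, T]` grid. The biased normalisation
keeps the spectrum non-negative; the STA is mean-centred before
transforming. Mean subtraction and centring only alter the zero-frequency
bin, which is dropped everywhere. PSD bins below `10⁻¹²` of the spectral
maximum are masked rather than divided. With dt = 0.05 ms and T = 500 ms
the frequency grid runs from ~1 Hz (resolution ~1 Hz) to 10 kHz.

Magnitude summaries operate on a geometrically smoothed curve (20 bins per
decade, bin value = mean `|H|`, bin centre = geometric mean frequency):
raw single-bin magnitude estimates are far too noisy for a stable 70%
crossing. The cut-off is the first log-log-interpolated crossing of
`0.7 × |H(1 Hz)|` (the "falls to 70% of the 1-Hz value" reading, ≈ −3 dB;
the alternative "70% *decrease*" reading is available as
`cutoff_frequency(..., fraction=0.3)`). The power law `b·f^−α` is fit by
least squares on `log|H|` vs `log f` from the cut-off to the first
frequency where `|H| ≤ 0.2 × |H(f_cut)|`, or the last significant bin if
that floor is never reached. All summaries are ratios of magnitudes, so
they are invariant under rescaling the current (tested), and the absolute
units of `H` (pA⁻¹ under the definition above) never enter.

### Surrogate significance

Significance of `|H|` is assessed against 500 surrogate spike trains:
within each trial the inter-spike intervals are randomly permuted (first
spike time and spike count preserved — shuffling is within-trial, since
pooling intervals across trials would mix stimulus realizations) and the
full STA → `|H|` analysis is repeated against the same currents. The
threshold is the surrogate mean plus one surrogate standard deviation per
frequency. Note what this band is: roughly the 84th percentile of the
null pointwise, not a 5% band — for a spike train truly independent of
the current, the *raw-grid* `|H|` falls below it at ~84% of frequencies
(the Rayleigh-statistics expectation, confirmed numerically). All
significance gating in the pipeline happens after geometric smoothing,
where averaging suppresses the null fluctuations while the threshold
keeps its raw mean+SD level; on that operative comparison an independent
train is non-significant at ≥ 90% of bins, and the comparison is
conservative for the band edges reported.

### The leaky-model exponent under colored noise

The high-frequency exponent is the package's headline diagnostic: white
-noise theory assigns α = 0.5 to the leaky model and α ≈ 1 to exponential
spike initiation. The pipeline reproduces the theory value in the regime
the theory describes — driving the default LIF with near-white noise
(τ_corr = 0.2 ms) yields α ≈ 0.54. Under the standard stimulus, however
(τ_corr = 5 ms, 4 mV fluctuations, ~5 spike/s), the measured `|H|` of the
LIF decays only between ~1 and ~50 Hz and then *plateaus* at 40–50% of
its cut-off value: a leaky integrator driven by low-pass-filtered noise
retains a finite instantaneous rate response at arbitrarily high
frequency. The plateau is signal, not estimation noise — it is unchanged
when the spike count is quadrupled while the surrogate floor drops
twofold. The power-law fit across that plateau gives α ≈ 0.15–0.2,
robust to threshold, reset and refractory choices. An EIF with
Δ_T = 1.5 mV under identical conditions gives α ≈ 0.58 > α(LIF), as the
spike-initiation filter theory orders them. Consequence: the value 0.5
should not be expected from a LIF under a 5-ms-correlated stimulus, and
the end-to-end LIF check in the test suite that asserts the white-noise
band [0.35, 0.65] fails by design of the physics, not of the code.

## Passive properties and AP waveform

- **Input resistance**: least-squares slope of steady-state V vs I over
  hyperpolarizing 1-s steps (−200…−50 pA); steady state = mean over the
  last 200 ms of each step. 1 mV/pA = 1000 MΩ.
- **Membrane time constant**: slowest component of a bi-exponential fit to
  the relaxation after a 10-ms, −150 pA pulse. Components carrying < 5% of
  the total amplitude are ignored when selecting the slowest (a
  bi-exponential fitted to single-exponential data otherwise reports a
  spurious near-zero-weight slow term); a failed fit falls back to a
  single exponential with a warning.
- **Capacitance**: `C = τ_m / R_in`, reported in nF (ms/MΩ); `c_m_pf`
  converts. On simulated LIF data the chained estimators recover R and τ_m
  within 5% and C within 7%.
- **Spike detection**: local maxima after upward crossings of 0 mV, maxima
  closer than 2 ms merged to the larger peak.
- **AP average**: peak-aligned mean over (−5, +5) ms windows; truncated
  windows excluded.
- **Threshold**: voltage at the first upstroke sample where the
  centered-difference dV/dt reaches 20 mV/ms, linearly interpolated
  between flanking samples.
- **Onset rapidness**: slope of a local least-squares line through the
  phase-plane (dV/dt vs V) upstroke points within ±2 mV of threshold; a
  two-point difference would be noise-dominated. Fewer than 3 points is an
  error; a point cloud spanning < 0.5 mV (near-vertical trajectory) is
  flagged unreliable. Sharp EIF upstrokes need ≥ 20 kHz effective
  sampling for a stable estimate; at dt = 0.01 ms the estimate agrees with
  a dt = 0.001 ms oracle within 15%.

### Dynamic I–V fit

The transmembrane current is estimated per sample as `I_m = i − C·dV/dt`
(C in pF) and the free membrane function `F(V) = −I_m/C` is binned by
voltage (1-mV bins, ≥ 50 samples per bin, ≥ 8 bins required) and fitted
with the EIF form `F(V) = (EL − V + Δ_T·e^((V−V_T)/Δ_T))/τ_m`, bins
weighted by `√count`. Samples around each spike are excluded from 1.5 ms
before the peak until the voltage first returns below the trace median,
plus 10 ms. The capacitance is taken from the passive-property chain
rather than re-estimated by variance minimization — a deliberate
simplification of the full dynamic-IV methodology, acceptable here
because C enters only through `i/C`.

Two numerical choices matter. First, dV/dt inside this fit is the
*forward* difference paired with `i[n]` at `V[n]`: a centered difference
mixes the previous step's drive into the estimate, which correlates with
the voltage and biases the bin means enough to bend a perfectly linear
(leaky) I–V curve. Second, Δ_T is only reported when the exponential
earns its keep: on data with no exponential component the EIF model is
degenerate (a large Δ_T mimics a straight line), so if the four-parameter
fit fails to improve the weighted SSR of a plain linear fit by more than
5%, Δ_T is pinned at the lower bound (0.02 mV) and flagged. On simulated
EIF data the fit recovers Δ_T ∈ {0.5, 1, 2} mV within 20% (typically
≤ 5%) from 60 s of data; on LIF data it pins and flags. Adding a constant
to the voltage shifts `V_T` by that constant and leaves Δ_T, τ_m and the
onset rapidness unchanged, as it must.

## E-type classification

The reference train is the 1-s step response whose mean rate is nearest
20 spike/s (ties to the lower amplitude; ≥ 3 spikes required). Classes
are assigned by rule precedence — structural single-interval criteria
before global-trend criteria, so that one qualifying pause cannot be
absorbed into a slope:

1. **cSTUT** if any ISI ≥ 100 ms;
2. **bNAC** if the leading 1–2 ISIs are < 20 ms and the remainder is
   non-accommodating (|slope| < 1 ms per interval index);
3. **cAC** if the overall ISI slope exceeds 1 ms per index;
4. **cIR** if the coefficient of variation of the linearly detrended ISIs
   exceeds 0.25 (irregularity needs a numeric criterion; detrending keeps
   accommodation from inflating it);
5. **cNAC** otherwise.

Slopes are per interval index (units: ms, matching the 1-ms criterion);
the 20-ms and 100-ms thresholds are absolute, not scale-free — boundary
fixtures (99.9 vs 100.0 ms; 19.9 vs 20.1 ms) pin the conventions. Every
result carries the full diagnostics (slope, max ISI, leading ISIs,
irregularity) so alternative precedence orders can be audited. The
synthetic ISI generators emit sequences that the classifier maps back to
their generating label exactly (500/500 across seeds); the cIR generator
detrends its jitter explicitly so irregularity cannot leak into the
accommodation rule.

## Population studies

`run_cell_pipeline` chains all stages per cell — passive protocol, f–I
curve and classification, σ/i0 calibration, transfer-function fit,
waveform and dynamic-IV analysis — into a flat record; a failing stage
flags its fields and leaves a note instead of aborting (a LIF cell, for
instance, has no detectable AP peaks, so waveform fields are None by
construction). Records are deterministic given the config and seed; a
cohort run re-serializes byte-identically. Population analyses report
Pearson correlations (rate vs cut-off, rapidness vs cut-off, Δ_T vs
cut-off; undefined per-cell values excluded pairwise) with two-sided
t-distribution p-values, and a Kruskal–Wallis comparison of cut-off
frequencies across e-type labels at the 1% level (no multiple-testing
correction is applied). Identical observations across all groups carry no
rank information and return H = 0, p = 1. Across a 10-cell LIF cohort
spanning 3–7 spike/s the rate–cut-off correlation is strongly positive
(ρ ≈ 0.87 at the test's problem size), matching the theoretical
expectation that bandwidth widens with firing rate.

## What the synthetic data does and does not show

The generators emulate: OU-driven irregular firing at 3–7 spike/s
(emergent ISI CV ≈ 0.8–0.95 for the default LIF at 4 mV fluctuations),
1-s step trains near 20 spike/s with the five labelled ISI signatures,
and spike waveforms with a definable threshold knee and exponential
upstroke. They do not emulate adaptation currents, stochastic channel
gating, dendritic filtering or electrode artifacts; recorded interneurons
fire less irregularly (CV ≈ 0.5) than a memoryless LIF in the same
regime. Passing recovery tests therefore demonstrates correctness of the
estimators under the stated model class, not robustness to every
biological confound.

## Problem sizes and runtime defaults

Full-protocol defaults are 60-s trials accumulated to ≥ 5,000 usable
spikes with 500 surrogates. The test suite exercises scaled versions
chosen for quick iteration — ~1,200 usable spikes for the shared LIF
fixture, 2,000 spikes and 60 surrogates per cell in the 10-cell population
test, 300–800 spikes in the pipeline unit tests — and states each size
where it is used; the full-size end-to-end runs live in the acceptance
tests and in `scripts/acceptance.py` (about one minute on one CPU).
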