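"""Population-level statistics and pipeline orchestration.

Chains stimulus generation, integrate-and-fire simulation, passive-property
estimation, e-type classification, waveform quantification and transfer
function analysis into per-cell records, and runs the population analyses
(rate vs cut-off correlation, per-class comparisons, power-law-exponent
distribution) on synthetic cell cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sstats

from . import waveform as wf
from .etype import classify, fi_curve, select_reference_train
from .simulate import IFModelParams, simulate_if, step_protocol
from .stimulus import (
    CalibrationResult,
    calibrate_dc,
    calibrate_sigma,
    make_ou_current,
)
from .transfer import TransferFunctionModel, TransferFunctionResults

__all__ = [
    "CellConfig",
    "CellRecord",
    "StudyResult",
    "pearson_corr",
    "kruskal_wallis",
    "run_cell_pipeline",
    "run_population_study",
    "make_lif_population",
]


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson correlation with a two-sided t-distribution p-value (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-d arrays with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    r = sstats.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis rank test across groups (tie-corrected H, chi2 p).

    All-identical observations across groups carry no rank information; that
    degenerate case returns (0.0, 1.0).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.size < 2:
            raise ValueError("each group needs at least 2 observations")
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0
    h, p = sstats.kruskal(*groups)
    return float(h), float(p)


@dataclass(frozen=True)
class CellConfig:
    """Study conditions for one synthetic cell.

    Defaults are the full protocol: 60-s trials repeated until at least
    5,000 usable spikes, noise correlation time 5 ms, noise amplitude
    calibrated to 4 mV membrane-potential SD, DC calibrated by bisection to
    the target rate, T = 500 ms, 500 surrogates.
    """

    cell_id: str
    model: IFModelParams = field(default_factory=IFModelParams)
    seed: int = 0
    dt: float = 0.05
    tau_corr: float = 5.0
    target_rate: float = 5.0
    sigma: float | None = None
    vm_std_target: float = 4.0
    sigma_bounds: tuple[float, float] = (1.0, 300.0)
    i0_bounds: tuple[float, float] = (0.0, 600.0)
    rate_tol: float = 0.2
    n_spikes_min: int = 5000
    trial_duration: float = 60000.0
    max_trials: int = 80
    calib_duration: float = 20000.0
    T: float = 500.0
    n_surrogates: int = 500
    bins_per_decade: int = 20
    step_amplitudes: tuple[float, ...] = tuple(float(a) for a in range(0, 301, 25))
    step_dt: float = 0.05


@dataclass
class CellRecord:
    """Per-cell observables; fields are None when a stage failed (see notes)."""

    cell_id: str
    label: str | None = None
    r_in: float | None = None
    tau_m: float | None = None
    c_m: float | None = None
    v_threshold: float | None = None
    onset_rapidness: float | None = None
    delta_T_fit: float | None = None
    mean_rate: float | None = None
    isi_cv: float | None = None
    f_cut: float | None = None
    alpha: float | None = None
    sigma: float | None = None
    i0: float | None = None
    n_spikes: int | None = None
    notes: dict = field(default_factory=dict)
    intermediates: dict = field(default_factory=dict)


def _passive_stage(cfg: CellConfig, rec: CellRecord) -> None:
    steady_window = 200.0  # ms; steady-state = mean over the last 200 ms
    pts = []
    for amp in (-200.0, -150.0, -100.0, -50.0):
        stim = step_protocol([amp], duration=1000.0, dt=cfg.step_dt)[0]
        v, _ = simulate_if(cfg.model, stim)
        n_tail = int(round(steady_window / cfg.step_dt))
        pts.append((amp, v.values[-n_tail:].mean()))
    rec.r_in = wf.input_resistance(pts)

    stim = step_protocol([-150.0], duration=10.0, dt=cfg.step_dt, post_ms=400.0)[0]
    v, _ = simulate_if(cfg.model, stim)
    n_pulse = int(round(10.0 / cfg.step_dt))
    recovery = wf.VoltageTrace(dt=cfg.step_dt, values=v.values[n_pulse:])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rec.tau_m = wf.membrane_time_constant(recovery)
    rec.c_m = wf.capacitance(rec.r_in, rec.tau_m)


def _etype_stage(cfg: CellConfig, rec: CellRecord) -> None:
    responses = []
    for amp, stim in zip(cfg.step_amplitudes,
                         step_protocol(cfg.step_amplitudes, duration=1000.0,
                                       dt=cfg.step_dt)):
        _, train = simulate_if(cfg.model, stim)
        responses.append((amp, train))
    rec.intermediates["fi_curve"] = fi_curve(responses)
    ref = select_reference_train(responses, target=20.0)
    res = classify(ref)
    rec.label = res.label
    rec.intermediates["etype"] = res


def _transfer_stage(cfg: CellConfig, rec: CellRecord) -> TransferFunctionResults | None:
    if cfg.sigma is not None:
        sigma = float(cfg.sigma)
    else:
        def vm_sd(s: float) -> float:
            cur = make_ou_current(0.0, s, 10000.0, dt=cfg.dt,
                                  tau_corr=cfg.tau_corr, seed=cfg.seed + 20_000)
            v, _ = simulate_if(cfg.model, cur)
            skip = int(round(200.0 / cfg.dt))
            return float(np.std(v.values[skip:]))

        sigma = calibrate_sigma(vm_sd, cfg.vm_std_target,
                                bounds=cfg.sigma_bounds, tol=0.05).value
    rec.sigma = sigma

    def rate_of(i0: float) -> float:
        cur = make_ou_current(i0, sigma, cfg.calib_duration, dt=cfg.dt,
                              tau_corr=cfg.tau_corr, seed=cfg.seed + 10_000)
        _, train = simulate_if(cfg.model, cur)
        return train.mean_rate

    cal: CalibrationResult = calibrate_dc(rate_of, cfg.target_rate,
                                          bounds=cfg.i0_bounds, tol=cfg.rate_tol)
    rec.i0 = cal.value

    trials = []
    usable = 0
    for k in range(cfg.max_trials):
        cur = make_ou_current(cal.value, sigma, cfg.trial_duration, dt=cfg.dt,
                              tau_corr=cfg.tau_corr, seed=cfg.seed + k)
        v, train = simulate_if(cfg.model, cur)
        trials.append((cur, train))
        if k == 0:
            rec.intermediates["first_trial"] = (cur, v, train)
        edge = train.times[(train.times >= cfg.T)
                           & (train.times < cfg.trial_duration - cfg.T)]
        usable += edge.size
        if usable >= cfg.n_spikes_min:
            break
    rec.n_spikes = usable
    if usable < 10:
        rec.notes["transfer"] = "too few spikes for a transfer-function estimate"
        return None
    model = TransferFunctionModel(trials, T=cfg.T)
    res = model.fit(n_surrogates=cfg.n_surrogates, seed=cfg.seed + 30_000,
                    bins_per_decade=cfg.bins_per_decade)
    rec.mean_rate = res.mean_rate
    rec.isi_cv = res.isi_cv
    rec.f_cut = res.f_cut if res.cutoff.defined else None
    if not res.cutoff.defined:
        rec.notes["f_cut"] = res.cutoff.reason
    rec.alpha = res.alpha if res.powerlaw is not None else None
    if res.powerlaw is None and res.powerlaw_error:
        rec.notes["alpha"] = res.powerlaw_error
    rec.intermediates["transfer"] = res
    return res


def _waveform_stage(cfg: CellConfig, rec: CellRecord) -> None:
    first = rec.intermediates.get("first_trial")
    if first is None:
        rec.notes["waveform"] = "no voltage trace available"
        return
    cur, v, train = first
    detected = wf.detect_spikes(v)
    if detected.n_spikes == 0:
        rec.notes["waveform"] = ("no suprathreshold AP peaks (expected for the "
                                 "leaky IF, whose voltage is cut at threshold)")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ap = wf.average_ap(v, detected)
        rec.v_threshold = ap.v_threshold
        rec.onset_rapidness = ap.onset_rapidness
        rec.intermediates["ap_waveform"] = ap
    if rec.c_m is None:
        rec.notes["delta_T"] = "no capacitance estimate for the dynamic I-V fit"
        return
    try:
        fit = wf.dynamic_iv(v, cur, C=rec.c_m * 1000.0, spikes=train)
        rec.delta_T_fit = fit.delta_T_fit if not fit.at_lower_bound else None
        if fit.at_lower_bound:
            rec.notes["delta_T"] = "delta_T pinned at the lower fit bound"
        rec.intermediates["dynamic_iv"] = fit
    except ValueError as e:
        rec.notes["delta_T"] = str(e)


def run_cell_pipeline(cfg: CellConfig) -> CellRecord:
    """Run the full per-cell protocol; failures flag fields, never abort."""
    rec = CellRecord(cell_id=cfg.cell_id)
    for name, stage in (("passive", _passive_stage), ("etype", _etype_stage)):
        try:
            stage(cfg, rec)
        except (ValueError, RuntimeError) as e:
            rec.notes[name] = str(e)
    try:
        _transfer_stage(cfg, rec)
    except (ValueError, RuntimeError) as e:
        rec.notes["transfer"] = str(e)
    try:
        _waveform_stage(cfg, rec)
    except (ValueError, RuntimeError) as e:
        rec.notes["waveform"] = str(e)
    return rec


_TABLE_COLUMNS = [
    "cell_id", "label", "r_in", "tau_m", "c_m", "v_threshold",
    "onset_rapidness", "delta_T_fit", "mean_rate", "isi_cv", "f_cut",
    "alpha", "sigma", "i0", "n_spikes",
]


@dataclass
class StudyResult:
    """Population study output: per-cell table plus the analysis report."""

    table: pd.DataFrame
    records: list[CellRecord]
    report: dict


def _pairwise_corr(table: pd.DataFrame, xcol: str, ycol: str):
    sub = table[[xcol, ycol]].dropna()
    if len(sub) < 3:
        return None
    rho, p = pearson_corr(sub[xcol].to_numpy(), sub[ycol].to_numpy())
    return {"rho": rho, "p": p, "n": int(len(sub))}


def run_population_study(configs, alpha_level: float = 0.01) -> StudyResult:
    """Run the per-cell pipeline over a cohort and the population analyses.

    Reports the rate-vs-cut-off, rapidness-vs-cut-off and delta_T-vs-cut-off
    Pearson correlations (undefined per-cell values excluded pairwise), the
    Kruskal-Wallis comparison of cut-off frequencies across e-type labels at
    the 1% significance level, and the distribution of the power-law
    exponent.  Deterministic given the per-cell seeds.
    """
    records = [run_cell_pipeline(cfg) for cfg in configs]
    ids = [r.cell_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("cell_ids must be unique")
    table = pd.DataFrame(
        [{c: getattr(r, c) for c in _TABLE_COLUMNS} for r in records],
        columns=_TABLE_COLUMNS,
    )
    report: dict = {
        "n_cells": len(records),
        "rate_vs_fcut": _pairwise_corr(table, "mean_rate", "f_cut"),
        "rapidness_vs_fcut": _pairwise_corr(table, "onset_rapidness", "f_cut"),
        "deltaT_vs_fcut": _pairwise_corr(table, "delta_T_fit", "f_cut"),
        "alpha_values": [a for a in table["alpha"] if a is not None and np.isfinite(a)],
        "fcut_values": [f for f in table["f_cut"] if f is not None and np.isfinite(f)],
    }
    groups = []
    for _, sub in table.dropna(subset=["label", "f_cut"]).groupby("label"):
        if len(sub) >= 2:
            groups.append(sub["f_cut"].to_numpy())
    if len(groups) >= 2:
        h, p = kruskal_wallis(groups)
        report["fcut_by_etype"] = {
            "H": h, "p": p, "reject_at_1pct": bool(p < alpha_level),
        }
    else:
        report["fcut_by_etype"] = None
    return StudyResult(table=table, records=records, report=report)


def make_lif_population(
    n_cells: int = 10,
    rate_range: tuple[float, float] = (3.0, 7.0),
    seed: int = 0,
    base_model: IFModelParams | None = None,
    **config_overrides,
) -> list[CellConfig]:
    """Cohort of LIF cells with target rates spanning ``rate_range``.

    Thresholds are jittered slightly across cells so the cohort is not a
    single repeated neuron; per-cell seeds derive from the root seed.
    """
    base = base_model or IFModelParams()
    rng = np.random.default_rng(seed)
    rates = np.linspace(rate_range[0], rate_range[1], n_cells)
    configs = []
    for j, rate in enumerate(rates):
        model = replace(base, V_T=base.V_T + float(rng.uniform(-1.0, 1.0)))
        configs.append(
            CellConfig(
                cell_id=f"lif{j:02d}",
                model=model,
                seed=seed + 1000 * (j + 1),
                target_rate=float(rate),
                **config_overrides,
            )
        )
    return configs
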