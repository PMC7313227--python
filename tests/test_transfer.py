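"""Spike-triggered average, transfer function, cut-off and power law."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spikeband as sb
from spikeband.stimulus import autocorrelation
from spikeband.transfer import (
    STAResult,
    TransferFunction,
    compute_sta,
    cutoff_frequency,
    estimate_transfer,
    powerlaw_fit,
    smooth_transfer,
    surrogate_threshold,
)


def naive_sta(cur, train, T):
    """Brute-force per-spike loop oracle for the STA."""
    nT = int(round(T / cur.dt))
    windows = []
    for t in train.times:
        j = int(round(t / cur.dt))
        if j - nT >= 0 and j + nT < cur.values.size:
            windows.append([cur.values[j - lag] for lag in range(-nT, nT + 1)])
    return np.mean(windows, axis=0)


class TestComputeSTA:
    def test_single_spike_is_the_reversed_stimulus_window(self):
        vals = np.random.default_rng(0).normal(0, 1, 1200)
        cur = sb.CurrentTrace(dt=1.0, values=vals)
        train = sb.SpikeTrain(times=np.array([600.0]), duration=1200.0)
        sta = compute_sta([(cur, train)], T=500.0)
        np.testing.assert_array_equal(sta.values, vals[100:1101][::-1])
        assert sta.lags[0] == -500.0 and sta.lags[-1] == 500.0

    def test_two_spikes_mean_matches_brute_force(self):
        vals = np.random.default_rng(1).normal(0, 1, 400)
        cur = sb.CurrentTrace(dt=1.0, values=vals)
        train = sb.SpikeTrain(times=np.array([120.0, 260.0]), duration=400.0)
        sta = compute_sta([(cur, train)], T=50.0)
        np.testing.assert_allclose(sta.values, naive_sta(cur, train, 50.0),
                                   rtol=0, atol=1e-12)

    @given(st.integers(0, 2**31 - 1), st.integers(2, 50))
    @settings(max_examples=40, deadline=None)
    def test_oracle_equivalence_on_random_instances(self, seed, n_spikes):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 1, 500)
        cur = sb.CurrentTrace(dt=1.0, values=vals)
        times = np.sort(rng.choice(np.arange(500), n_spikes, replace=False))
        train = sb.SpikeTrain(times=times.astype(float), duration=500.0)
        try:
            sta = compute_sta([(cur, train)], T=40.0)
        except ValueError:
            # all spikes too close to the edges: the oracle has no windows either
            assert not [t for t in times if 40 <= t < 460]
            return
        np.testing.assert_allclose(sta.values, naive_sta(cur, train, 40.0),
                                   rtol=0, atol=1e-12)

    def test_edge_spikes_are_excluded(self):
        cur = sb.CurrentTrace(dt=1.0, values=np.arange(1200.0))
        train = sb.SpikeTrain(times=np.array([10.0, 600.0, 1150.0]),
                              duration=1200.0)
        sta = compute_sta([(cur, train)], T=500.0)
        assert sta.n_spikes_used == 1

    def test_no_usable_spikes_raises(self):
        cur = sb.CurrentTrace(dt=1.0, values=np.zeros(1100))
        train = sb.SpikeTrain(times=np.array([5.0]), duration=1100.0)
        with pytest.raises(ValueError, match="window"):
            compute_sta([(cur, train)], T=500.0)

    def test_independent_poisson_train_gives_flat_sta(self):
        """Spikes independent of the current: sta ~ i0 at every lag."""
        cur = sb.make_ou_current(100.0, 30.0, 120_000.0, dt=0.5, seed=6)
        rng = np.random.default_rng(7)
        t = np.cumsum(rng.exponential(100.0, 2000))
        t = t[t < 119_999.0]
        train = sb.SpikeTrain(times=t, duration=120_000.0)
        sta = compute_sta([(cur, train)], T=500.0)
        se = 30.0 / np.sqrt(sta.n_spikes_used)
        assert np.max(np.abs(sta.values - 100.0)) < 6 * se


class TestEstimateTransfer:
    def _iac(self, seed=2):
        cur = sb.make_ou_current(0.0, 1.0, 20000.0, dt=0.5, seed=seed)
        return autocorrelation(cur, 100.0)

    def test_identity_ratio_is_one_everywhere(self):
        iac = self._iac()
        sta = STAResult(lags=iac.lags, values=iac.values.copy(),
                        n_spikes_used=1, n_trials=1)
        tf = estimate_transfer(sta, iac)
        np.testing.assert_allclose(tf.H, 1.0, atol=1e-9)
        assert 0.0 not in tf.freqs

    def test_shift_theorem(self):
        """sta delayed by Delta: |H| = 1 and phase = -2 pi f Delta."""
        iac = self._iac()
        m = 10
        delta_s = m * 0.5 * 1e-3
        sta = STAResult(lags=iac.lags, values=np.roll(iac.values, m),
                        n_spikes_used=1, n_trials=1)
        tf = estimate_transfer(sta, iac)
        np.testing.assert_allclose(np.abs(tf.H), 1.0, atol=1e-9)
        np.testing.assert_allclose(
            tf.H, np.exp(-1j * 2 * np.pi * tf.freqs * delta_s), atol=1e-9)

    def test_mismatched_grids_rejected(self):
        iac = self._iac()
        sta = STAResult(lags=iac.lags[:-2], values=iac.values[:-2],
                        n_spikes_used=1, n_trials=1)
        with pytest.raises(ValueError, match="grid"):
            estimate_transfer(sta, iac)

    def test_magnitude_scale_invariance_of_summaries(self):
        """Scaling the current by c rescales sta and PSD consistently, so
        f_cut and alpha are unchanged."""
        cur = sb.make_ou_current(0.0, 1.0, 60000.0, dt=0.5, seed=2)
        ref_cut = ref_alpha = None
        for c in (1.0, 5.0):
            scaled = sb.CurrentTrace(dt=0.5, values=c * cur.values)
            iac = autocorrelation(scaled, 500.0)
            # synthetic 'neuron': sta is a slower exponential kernel scaled
            # like the current, so H is a genuine low-pass filter
            sta = STAResult(lags=iac.lags,
                            values=c * np.exp(-np.abs(iac.lags) / 20.0),
                            n_spikes_used=1, n_trials=1)
            tf = estimate_transfer(sta, iac)
            sm = smooth_transfer(tf)
            cut = cutoff_frequency(sm)
            assert cut.defined
            fit = powerlaw_fit(sm, cut.f_cut)
            if c == 1.0:
                ref_cut, ref_alpha = cut.f_cut, fit.alpha
            else:
                assert cut.f_cut == pytest.approx(ref_cut, rel=1e-9)
                assert fit.alpha == pytest.approx(ref_alpha, rel=1e-9)


class TestCutoff:
    def _single_pole(self, corner=100.0, scale=1.0):
        f = np.logspace(0, 3, 4000)
        return TransferFunction(
            freqs=f, H=None,
            magnitude=scale / np.sqrt(1.0 + (f / corner) ** 2))

    def test_single_pole_closed_form(self):
        """0.7-of-1-Hz crossing of A/sqrt(1+(f/100)^2) sits at 102.03 Hz."""
        cut = cutoff_frequency(self._single_pole())
        ref = 1.0 / np.sqrt(1.0 + 1e-4)
        f_true = 100.0 * np.sqrt(1.0 / (0.7 * ref) ** 2 - 1.0)
        assert cut.defined
        assert cut.f_cut == pytest.approx(f_true, abs=0.2)

    def test_scale_invariance(self):
        a = cutoff_frequency(self._single_pole(scale=1.0)).f_cut
        b = cutoff_frequency(self._single_pole(scale=37.0)).f_cut
        assert a == pytest.approx(b, rel=1e-12)

    def test_flat_magnitude_is_undefined(self):
        f = np.logspace(0, 3, 100)
        tf = TransferFunction(freqs=f, H=None, magnitude=np.ones_like(f))
        cut = cutoff_frequency(tf)
        assert not cut.defined
        assert np.isnan(cut.f_cut)

    def test_insignificant_reference_is_undefined(self):
        tf = self._single_pole()
        tf.threshold = np.full_like(tf.magnitude, 10.0)  # everything below
        cut = cutoff_frequency(tf)
        assert not cut.defined

    def test_seventy_percent_decrease_variant(self):
        """fraction=0.3 implements the falls-to-30%-of-reference reading."""
        cut = cutoff_frequency(self._single_pole(), fraction=0.3)
        f_true = 100.0 * np.sqrt(1.0 / (0.3 / np.sqrt(1.0 + 1e-4)) ** 2 - 1.0)
        assert cut.f_cut == pytest.approx(f_true, rel=0.01)


class TestPowerLaw:
    def test_exact_power_laws(self):
        f = np.logspace(0, 4, 2000)
        for b_true, a_true in ((3.0, 0.5), (1.0, 1.0)):
            tf = TransferFunction(freqs=f, H=None,
                                  magnitude=b_true * f ** -a_true)
            fit = powerlaw_fit(tf, f_cut=2.0)
            assert fit.alpha == pytest.approx(a_true, abs=1e-9)
            assert fit.b == pytest.approx(b_true, rel=1e-9)

    def test_stop_frequency_honours_the_twenty_percent_floor(self):
        f = np.logspace(0, 4, 2000)
        tf = TransferFunction(freqs=f, H=None, magnitude=f ** -1.0)
        fit = powerlaw_fit(tf, f_cut=2.0)
        # |H| falls to 0.2 |H(2)| at f = 10
        assert fit.f_stop == pytest.approx(10.0, rel=0.02)

    def test_too_few_bins_rejected(self):
        f = np.logspace(0, 1, 6)
        tf = TransferFunction(freqs=f, H=None, magnitude=f ** -1.0)
        with pytest.raises(ValueError, match="bins"):
            powerlaw_fit(tf, f_cut=9.0)


class TestISICV:
    def test_periodic_train_has_zero_cv(self):
        train = sb.SpikeTrain(times=np.arange(10.0, 1000.0, 50.0),
                              duration=1000.0)
        assert sb.isi_cv(train) == 0.0

    def test_hand_computed_pair(self):
        """ISIs {40, 60}: population SD 10, mean 50 -> CV 0.2."""
        assert sb.isi_cv(np.array([40.0, 60.0])) == pytest.approx(0.2)

    def test_poisson_train_cv_near_one(self):
        rng = np.random.default_rng(3)
        isis = rng.exponential(50.0, 20000)
        assert sb.isi_cv(isis) == pytest.approx(1.0, abs=0.03)

    def test_single_isi_rejected(self):
        with pytest.raises(ValueError):
            sb.isi_cv(np.array([50.0]))


class TestSurrogates:
    def test_fewer_than_two_surrogates_rejected(self):
        cur = sb.make_ou_current(0.0, 1.0, 5000.0, dt=0.5, seed=0)
        train = sb.SpikeTrain(times=np.arange(100.0, 4900.0, 200.0),
                              duration=5000.0)
        with pytest.raises(ValueError):
            surrogate_threshold([(cur, train)], T=500.0, n_surrogates=1)

    def test_seeded_reproducibility(self):
        cur = sb.make_ou_current(0.0, 1.0, 5000.0, dt=0.5, seed=0)
        train = sb.SpikeTrain(times=np.arange(600.0, 4400.0, 150.0),
                              duration=5000.0)
        a = surrogate_threshold([(cur, train)], T=500.0, n_surrogates=10, seed=5)
        b = surrogate_threshold([(cur, train)], T=500.0, n_surrogates=10, seed=5)
        np.testing.assert_array_equal(a, b)


class TestModelResults:
    def test_lif_pipeline_produces_a_lowpass_profile(self, lif_trials_small):
        """Driven LIF: |H| significant over a contiguous low-frequency band,
        with a defined cut-off and a decaying high-frequency tail."""
        model = sb.TransferFunctionModel(lif_trials_small["trials"], T=500.0)
        res = model.fit(n_surrogates=60, seed=9)
        assert res.cutoff.defined
        assert res.f_cut >= 1.0
        sm = res.smoothed
        sig = sm.magnitude > sm.threshold
        assert sig[:5].all()  # low-frequency band is significant
        ref = res.cutoff.ref_magnitude
        high = sm.magnitude[(sm.freqs > res.f_cut * 3) & sig]
        assert high.size == 0 or np.median(high) < 0.8 * ref
        assert 0.3 < res.isi_cv < 1.0
        assert res.n_spikes_used == lif_trials_small["usable"]

    def test_summary_renders_the_key_quantities(self, lif_trials_small):
        model = sb.TransferFunctionModel(lif_trials_small["trials"], T=500.0)
        res = model.fit(n_surrogates=0)
        text = res.summary()
        assert "cut-off" in text and "alpha" in text
        s = res.to_summary()
        assert s.mean_rate == pytest.approx(res.mean_rate)

    def test_short_trials_rejected(self):
        cur = sb.make_ou_current(0.0, 1.0, 800.0, dt=0.5, seed=0)
        train = sb.SpikeTrain(times=np.array([100.0, 300.0]), duration=800.0)
        with pytest.raises(ValueError, match="2\\*T"):
            sb.TransferFunctionModel([(cur, train)], T=500.0)
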