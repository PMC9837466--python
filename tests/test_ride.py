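"""RIDE decomposition: latency estimation, aligned medians, recovery."""

import numpy as np
import pandas as pd
import pytest

from simonstop.epochs import EEGEpochs
from simonstop.ride import (
    RideConfig,
    _batch_latencies,
    aligned_median_waveform,
    estimate_latency,
    ride_decompose,
    shift_waveform,
)

SRATE = 256.0
DT = 1000.0 / SRATE


def hann_lobe(times, onset, offset, amp):
    w = np.zeros_like(times)
    inside = (times >= onset) & (times <= offset)
    w[inside] = amp * np.sin(np.pi * (times[inside] - onset) / (offset - onset)) ** 2
    return w


def make_times():
    return -2000.0 + np.arange(1024) * DT


def make_cell_epochs(data):
    n = data.shape[0]
    return EEGEpochs(
        data=data,
        srate=SRATE,
        times=make_times(),
        channel_labels=[f"ch{i}" for i in range(data.shape[1])],
        metadata=pd.DataFrame(
            {"trial_index": np.arange(n), "response": "go", "congruency": "congruent"}
        ),
    )


@pytest.fixture
def c_template():
    times = make_times()
    wave = hann_lobe(times, 390.0, 790.0, 5.0)
    topo = np.array([1.0, 0.8, 0.4])
    return (topo[:, None] * wave[None, :]), times


class TestLatencyEstimation:
    def test_shifted_template_recovers_shift(self, c_template):
        template, times = c_template
        trial = shift_waveform(template, 5)
        lat = estimate_latency(trial, template, (200.0, 800.0), 300.0, times, SRATE)
        assert lat == pytest.approx(5 * DT)

    def test_unshifted_template_gives_zero(self, c_template):
        template, times = c_template
        lat = estimate_latency(template, template, (200.0, 800.0), 300.0, times, SRATE)
        assert lat == 0.0

    def test_all_zero_template_rejected(self, c_template):
        _, times = c_template
        with pytest.raises(ValueError):
            estimate_latency(np.ones((3, 1024)), np.zeros((3, 1024)), (200.0, 800.0), 300.0, times, SRATE)

    def test_tie_break_prefers_smallest_absolute_shift(self):
        # constant trial: every shift of a symmetric template scores equally
        times = make_times()
        template = np.zeros((1, 1024))
        template[0, 500:540] = 1.0
        trial = np.ones((1, 1024))
        lat = estimate_latency(trial, template, (-200.0, 600.0), 300.0, times, SRATE)
        assert lat == 0.0

    def test_noisy_recovery_monte_carlo(self, c_template):
        # template at SNR 2 (peak/noise-sd), known shift of 12 samples:
        # estimates within +/-3 samples in at least 90% of 500 draws
        template, times = c_template
        rng = np.random.default_rng(99)
        true_shift = 12
        shifted = shift_waveform(template, true_shift)
        trials = shifted[None, :, :] + rng.normal(0, 2.5, size=(500, 3, 1024))
        idx = np.flatnonzero((times >= 200.0) & (times <= 800.0))
        est = _batch_latencies(trials, template, idx, int(round(300.0 / DT)), 0.1)
        assert np.mean(np.abs(est - true_shift) <= 3) >= 0.90


class TestAlignedMedian:
    def test_identical_trials_zero_latency(self, c_template):
        template, _ = c_template
        trials = np.repeat(template[None, :, :], 11, axis=0)
        out = aligned_median_waveform(trials, np.zeros(11), SRATE)
        assert np.allclose(out, template)

    def test_shift_compensation(self, c_template):
        template, _ = c_template
        shifts = np.array([-20, -10, 0, 10, 20])
        trials = np.stack([shift_waveform(template, s) for s in shifts])
        out = aligned_median_waveform(trials, shifts * DT, SRATE)
        core = slice(200, 900)
        r = np.corrcoef(out[0, core], template[0, core])[0, 1]
        assert r > 0.99

    def test_median_resists_gross_outlier(self, c_template):
        template, _ = c_template
        trials = np.repeat(template[None, :, :], 21, axis=0)
        trials[0] += 500.0  # one broken trial
        med = aligned_median_waveform(trials, np.zeros(21), SRATE)
        mean = trials.mean(axis=0)
        assert np.abs(med - template).max() < 1e-9
        assert np.abs(mean - template).max() > 20.0


class TestDecomposition:
    def _noiseless_epochs(self, n=24, jitter=None):
        times = make_times()
        s_wave = hann_lobe(times, 80.0, 140.0, 3.0) - hann_lobe(times, 260.0, 350.0, 3.0)
        c_wave = hann_lobe(times, 390.0, 790.0, 5.0)
        topo_s = np.array([0.2, 1.0, 0.5])
        topo_c = np.array([1.0, 0.8, 0.4])
        S = topo_s[:, None] * s_wave[None, :]
        C = topo_c[:, None] * c_wave[None, :]
        if jitter is None:
            jitter = np.zeros(n, dtype=int)
        data = np.stack([S + shift_waveform(C, j) for j in jitter])
        return make_cell_epochs(data), S, C, jitter

    def test_noiseless_zero_jitter_reconstructs_average(self):
        epochs, S, C, _ = self._noiseless_epochs()
        res = ride_decompose(epochs, RideConfig(dtype="float64"))
        avg = epochs.data.mean(axis=0)
        assert np.allclose(res.s_waveform + res.c_waveform, avg, atol=1e-9)
        assert res.residual_rms.max() < 1e-9
        assert np.all(res.c_latencies_ms == 0.0)

    def test_decomposition_identity_holds_exactly(self):
        rng = np.random.default_rng(3)
        epochs, *_ = self._noiseless_epochs(n=16, jitter=rng.integers(-10, 11, 16))
        epochs.data += rng.normal(0, 5.0, epochs.data.shape)
        res = ride_decompose(epochs)
        shifts = np.round(res.c_latencies_ms / DT).astype(int)
        for i in range(epochs.n_trials):
            recon = res.s_waveform + shift_waveform(res.c_waveform, shifts[i])
            resid = epochs.data[i] - recon
            rms = np.sqrt((resid**2).mean())
            assert rms == pytest.approx(res.residual_rms[i], rel=1e-9)

    def test_latency_and_waveform_recovery_with_jitter(self):
        rng = np.random.default_rng(4)
        n = 120
        jitter = np.clip(np.round(rng.normal(0, 50.0 / DT, n)), -38, 38).astype(int)
        epochs, S, C, _ = self._noiseless_epochs(n=n, jitter=jitter)
        epochs.data += rng.normal(0, 5.0, epochs.data.shape)
        res = ride_decompose(epochs)
        r_lat = np.corrcoef(res.c_latencies_ms, jitter * DT)[0, 1]
        assert r_lat >= 0.8
        mask = (epochs.times >= 200.0) & (epochs.times <= 800.0)
        r_c = np.corrcoef(res.c_waveform[0, mask], C[0, mask])[0, 1]
        assert r_c >= 0.9

    def test_latencies_have_zero_median(self):
        rng = np.random.default_rng(5)
        jitter = rng.integers(-15, 16, 40)
        epochs, *_ = self._noiseless_epochs(n=40, jitter=jitter)
        epochs.data += rng.normal(0, 5.0, epochs.data.shape)
        res = ride_decompose(epochs)
        assert abs(np.median(res.c_latencies_ms)) <= DT / 2

    def test_condition_effect_stays_in_c_cluster(self):
        # implant an amplitude difference on C only; the S window means of the
        # two decompositions must differ by far less than the C effect
        rng = np.random.default_rng(6)
        n = 80
        jitter = np.clip(np.round(rng.normal(0, 50.0 / DT, n)), -38, 38).astype(int)
        means = {}
        for label, amp in (("base", 5.0), ("boost", 6.0)):
            times = make_times()
            c_wave = hann_lobe(times, 390.0, 790.0, amp)
            s_wave = hann_lobe(times, 80.0, 140.0, 3.0)
            S = np.array([0.2, 1.0, 0.5])[:, None] * s_wave[None, :]
            C = np.array([1.0, 0.8, 0.4])[:, None] * c_wave[None, :]
            data = np.stack([S + shift_waveform(C, j) for j in jitter])
            data += rng.normal(0, 2.0, data.shape)
            res = ride_decompose(make_cell_epochs(data))
            s_mask = (times >= -200.0) & (times <= 600.0)
            c_mask = (times >= 530.0) & (times <= 650.0)
            means[label] = (
                res.s_waveform[0, s_mask].mean(),
                res.c_waveform[0, c_mask].mean(),
            )
        c_effect = means["boost"][1] - means["base"][1]
        s_effect = means["boost"][0] - means["base"][0]
        assert c_effect > 0.3  # most of the implanted 1 uV appears in C
        assert abs(s_effect) < 0.1 * abs(c_effect)

    def test_response_locked_variance_is_absorbed_by_c(self):
        # with no R cluster modeled, a latency-variable (response-locked)
        # component must end up in C, not in the residual
        rng = np.random.default_rng(7)
        n = 40
        jitter = rng.integers(-25, 26, n)
        times = make_times()
        r_wave = hann_lobe(times, 450.0, 650.0, 4.0)
        R = np.array([0.5, 1.0, 0.3])[:, None] * r_wave[None, :]
        data = np.stack([shift_waveform(R, j) for j in jitter])
        epochs = make_cell_epochs(data)
        res = ride_decompose(epochs, RideConfig(dtype="float64"))
        c_mask = (times >= 200.0) & (times <= 800.0)
        c_power = (res.c_waveform[:, c_mask] ** 2).mean()
        resid_power = (res.residual_rms**2).mean()
        assert c_power > 10 * resid_power

    def test_too_few_trials_rejected(self):
        epochs, *_ = self._noiseless_epochs(n=5)
        with pytest.raises(ValueError, match="at least"):
            ride_decompose(epochs)

    def test_latency_updates_settle(self):
        rng = np.random.default_rng(8)
        settled = 0
        runs = 6
        for k in range(runs):
            n = 60
            jitter = np.clip(np.round(rng.normal(0, 50.0 / DT, n)), -38, 38).astype(int)
            epochs, *_ = self._noiseless_epochs(n=n, jitter=jitter)
            epochs.data += rng.normal(0, 5.0, epochs.data.shape)
            res = ride_decompose(epochs)
            h = res.latency_update_history
            if len(h) < 2 or h[-1] <= h[-2]:
                settled += 1
        assert settled >= runs - 1
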