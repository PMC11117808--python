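import numpy as np
import pytest

from sspdim import (
    BaselinePower,
    TFPower,
    baseline_power,
    channel_weights,
    distortion_objective,
    estimate_threshold,
    noise_objective,
    tf_power,
)
from sspdim.data_model import AnalysisWindows

from conftest import make_continuous, make_epochs


def _tfp(power, freqs, times, n_trials=1):
    return TFPower(
        power=np.asarray(power, dtype=float),
        freqs=np.asarray(freqs, dtype=float),
        times=np.asarray(times, dtype=float),
        n_trials=n_trials,
        n_cycles=np.full(len(freqs), 1e-6),  # negligible edge margin
    )


class TestTFPower:
    def test_pure_tone_ridge_at_its_frequency(self):
        srate = 1000.0
        times = np.arange(-200, 801) / srate
        sig = np.where((times >= 0) & (times < 0.5),
                       np.sin(2 * np.pi * 10 * times), 0.0)
        ep = make_epochs(sig[None, None, :], srate)
        tfp = tf_power(ep, [10.0, 20.0])
        mid = (tfp.times >= 0.15) & (tfp.times <= 0.35)  # away from edges
        ratio = tfp.power[0, 0, mid].mean() / tfp.power[0, 1, mid].mean()
        assert ratio >= 5.0

    def test_zero_signal_zero_power(self):
        ep = make_epochs(np.zeros((2, 3, 1001)))
        tfp = tf_power(ep, [10.0])
        assert np.abs(tfp.power).max() == 0.0

    def test_power_scales_quadratically(self, tiny_epochs):
        tfp1 = tf_power(tiny_epochs, [10.0])
        doubled = tiny_epochs.copy_with(2.0 * tiny_epochs.data)
        tfp2 = tf_power(doubled, [10.0])
        np.testing.assert_allclose(tfp2.power, 4.0 * tfp1.power, rtol=1e-10)

    def test_wavelet_longer_than_epoch_rejected(self):
        ep = make_epochs(np.zeros((1, 1, 200)), tmin=-0.05)  # 0.2 s epoch
        with pytest.raises(ValueError, match="at least"):
            tf_power(ep, [3.0])  # 3 cycles at 3 Hz needs ~1.6 s


class TestBaselinePower:
    def test_constant_power_recovered(self):
        times = np.arange(-200, 801) / 1000.0
        power = np.full((2, 1, times.size), 3.5)
        base = baseline_power(_tfp(power, [10.0], times), -0.2, 0.0)
        np.testing.assert_allclose(base.power, 3.5)

    def test_post_stimulus_power_invisible(self):
        times = np.arange(-200, 801) / 1000.0
        power = np.zeros((1, 1, times.size))
        power[:, :, times > 0.1] = 9.0
        base = baseline_power(_tfp(power, [10.0], times), -0.2, 0.0)
        assert base.power[0, 0] == 0.0

    def test_single_spike_averaging_arithmetic(self):
        # baseline window strictly interior to the epoch: m = 11 samples
        times = np.arange(-15, 11) / 1000.0
        power = np.zeros((1, 1, times.size))
        power[0, 0, 5] = 42.0  # the sample at t = -0.010 s
        base = baseline_power(_tfp(power, [10.0], times), -0.010, 0.0)
        m = np.sum((times >= -0.010) & (times <= 0.0))
        assert m == 11
        assert base.power[0, 0] == pytest.approx(42.0 / m)

    def test_baseline_after_stimulus_rejected(self):
        times = np.arange(-10, 11) / 1000.0
        with pytest.raises(ValueError):
            baseline_power(_tfp(np.zeros((1, 1, 21)), [10.0], times), 0.0, 0.005)


class TestDistortionObjective:
    def _win(self):
        return AnalysisWindows(0.0, 0.5, -0.2, 0.0, 9.0, 11.0)

    def test_identity_denoising_gives_exactly_one(self, tiny_epochs, sim_windows):
        tfp = tf_power(tiny_epochs, [9.0, 10.0, 11.0])
        base = baseline_power(tfp, -0.2, 0.0)
        assert distortion_objective(tfp, base, tfp, base, sim_windows) == 1.0

    def test_zero_denoised_gives_zero(self, tiny_epochs, sim_windows):
        tfp = tf_power(tiny_epochs, [9.0, 10.0, 11.0])
        base = baseline_power(tfp, -0.2, 0.0)
        zeros = tf_power(tiny_epochs.copy_with(np.zeros_like(tiny_epochs.data)),
                         [9.0, 10.0, 11.0])
        zbase = baseline_power(zeros, -0.2, 0.0)
        assert distortion_objective(tfp, base, zeros, zbase, sim_windows) == 0.0

    def test_two_channel_arithmetic(self):
        # raw per-channel evoked power (4, 2); denoised (2, 1) -> ratio 0.5
        times = np.arange(-200, 801) / 1000.0
        signal_mask = (times >= 0.0) & (times <= 0.5)

        def build(vals):
            power = np.zeros((2, 1, times.size))
            for i, v in enumerate(vals):
                power[i, 0, signal_mask] = v
            return _tfp(power, [10.0], times)

        raw, den = build([4.0, 2.0]), build([2.0, 1.0])
        zero_base = BaselinePower(power=np.zeros((2, 1)), baseline=(-0.2, 0.0))
        win = self._win()
        fb = distortion_objective(raw, zero_base, den, zero_base, win)
        assert fb == pytest.approx(0.5)

    def test_no_evoked_power_is_an_error(self):
        times = np.arange(-200, 801) / 1000.0
        flat = _tfp(np.zeros((2, 1, times.size)), [10.0], times)
        base = BaselinePower(power=np.zeros((2, 1)), baseline=(-0.2, 0.0))
        with pytest.raises(ValueError, match="no evoked power"):
            distortion_objective(flat, base, flat, base, self._win())


class TestChannelWeights:
    def test_proportional_to_std(self):
        rng = np.random.default_rng(7)
        base = rng.standard_normal((2, 5, 200))
        base -= base.mean(axis=(1, 2), keepdims=True)
        base /= base.reshape(2, -1).std(axis=1)[:, None, None]
        data = base * np.array([3.0, 1.0])[:, None, None]
        w = channel_weights(make_epochs(data, tmin=-0.05))
        np.testing.assert_allclose(w, [0.75, 0.25], atol=1e-12)

    def test_identical_channels_uniform(self):
        data = np.tile(np.sin(np.arange(300) / 10.0), (4, 2, 1))
        w = channel_weights(make_epochs(data, tmin=-0.05))
        np.testing.assert_allclose(w, 0.25)

    def test_scale_invariant_and_normalized(self, tiny_epochs):
        w1 = channel_weights(tiny_epochs)
        w2 = channel_weights(tiny_epochs.copy_with(37.5 * tiny_epochs.data))
        np.testing.assert_allclose(w1, w2, rtol=1e-12)
        assert w1.sum() == pytest.approx(1.0)

    def test_all_zero_data_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            channel_weights(make_epochs(np.zeros((2, 2, 50)), tmin=-0.01))


class TestNoiseObjective:
    def test_identity_gives_one(self, tiny_epochs):
        w = channel_weights(tiny_epochs)
        assert noise_objective(tiny_epochs, tiny_epochs, w) == pytest.approx(1.0)

    def test_halving_amplitude_quadruples_ratio(self, tiny_epochs):
        w = channel_weights(tiny_epochs)
        half = tiny_epochs.copy_with(tiny_epochs.data / 2.0)
        assert noise_objective(tiny_epochs, half, w) == pytest.approx(4.0)

    def test_zero_weight_masks_a_channel(self, rng):
        raw = make_epochs(rng.standard_normal((2, 3, 100)), tmin=-0.01)
        den_data = raw.data.copy()
        den_data[1] = rng.standard_normal((3, 100)) * 100  # only channel 2 changes
        den = raw.copy_with(den_data)
        assert noise_objective(raw, den, np.array([1.0, 0.0])) == pytest.approx(1.0)

    def test_everything_removed_gives_inf(self, tiny_epochs):
        w = channel_weights(tiny_epochs)
        zero = tiny_epochs.copy_with(np.zeros_like(tiny_epochs.data))
        assert noise_objective(tiny_epochs, zero, w) == float("inf")


@pytest.fixture(scope="module")
def small_dataset():
    from sspdim import simulate_dataset, bandpass_filter
    from sspdim.simulation import InterferenceModel

    raw, er, truth = simulate_dataset(
        seed=42, n_trials=20, interference=InterferenceModel(rank=2)
    )
    return (
        bandpass_filter(raw, 1.0, 40.0),
        bandpass_filter(er, 1.0, 40.0),
        truth,
    )


class TestEstimateThreshold:
    def test_single_threshold_range_degenerates_gracefully(self, small_dataset, sim_windows):
        ep, er, _ = small_dataset
        with pytest.warns(RuntimeWarning, match="degenerate"):
            trace = estimate_threshold(ep, er, "ssp", sim_windows, [3])
        assert trace.selected == 3
        assert np.isfinite(trace.Fall[0])

    def test_trace_invariants(self, small_dataset, sim_windows):
        ep, er, _ = small_dataset
        trace = estimate_threshold(ep, er, "ssp", sim_windows, range(1, 7))
        fb = np.array(trace.FB_norm)
        fn = np.array(trace.FN_norm)
        assert np.all((fb >= -1e-12) & (fb <= 1 + 1e-12))
        assert np.all((fn >= -1e-12) & (fn <= 2 + 1e-12))
        fall = trace.alpha * fb + (1 - trace.alpha) * np.tanh(fn)
        np.testing.assert_allclose(trace.Fall, fall, rtol=1e-12)
        best = max(trace.Fall)
        assert trace.selected == min(
            x for x, f in zip(trace.thresholds, trace.Fall) if f >= best - 1e-15
        )
        assert np.sum(trace.weights) == pytest.approx(1.0)

    def test_scale_invariance_of_selection(self, small_dataset, sim_windows):
        # both objectives are ratios: a common positive rescaling of all
        # channel data must not change the trace
        ep, er, _ = small_dataset
        t1 = estimate_threshold(ep, er, "ssp", sim_windows, range(1, 7))
        t2 = estimate_threshold(
            ep.copy_with(ep.data * 12.5), er.copy_with(er.data * 12.5),
            "ssp", sim_windows, range(1, 7),
        )
        np.testing.assert_allclose(t1.Fall, t2.Fall, rtol=1e-9)
        assert t1.selected == t2.selected

    def test_alpha_extremes_reduce_to_single_objectives(self, small_dataset, sim_windows):
        ep, er, _ = small_dataset
        t_b = estimate_threshold(ep, er, "ssp", sim_windows, range(1, 7), alpha=1.0)
        assert t_b.Fall == pytest.approx(t_b.FB_norm)
        t_n = estimate_threshold(ep, er, "ssp", sim_windows, range(1, 7), alpha=0.0)
        np.testing.assert_allclose(t_n.Fall, np.tanh(t_n.FN_norm), rtol=1e-12)

    def test_s3p_sweep_runs_and_selects_in_range(self, small_dataset, sim_windows):
        ep, er, _ = small_dataset
        trace = estimate_threshold(ep, er, "s3p", sim_windows, range(1, 7))
        assert trace.selected in range(1, 7)
        assert trace.algorithm == "s3p"

    def test_x_range_validation(self, small_dataset, sim_windows):
        ep, er, _ = small_dataset
        with pytest.raises(ValueError):
            estimate_threshold(ep, er, "ssp", sim_windows, [])
        with pytest.raises(ValueError):
            estimate_threshold(ep, er, "ssp", sim_windows, [99])
        with pytest.raises(ValueError):
            estimate_threshold(ep, er, "ssp", sim_windows, [1, 2], alpha=1.5)
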