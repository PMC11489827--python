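"""Current-clamp feature extraction: RMP, Rm, AP detection, excitability."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.signal import savgol_filter

from neosync import intrinsic as ic
from neosync import synth
from neosync.types import IntrinsicProperties, Sweep

from conftest import make_config


def _flat_sweep(value=-70.0, dur=100.0, rate=20_000.0):
    n = int(dur * rate)
    return Sweep(np.full(n, value), np.zeros(n), rate)


class TestEstimateRmp:
    def test_constant_voltage(self):
        out = ic.estimate_rmp(_flat_sweep(-70.0))
        assert np.allclose(out["medians"], -70.0)
        assert out["summary_mv"] == -70.0

    def test_median_robust_to_spike_artifacts(self):
        # 1% of samples jump by +40 mV; the median must not move
        sweep = _flat_sweep(-70.0, dur=40.0)
        rng = np.random.default_rng(0)
        idx = rng.choice(sweep.data.size, sweep.data.size // 100, replace=False)
        sweep.data[idx] += 40.0
        out = ic.estimate_rmp(sweep)
        assert np.allclose(out["medians"], -70.0)

    def test_recovers_planted_resting_potential(self):
        sweeps, _ = synth.gen_currentclamp(make_config(
            "currentclamp", 600.0, 20_000.0, 2, noise_sd_mv=0.5,
            test_pulse_pa=0.0))
        out = ic.estimate_rmp(sweeps.sweeps[0])
        assert out["summary_mv"] == pytest.approx(-61.3, abs=0.2)

    def test_pulse_epochs_are_excised(self):
        sweeps, _ = synth.gen_currentclamp(make_config(
            "currentclamp", 600.0, 20_000.0, 3, noise_sd_mv=0.0))
        out = ic.estimate_rmp(sweeps.sweeps[0])
        # without excision the -1.5 mV deflections would bias some medians
        assert np.allclose(out["medians"], -61.3, atol=1e-6)

    def test_interval_longer_than_sweep(self):
        with pytest.raises(ValueError):
            ic.estimate_rmp(_flat_sweep(dur=10.0), interval_s=20.0)


class TestEstimateRm:
    def test_ohms_law(self):
        # -1.0 mV deflection at -10 pA -> 100 MOhm
        rate = 20_000.0
        n = int(1.0 * rate)
        data = np.full(n, -70.0)
        command = np.zeros(n)
        command[int(0.4 * rate):int(0.9 * rate)] = -10.0
        data[int(0.4 * rate):int(0.9 * rate)] = -71.0
        out = ic.estimate_rm(Sweep(data, command, rate))
        assert out["rm_mohm"] == pytest.approx(100.0)

    def test_published_control_value(self):
        # -1.545 mV at -10 pA -> 154.5 MOhm
        sweeps, _ = synth.gen_currentclamp(make_config(
            "currentclamp", 100.0, 20_000.0, 1, noise_sd_mv=0.0))
        out = ic.estimate_rm(sweeps.sweeps[0])
        assert out["rm_mohm"] == pytest.approx(154.5, rel=0.01)

    def test_rc_model_within_one_percent(self):
        sweeps, _ = synth.gen_currentclamp(make_config(
            "currentclamp", 100.0, 20_000.0, 1, r_mohm=200.0, c_pf=100.0,
            noise_sd_mv=0.0))
        out = ic.estimate_rm(sweeps.sweeps[0])
        assert out["rm_mohm"] == pytest.approx(200.0, rel=0.01)

    def test_invariant_to_voltage_offset(self):
        sweeps, _ = synth.gen_currentclamp(make_config(
            "currentclamp", 100.0, 20_000.0, 4, noise_sd_mv=0.1))
        sweep = sweeps.sweeps[0]
        r1 = ic.estimate_rm(sweep)["rm_mohm"]
        shifted = Sweep(sweep.data + 13.7, sweep.command, sweep.sampling_rate)
        r2 = ic.estimate_rm(shifted)["rm_mohm"]
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_steady_state_warning(self):
        with pytest.warns(UserWarning):
            sweeps, _ = synth.gen_currentclamp(make_config(
                "currentclamp", 100.0, 20_000.0, 1, r_mohm=2000.0, c_pf=200.0,
                noise_sd_mv=0.0))
            ic.estimate_rm(sweeps.sweeps[0])

    def test_parameter_recovery_over_seeds(self):
        errs = []
        for seed in range(50):
            sweeps, _ = synth.gen_currentclamp(make_config(
                "currentclamp", 60.0, 20_000.0, seed, noise_sd_mv=0.2))
            r = ic.estimate_rm(sweeps.sweeps[0])["rm_mohm"]
            errs.append(abs(r - 154.5) / 154.5)
        assert np.median(errs) < 0.02


class TestDetectAps:
    def test_subthreshold_sweep_is_empty(self):
        rate = 20_000.0
        t = np.arange(int(0.2 * rate)) / rate
        data = -70.0 + 2.0 * np.sin(2 * np.pi * 5 * t)   # max dV/dt ~ 0.06 V/s
        table = ic.detect_aps(Sweep(data, np.zeros(t.size), rate))
        assert len(table) == 0

    def test_template_onsets_match_analytic_derivative_oracle(self):
        rate = 20_000.0
        template = synth.ap_template(rate)
        # oracle: first point where the analytic template derivative (after the
        # same SG smoothing of the sampled derivative) crosses 20 V/s
        amp, sig, t0 = 60.0, 0.3e-3, 1e-3

        def dvdt(t):   # analytic derivative of the Gaussian upstroke, V/s
            return -amp * (t - t0) / sig ** 2 * np.exp(
                -0.5 * ((t - t0) / sig) ** 2) / 1e3

        # first upward crossing lies before the maximum-slope point t0 - sigma
        t_cross = brentq(lambda t: dvdt(t) - 20.0, 1e-5, t0 - sig)
        planted = np.array([0.05, 0.12, 0.31])
        n = int(0.5 * rate)
        data = np.full(n, -60.0)
        for tp in planted:
            i = int(round(tp * rate))
            data[i:i + template.size] += template
        table = ic.detect_aps(Sweep(data, np.zeros(n), rate))
        assert len(table) == len(planted)
        np.testing.assert_allclose(table["time_s"], planted + t_cross, atol=2e-4)

    def test_invariant_to_offset_and_translation(self):
        sweeps, truth = synth.gen_currentclamp(make_config(
            "currentclamp", 1.0, 20_000.0, 6, protocol="step_series",
            noise_sd_mv=0.1))
        sweep = sweeps.sweeps[-1]
        base = ic.detect_aps(sweep)
        shifted = ic.detect_aps(Sweep(sweep.data + 25.0, sweep.command,
                                      sweep.sampling_rate))
        assert len(base) == len(shifted)
        np.testing.assert_array_equal(base["sample"], shifted["sample"])
        pad = 400
        translated = ic.detect_aps(Sweep(
            np.concatenate([np.full(pad, sweep.data[0]), sweep.data]),
            np.concatenate([np.zeros(pad), sweep.command]),
            sweep.sampling_rate))
        np.testing.assert_array_equal(base["sample"] + pad,
                                      translated["sample"][-len(base):])

    def test_noiseless_detection_reproduces_generator_counts(self):
        sweeps, truth = synth.gen_currentclamp(make_config(
            "currentclamp", 1.0, 20_000.0, 41, protocol="step_series",
            noise_sd_mv=0.0))
        for i, sweep in enumerate(sweeps.sweeps):
            assert len(ic.detect_aps(sweep)) == len(truth.event_times["ap"][i])

    def test_low_sampling_rate_warns(self):
        with pytest.warns(UserWarning, match="10 kHz"):
            ic.detect_aps(Sweep(np.zeros(1000), np.zeros(1000), 5_000.0))


class TestExcitabilityMetrics:
    def test_rate_arithmetic(self):
        # 3 APs in a 500-ms step -> 6 Hz mean; min ISI 20 ms -> 50 Hz inst.
        rate = 20_000.0
        n = int(0.8 * rate)
        command = np.zeros(n)
        command[int(0.1 * rate):int(0.6 * rate)] = 50.0
        data = np.full(n, -60.0)
        template = synth.ap_template(rate)
        for tp in (0.2, 0.22, 0.5):
            i = int(round(tp * rate))
            data[i:i + template.size] += template
        from neosync.types import SweepSet
        sweeps = SweepSet([Sweep(data, command, rate, step_amplitude_pa=50.0)],
                          rate, "step_series", step_amplitudes=[50.0])
        props = ic.excitability_metrics(sweeps)[0]
        assert props.max_mean_rate == pytest.approx(6.0)
        assert props.max_inst_rate == pytest.approx(50.0, rel=0.01)
        assert props.rheobase == 50.0

    def test_io_curve_nondecreasing_and_exact(self):
        sweeps, truth = synth.gen_currentclamp(make_config(
            "currentclamp", 1.0, 20_000.0, 9, protocol="step_series",
            noise_sd_mv=0.0))
        counts = {}
        for i, sweep in enumerate(sweeps.sweeps):
            if sweep.series_index == 0:
                counts[sweep.step_amplitude_pa] = len(truth.event_times["ap"][i])
        amps = sorted(counts)
        assert all(counts[a] <= counts[b] for a, b in zip(amps, amps[1:]))
        props = ic.excitability_metrics(sweeps)
        expected_rheobase = min((a for a in amps if counts[a] > 0), default=None)
        for p in props:
            assert p.rheobase == expected_rheobase

    def test_rheobase_aggregates_by_median(self):
        series = [IntrinsicProperties(rheobase=50.0),
                  IntrinsicProperties(rheobase=60.0),
                  IntrinsicProperties(rheobase=60.0)]
        assert ic.aggregate_series(series).rheobase == 60.0

    def test_undefined_metrics_stay_nan(self):
        sweeps, _ = synth.gen_currentclamp(make_config(
            "currentclamp", 1.0, 20_000.0, 2, protocol="step_series",
            step_stop_pa=60.0, noise_sd_mv=0.0))
        agg = ic.aggregate_series(ic.excitability_metrics(sweeps))
        assert np.isnan(agg.rheobase) and np.isnan(agg.max_mean_rate)
        assert np.isnan(agg.max_inst_rate) and np.isnan(agg.ap_threshold)

    def test_max_inst_at_least_max_mean(self):
        sweeps, _ = synth.gen_currentclamp(make_config(
            "currentclamp", 1.0, 20_000.0, 12, protocol="step_series",
            noise_sd_mv=0.1))
        for p in ic.excitability_metrics(sweeps):
            if np.isfinite(p.max_inst_rate) and np.isfinite(p.max_mean_rate):
                assert p.max_inst_rate >= p.max_mean_rate
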