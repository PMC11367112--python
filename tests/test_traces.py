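"""Trace processing: Gaussian filtering, leak and bleach corrections, dF/F,
and the zero-noise end-to-end identity against the generator's closed forms."""

import numpy as np
import pytest

from tevcf import synthetic as syn
from tevcf import traces as tr


class TestGaussianFilter:
    def test_dc_gain_unity(self):
        out = tr.gaussian_filter_trace(np.full(500, 3.7), 1000.0, 5000.0)
        np.testing.assert_allclose(out, 3.7, rtol=1e-12)

    def test_impulse_response_normalized(self):
        x = np.zeros(501)
        x[250] = 1.0
        out = tr.gaussian_filter_trace(x, 1000.0, 5000.0)
        assert out.sum() == pytest.approx(1.0, rel=1e-9)
        assert len(out) == len(x)

    def test_minus_3db_at_cutoff(self):
        # FFT oracle: attenuation of a pure sine at the cutoff frequency
        fs, fc, n = 5000.0, 500.0, 5000
        t = np.arange(n) / fs
        x = np.sin(2 * np.pi * fc * t)
        y = tr.gaussian_filter_trace(x, fc, fs)
        spectrum_in = np.abs(np.fft.rfft(x))
        spectrum_out = np.abs(np.fft.rfft(y))
        k = np.argmax(spectrum_in)
        attenuation = spectrum_out[k] / spectrum_in[k]
        assert attenuation == pytest.approx(10 ** (-3 / 20), rel=0.05)

    @pytest.mark.parametrize("cutoff", [0.0, 2500.0, 3000.0])
    def test_invalid_cutoff_rejected(self, cutoff):
        with pytest.raises(ValueError):
            tr.gaussian_filter_trace(np.zeros(10), cutoff, 5000.0)


def _ohmic_sweepset(protocol, conductance=0.01, offset=0.0):
    sweeps = []
    t = protocol.time_ms()
    for v in protocol.test_potentials():
        v_cmd = protocol.voltage_trace(v)
        cur = offset + conductance * v_cmd
        sweeps.append(
            tr.Sweep(test_potential=v, time_ms=t, current_ua=cur,
                     fluorescence_au=np.full_like(t, 100.0))
        )
    return tr.SweepSet("c0", "control", "day1", protocol, sweeps)


class TestLeak:
    def test_pure_ohmic_recovered_exactly(self, protocol):
        ss = _ohmic_sweepset(protocol, conductance=0.01, offset=0.0)
        offset, g = tr.estimate_leak(ss)
        assert offset == pytest.approx(0.0, abs=1e-12)
        assert g == pytest.approx(0.01, rel=1e-12)

    def test_channel_contamination_below_one_percent(self, protocol):
        # with the default gating midpoint, open probability at <= -80 mV is
        # ~3e-3, so the subthreshold ohmic fit recovers the leak within 1%
        gt = syn.GatingGroundTruth(noise_sd_current=0.0)
        ss = syn.simulate_sweepset(gt, protocol, rng=0)
        _, g = tr.estimate_leak(ss)
        assert g == pytest.approx(gt.leak_conductance, rel=0.01)

    def test_single_qualifying_sweep_rejected(self, protocol):
        ss = _ohmic_sweepset(protocol)
        with pytest.raises(tr.InsufficientLeakDataError):
            tr.estimate_leak(ss, fit_voltage_range=(-140.0, -140.0))

    def test_subtraction_zeroes_ohmic_set(self, protocol):
        ss = _ohmic_sweepset(protocol, conductance=0.02, offset=0.1)
        corrected = tr.subtract_leak(ss, tr.estimate_leak(ss))
        for c in corrected:
            np.testing.assert_allclose(c, 0.0, atol=1e-12)

    def test_zero_leak_params_identity(self, protocol):
        ss = _ohmic_sweepset(protocol)
        corrected = tr.subtract_leak(ss, (0.0, 0.0))
        for c, s in zip(corrected, ss.sweeps):
            np.testing.assert_array_equal(c, s.current_ua)

    def test_estimate_subtract_idempotent(self, protocol):
        # re-estimating on corrected sweeps returns leak below the noise floor
        gt = syn.GatingGroundTruth()
        ss = syn.simulate_sweepset(gt, protocol, rng=4)
        leak = tr.estimate_leak(ss)
        corrected = tr.subtract_leak(ss, leak)
        ss2 = tr.SweepSet(
            "c0", "control", "day1", protocol,
            [tr.Sweep(s.test_potential, s.time_ms, c, s.fluorescence_au)
             for s, c in zip(ss.sweeps, corrected)],
        )
        _, g2 = tr.estimate_leak(ss2)
        noise_floor = gt.noise_sd_current / 100.0  # mean over >1000 samples
        assert abs(g2) < 3 * noise_floor


class TestBleachAndDff:
    def test_trace_equal_baseline_flattens(self, rng):
        base = 1000.0 * np.exp(-0.02 * np.arange(500) / 5000.0)
        out = tr.correct_photobleach(base, base, slice(0, 100))
        np.testing.assert_allclose(out, np.mean(base[:100]), rtol=1e-12)

    def test_boxcar_recovered_exactly(self):
        base = 1000.0 * np.exp(-0.05 * np.arange(500) / 5000.0)
        boxcar = np.zeros(500)
        boxcar[200:400] = 7.0
        out = tr.correct_photobleach(base + boxcar, base, slice(0, 100))
        np.testing.assert_allclose(out - np.mean(base[:100]), boxcar, atol=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tr.correct_photobleach(np.zeros(10), np.zeros(11), slice(0, 5))

    def test_residual_bleach_drift_small(self, protocol):
        # correcting a bleaching sweep with the hyperpolarized baseline leaves
        # drift well under 5% of the signal amplitude over the 250-ms pulse
        gt = syn.GatingGroundTruth(noise_sd_fluor=0.0, bleach_rate=0.02)
        sig = syn.simulate_fluorescence_sweep(gt, protocol, 40.0, rng=0)
        base = syn.simulate_fluorescence_sweep(gt, protocol, -140.0, rng=0)
        n_base = int(round(50.0 / protocol.dt_ms))
        pulse = protocol.pulse_slice()
        window = slice(pulse.start - n_base, pulse.start)
        out = tr.correct_photobleach(sig, base, window)
        dff = tr.compute_dff(out, window)
        amplitude = gt.dff_max
        drift = abs(dff[pulse][-1] - dff[pulse][len(dff[pulse]) // 2])
        assert drift < 0.05 * amplitude

    def test_dff_plateau_percentage(self):
        trace = np.full(500, 100.0)
        trace[250:] = 102.0
        dff = tr.compute_dff(trace, slice(0, 250))
        assert dff[-1] == pytest.approx(2.0)
        np.testing.assert_allclose(dff[:250], 0.0, atol=1e-12)

    def test_flat_trace_zero_dff(self):
        np.testing.assert_allclose(
            tr.compute_dff(np.full(100, 50.0), slice(0, 20)), 0.0, atol=1e-12
        )

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(ValueError):
            tr.compute_dff(np.full(100, -1.0), slice(0, 20))

    @pytest.mark.parametrize("gain", [0.5, 3.0, 1e4])
    def test_dff_gain_invariance(self, gain, protocol, clean_ground_truth):
        trace = syn.simulate_fluorescence_sweep(clean_ground_truth, protocol, 0.0, rng=0)
        window = slice(0, 100)
        np.testing.assert_allclose(
            tr.compute_dff(trace, window), tr.compute_dff(gain * trace, window),
            rtol=1e-9, atol=1e-12,
        )


class TestSummaryExtraction:
    def test_peak_of_monotone_rise_is_final_value(self):
        y = -np.expm1(-np.linspace(0, 5, 200))
        assert tr.extract_peak_current(y, slice(0, 200)) == pytest.approx(y[-1])

    def test_peak_of_zero_trace_is_zero(self):
        assert tr.extract_peak_current(np.zeros(100), slice(0, 100)) == 0.0

    def test_peak_is_signed(self):
        y = np.zeros(100)
        y[60] = -2.0
        assert tr.extract_peak_current(y, slice(0, 100)) == -2.0

    def test_steady_state_of_ideal_plateau(self):
        y = np.full(200, 1.5)
        assert tr.extract_steady_state_dff(y, slice(0, 200)) == pytest.approx(1.5)

    def test_steady_state_near_asymptote_for_slow_component(self):
        # double-exp rise, tau_slow = 50 ms: last 10% of a 250-ms pulse sits
        # within 1% of the asymptote
        t = np.linspace(0, 250, 1250)
        y = 0.9 * -np.expm1(-t / 5.0) + 0.1 * -np.expm1(-t / 50.0)
        est = tr.extract_steady_state_dff(y, slice(0, 1250), steady_fraction=0.1)
        assert est == pytest.approx(1.0, rel=0.01)


class TestEndToEnd:
    def test_zero_noise_tables_match_closed_form(self, protocol, clean_ground_truth):
        """With noise, bleach and filtering off and the true leak subtracted,
        the extracted (V, peak I) and (V, steady-state dF/F) tables equal the
        generator's closed-form predictions of the same estimators to 1e-9
        relative."""
        gt = clean_ground_truth
        ss = syn.simulate_sweepset(gt, protocol, rng=0)
        cfg = tr.ProcessingConfig(
            filter_cutoff_hz=None,
            peak_measurement_hz=None,
            known_leak=(gt.leak_offset, gt.leak_conductance),
        )
        processed = tr.process_sweepset(ss, cfg)
        v = processed.test_potentials
        # closed-form peak: I_ss * (1 - e^{-t_end/tau}) at the final sample
        t_end = (protocol.pulse_samples - 1) * protocol.dt_ms
        expected_peak = np.array(
            [
                float(gt.steady_state_current(pot))
                * -np.expm1(-t_end / gt.tau_act_by_v[pot])
                for pot in v
            ]
        )
        np.testing.assert_allclose(
            processed.peak_current, expected_peak, rtol=1e-9, atol=1e-12
        )
        # closed-form steady-state dF/F: analytic mean of the double-exp rise
        # over the final window (the baseline sweep subtracts its own tiny
        # deflection from every sweep)
        n_tail = int(round(0.1 * protocol.pulse_samples))
        t_pulse = np.arange(protocol.pulse_samples) * protocol.dt_ms

        def window_mean_dff(pot):
            tau_f, tau_s = gt.tau_fast_by_v[pot], gt.tau_slow_by_v[pot]
            f = gt.fast_fraction
            g = f * -np.expm1(-t_pulse / tau_f) + (1 - f) * -np.expm1(-t_pulse / tau_s)
            return float(gt.steady_state_dff(pot)) * np.mean(g[-n_tail:])

        baseline_pot = v[0]
        expected_dff = np.array(
            [window_mean_dff(pot) - window_mean_dff(baseline_pot) for pot in v]
        )
        np.testing.assert_allclose(
            processed.steady_state_dff, expected_dff, rtol=1e-9, atol=1e-12
        )

    def test_noisy_peak_within_three_noise_sd(self, protocol, ground_truth):
        ss = syn.simulate_sweepset(ground_truth, protocol, rng=6)
        processed = tr.process_sweepset(ss)
        v = processed.test_potentials
        i_ss = ground_truth.steady_state_current(v)
        np.testing.assert_allclose(
            processed.peak_current, i_ss, atol=3 * ground_truth.noise_sd_current
        )
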