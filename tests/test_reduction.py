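import math

import numpy as np
import pytest

from caspike.params import ModelParams, _coupling_matrix, _coupling_offsets, gating_steady
from caspike.protocols import figure_battery
from caspike.reduction import (CalciumWaveform, ThresholdError,
                               build_reduced_model, classify_event,
                               delta_input_threshold, detect_calcium_spike,
                               extract_waveform, min_conductance_for_spike,
                               slope_threshold_from_trace, threshold_by_epsp,
                               threshold_by_rate_mse, threshold_by_slope,
                               waveform_from_trace)
from caspike.simulator import integrate
from caspike.stimuli import invivo_ensemble


class TestDetection:
    def test_flat_trace_no_events(self):
        assert len(detect_calcium_spike(np.zeros(1000))) == 0

    def test_exact_threshold_not_detected(self):
        i = np.zeros(1000)
        i[100:150] = 1100.0
        assert len(detect_calcium_spike(i)) == 0  # strict "exceeds"

    def test_single_excursion(self):
        i = np.zeros(1000)
        i[200:250] = 1200.0
        events = detect_calcium_spike(i, dt=0.1)
        assert len(events) == 1
        assert events[0] == pytest.approx(20.0)

    @pytest.mark.parametrize("amp,expected", [
        (35.0, "full"), (29.9, "partial"), (30.0, "full")])
    def test_classification_boundary(self, amp, expected):
        assert classify_event(amp) == expected


class TestExtractWaveform:
    def test_identical_segments(self):
        seg = np.concatenate([np.linspace(0, 2000, 50),
                              np.linspace(2000, 0, 150)])
        wf = extract_waveform([seg] * 12, dt=0.1)
        np.testing.assert_allclose(wf.current, seg[:len(wf.current)])

    def test_integral_linearity(self):
        rng = np.random.default_rng(0)
        segs = [np.abs(rng.normal(1000, 100, 300)) for _ in range(15)]
        wf = extract_waveform(segs, dt=0.1)
        n = len(wf.current)
        per_seg = [s[:n].sum() * 0.1 for s in segs]
        assert wf.A == pytest.approx(np.mean(per_seg), rel=1e-9)

    def test_too_few_events(self):
        with pytest.raises(ValueError):
            extract_waveform([np.ones(10)] * 3, dt=0.1)

    def test_regime_b_peak_stereotypy(self, params, regime_b):
        # full calcium spikes have nearly identical peak amplitudes
        from caspike.reduction import event_segments
        _, tr = regime_b
        segs, _ = event_segments(tr, align="detection")
        peaks = np.array([s.max() for s in segs])
        assert len(peaks) >= 30
        assert peaks.std() / peaks.mean() < 0.1


class TestMinConductance:
    def test_bisection_matches_grid_scan(self, params):
        from caspike.reduction import _triggers
        a_bis = min_conductance_for_spike(params, 1.0, resolution=1.0)
        lo = int(a_bis) - 3
        grid = None
        for a in range(lo, lo + 8):
            ok, _ = _triggers(params, 1.0, float(a))
            if ok:
                grid = float(a)
                break
        assert grid is not None
        assert abs(a_bis - grid) <= 1.0

    def test_zero_calcium_never_triggers(self, params):
        with pytest.raises(ThresholdError):
            min_conductance_for_spike(params.replace(g_ca=1e-9), 1.0)


class TestSlopeThreshold:
    def test_monotone_trace_raises(self):
        t = np.arange(0, 100, 0.1)
        v = -70.0 + 40.0 * np.exp(-t / 20.0)  # no interior flattening
        with pytest.raises(ThresholdError):
            slope_threshold_from_trace(v, 0.1, onset=0.0, detection=90.0)

    def test_values_in_activation_zone(self, params):
        # thresholds lie near the gating half-activation voltages
        for tau_e in (0.0, 1.0, 5.0):
            v = threshold_by_slope(params, tau_e)
            assert -26.0 < v < -18.0

    def test_narrow_range_across_tau_e(self, params):
        vals = [threshold_by_slope(params, te) for te in (0.0, 0.5, 2.0)]
        assert max(vals) - min(vals) < 4.0


class TestEpspThreshold:
    def test_below_slope_threshold_for_slow_inputs(self, params):
        # slow inputs: the EPSP peak sits below the flattening voltage because
        # the calcium current adds on top of an already-decaying EPSP
        e = threshold_by_epsp(params, 5.0)
        s = threshold_by_slope(params, 5.0)
        assert e < s

    def test_delta_epsp_above_slope(self, params):
        # delta input overshoots: the peak EPSP exceeds the flattening voltage
        assert threshold_by_epsp(params, 0.0) > threshold_by_slope(params, 0.0)


class TestDeltaInputThreshold:
    def test_matches_dense_grid_oracle(self, params):
        v = delta_input_threshold(params)
        # independent oracle: locate the unstable intersection on a dense grid
        p = params
        def vd_of_m(m):
            G = _coupling_matrix(p, extra_g=(p.g_ca * m, 0.0, 0.0))
            b = np.array([p.g_l_d * p.U_l_d + p.g_ca * m * p.U_ca,
                          p.g_l_p * p.U_l_p, p.g_l_s * p.U_l_s])
            b += _coupling_offsets(p)
            return np.linalg.solve(G, b)[0]
        ms = np.linspace(1e-9, 1 - 1e-9, 100_000)
        g = np.array([gating_steady(vd_of_m(m), p.m_slope, p.m_half) - m
                      for m in ms])
        i = np.nonzero((g[:-1] < 0) & (g[1:] >= 0))[0][0]
        assert abs(v - vd_of_m(ms[i])) < 0.05

    def test_no_calcium_no_intersection(self, params):
        with pytest.raises(ThresholdError):
            delta_input_threshold(params.replace(g_ca=1e-9))

    def test_agrees_with_simulated_delta_threshold(self, params):
        fp = delta_input_threshold(params)
        sim = threshold_by_slope(params, 0.0)
        assert abs(fp - sim) < 1.5


class TestReducedModel:
    def test_missing_waveform_rejected(self, params):
        with pytest.raises(ValueError):
            build_reduced_model(params, CalciumWaveform(0.1, np.empty(0)))
        with pytest.raises(ValueError):
            build_reduced_model(params, CalciumWaveform(0.1, np.ones(10)))

    def test_subthreshold_identical_to_passive(self, params, beta_waveform):
        red = build_reduced_model(params, beta_waveform)
        from caspike.protocols import somatic_step
        trr = red.integrate(somatic_step(amplitude=300.0), duration=100.0,
                            spiking=False)
        trp = integrate(params, somatic_step(amplitude=300.0), duration=100.0,
                        mode="passive", spiking=False)
        assert len(trr.ca_trigger_times) == 0
        np.testing.assert_allclose(trr.V, trp.V, atol=1e-12)

    def test_injected_charge_equals_A(self, params, beta_waveform):
        from caspike.protocols import distal_beta
        red = build_reduced_model(params, beta_waveform)
        tr = red.integrate(distal_beta(), duration=300.0, spiking=False)
        assert len(tr.ca_trigger_times) == 1
        injected = tr.I_ca.sum() * tr.dt
        assert injected == pytest.approx(
            beta_waveform.current.sum() * beta_waveform.dt, rel=1e-9)

    def test_no_retrigger_during_waveform(self, params, beta_waveform):
        from caspike.protocols import distal_beta
        red = build_reduced_model(params, beta_waveform)
        tr = red.integrate(distal_beta(), duration=300.0)
        trig = tr.ca_trigger_times
        assert len(trig) >= 1
        if len(trig) > 1:
            assert np.diff(trig).min() >= beta_waveform.duration

    def test_battery_counts_match_kinetics(self, params, beta_waveform):
        red = build_reduced_model(params, beta_waveform)
        for name, prot in figure_battery().items():
            nk = len(integrate(params, prot, duration=200.0).spike_times)
            nr = len(red.integrate(prot, duration=200.0).spike_times)
            assert nk == nr, name


class TestRateMse:
    def test_single_entry_grid(self, params, beta_waveform):
        got = threshold_by_rate_mse(params, beta_waveform, [-24.0],
                                    p_grid=(0.5,), duration=3_000.0, seed=3)
        assert got == -24.0

    def test_empty_grid_rejected(self, params, beta_waveform):
        with pytest.raises(ValueError):
            threshold_by_rate_mse(params, beta_waveform, [])


class TestWaveformIO:
    def test_roundtrip(self, beta_waveform, tmp_path):
        path = tmp_path / "wave.tsv"
        beta_waveform.save(path)
        back = CalciumWaveform.load(path)
        np.testing.assert_allclose(back.current, beta_waveform.current,
                                   atol=1e-6)
        assert back.v_theta == pytest.approx(beta_waveform.v_theta)
        assert back.A == pytest.approx(beta_waveform.A, rel=1e-6)

    def test_negative_dt_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text('# {"dt_ms": -0.1, "V_theta_mV": -25.0}\n0\t0\n1\t1\n')
        with pytest.raises(ValueError):
            CalciumWaveform.load(path)

    def test_threshold_range_validated(self):
        with pytest.raises(ValueError):
            CalciumWaveform(0.1, np.ones(10), v_theta=100.0)
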