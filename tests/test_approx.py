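import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from caspike.approx import (FluctuationStats, LinearResponseModel,
                            campbell_stats, effective_conductance_analytic,
                            effective_conductance_semianalytic,
                            effective_conductance_semianalytic_1c,
                            first_order_response,
                            inhibitory_weight_for_target,
                            measure_calcium_somatic_potential,
                            stationary_mean, stats_from_trace)
from caspike.calibration import background_ensemble, mean_conductances
from caspike.params import ModelParams, resting_state
from caspike.reduction import CalciumWaveform
from caspike.simulator import integrate


class TestStationaryMean:
    def test_zero_conductances_is_rest(self, params):
        np.testing.assert_allclose(stationary_mean(params, (0,) * 3, (0,) * 3),
                                   resting_state(params), atol=1e-12)

    def test_campbell_mean_matches_long_simulation(self, params):
        w_e, w_i = 0.6, 1.0
        ge, gi = mean_conductances(params, w_e, w_i)
        predicted = stationary_mean(params, (ge,) * 3, (gi,) * 3)
        ens = background_ensemble(100_000.0, 21, w_e=w_e, w_i=w_i)
        tr = integrate(params.without_calcium(), ensemble=ens,
                       duration=100_000.0, mode="passive", spiking=False)
        simulated = tr.V[:, 5000:].mean(axis=1)
        np.testing.assert_allclose(simulated, predicted, atol=0.3)

    def test_calibrated_weights_give_minus_sixty(self, params):
        w_i = inhibitory_weight_for_target(params, 0.6, target=-60.0)
        ge, gi = mean_conductances(params, 0.6, w_i)
        vs = stationary_mean(params, (ge,) * 3, (gi,) * 3)[2]
        assert vs == pytest.approx(-60.0, abs=1e-3)


class TestLinearResponseModel:
    @given(ge=st.tuples(*[st.floats(0, 200)] * 3),
           gi=st.tuples(*[st.floats(0, 200)] * 3))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_eigenvalues_stable_for_nonneg_conductances(self, ge, gi):
        model = LinearResponseModel(ModelParams(), np.array(ge), np.array(gi))
        assert np.all(np.linalg.eigvals(model.M).real < 0)

    def test_zero_current_zero_response(self, params):
        model = LinearResponseModel(params, np.full(3, 3.0), np.full(3, 3.0))
        wf = CalciumWaveform(0.1, np.zeros(200))
        eps = first_order_response(model, wf, tail=50.0)
        assert np.abs(eps).max() == 0.0

    def test_single_compartment_delta_closed_form(self):
        # decoupled compartment, delta-like current of integral A:
        # eps(t) = (A/C) exp(-t (g_l + g) / C)
        p = ModelParams(g_pd=0.0, g_sp=0.0)
        g = 5.0
        model = LinearResponseModel(p, np.array([g, 0, 0]), np.zeros(3))
        dt = 0.1
        A = 500.0
        wave = np.zeros(400)
        wave[0] = A / dt
        eps = first_order_response(model, CalciumWaveform(dt, wave), tail=200.0)
        t = np.arange(1, eps.shape[1]) * dt
        expected = (A / p.C_d) * np.exp(-(p.g_l_d + g) * (t - dt) / p.C_d)
        # the discrete input is a one-step pulse, not a true delta: O(dt) bias
        np.testing.assert_allclose(eps[0, 1:], expected, rtol=1e-2)

    def test_matches_linear_ode_oracle(self, params, regime_b_waveform):
        from scipy.integrate import solve_ivp
        ge, gi = mean_conductances(params, 0.6, 1.76)
        model = LinearResponseModel(params, (ge,) * 3, (gi,) * 3)
        wf = regime_b_waveform
        eps = first_order_response(model, wf)
        M = model.M

        def rhs(t, y):
            k = int(t / wf.dt)
            u = wf.current[k] / params.C_d if k < len(wf.current) else 0.0
            return M @ y + np.array([u, 0.0, 0.0])

        t_eval = np.arange(eps.shape[1]) * wf.dt
        sol = solve_ivp(rhs, (0, t_eval[-1]), [0.0] * 3, t_eval=t_eval,
                        max_step=wf.dt / 4, rtol=1e-9, atol=1e-11)
        assert np.abs(eps - sol.y).max() < 1e-3

    def test_unstable_matrix_rejected(self, params):
        model = LinearResponseModel(params, np.full(3, -100.0), np.zeros(3))
        with pytest.raises(ValueError):
            first_order_response(model, CalciumWaveform(0.1, np.ones(10)))


class TestSemiAnalytic:
    def test_first_order_input_recovers_mean_conductance(self, params,
                                                         regime_b_waveform):
        # if the measured deviation equals the first-order prediction, the
        # effective conductance equals the mean synaptic conductance
        ge, gi = mean_conductances(params, 0.6, 1.76)
        model = LinearResponseModel(params, (ge,) * 3, (gi,) * 3)
        eps = first_order_response(model, regime_b_waveform, tail=3000.0,
                                   rel_floor=1e-12)
        integral = eps.sum(axis=1) * regime_b_waveform.dt
        g_eff = effective_conductance_semianalytic(integral,
                                                   regime_b_waveform.A, params)
        np.testing.assert_allclose(g_eff, ge + gi, rtol=1e-3)

    def test_reconstruction_identity(self, params, regime_b_waveform):
        # rebuilding the linear model with g_eff reproduces the integrals
        integral = np.array([900.0, 400.0, 250.0])
        g_eff = effective_conductance_semianalytic(integral,
                                                   regime_b_waveform.A, params)
        model = LinearResponseModel(params, g_eff, np.zeros(3))
        eps = first_order_response(model, regime_b_waveform, tail=5000.0,
                                   rel_floor=1e-12)
        rebuilt = eps.sum(axis=1) * regime_b_waveform.dt
        np.testing.assert_allclose(rebuilt, integral, rtol=1e-6)

    def test_monotone_in_integral_single_compartment(self):
        vals = [effective_conductance_semianalytic_1c(i, 1000.0, 10.0)
                for i in (50.0, 80.0, 120.0)]
        assert vals[0] > vals[1] > vals[2]

    def test_nonpositive_integral_rejected(self, params):
        with pytest.raises(ValueError):
            effective_conductance_semianalytic([0.0, 1.0, 1.0], 100.0, params)


class TestAnalytic:
    def _stats(self, **kw):
        base = dict(g_e_mean=3.0, g_i_mean=3.0, var_e=1.0, var_i=1.0,
                    tau_e=1.0, tau_i=2.0, g_l_total=30.0, C=100.0)
        base.update(kw)
        return FluctuationStats(**base)

    def test_zero_variance_reduces_to_means(self):
        s = self._stats(var_e=0.0, var_i=0.0)
        assert effective_conductance_analytic(s) == pytest.approx(6.0)

    def test_strictly_decreasing_in_variances(self):
        g0 = effective_conductance_analytic(self._stats())
        g_e = effective_conductance_analytic(self._stats(var_e=2.0))
        g_i = effective_conductance_analytic(self._stats(var_i=2.0))
        assert g_e < g0 and g_i < g0

    def test_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            self._stats(var_e=-1.0)

    def test_campbell_vs_empirical_stats(self, params):
        # cross-validate the analytic shot-noise moments against a simulation
        ens = background_ensemble(100_000.0, 31, w_e=0.6, w_i=1.0)
        tr = integrate(params.without_calcium(), ensemble=ens,
                       duration=100_000.0, mode="passive", spiking=False)
        ana = campbell_stats(params, 0, 0.6, 1.0)
        emp = stats_from_trace(tr, params, 0)
        assert emp.g_e_mean == pytest.approx(ana.g_e_mean, rel=0.05)
        assert emp.g_i_mean == pytest.approx(ana.g_i_mean, rel=0.05)
        assert emp.var_e == pytest.approx(ana.var_e, rel=0.1)
        assert emp.var_i == pytest.approx(ana.var_i, rel=0.1)


class TestMeasurement:
    def test_zero_amplitude_waveform_zero_deviation(self, params):
        bg = background_ensemble(20_000.0, 41, w_e=0.6, w_i=1.76)
        wf = CalciumWaveform(0.1, np.zeros(300), v_theta=-24.0)
        meas = measure_calcium_somatic_potential(params, wf, bg,
                                                 trigger="random",
                                                 event_rate=4.0,
                                                 min_events=10, seed=2)
        assert np.abs(meas["eps_mean"]).max() < 1e-12

    def test_random_trigger_conductances_flat(self, params, regime_b_waveform):
        bg = background_ensemble(40_000.0, 42, w_e=0.6, w_i=1.76)
        meas = measure_calcium_somatic_potential(params, regime_b_waveform, bg,
                                                 trigger="random",
                                                 event_rate=4.0,
                                                 min_events=50, seed=3)
        ge = meas["g_e_mean"][0]
        k0 = int(meas["lead_ms"] / meas["dt"])
        onset, tail = ge[k0], ge[-300:].mean()
        assert abs(onset - tail) / tail < 0.15

    def test_amplitude_neutrality_of_peak_ratio(self, params,
                                                regime_b_waveform):
        # halving/doubling the waveform amplitude leaves the
        # prediction/simulation peak ratio unchanged within sampling error
        ge, gi = mean_conductances(params, 0.6, 1.76)
        model = LinearResponseModel(params, (ge,) * 3, (gi,) * 3)
        bg = background_ensemble(60_000.0, 43, w_e=0.6, w_i=1.76)
        ratios = []
        for scale in (0.5, 2.0):
            wf = regime_b_waveform.scaled(scale)
            meas = measure_calcium_somatic_potential(params, wf, bg,
                                                     trigger="random",
                                                     event_rate=3.0,
                                                     min_events=100, seed=4)
            eps = first_order_response(model, wf)
            ratios.append(eps[2].max() / meas["peak_somatic"])
        assert ratios[0] == pytest.approx(ratios[1], rel=0.1)

    def test_too_few_events_rejected(self, params, regime_b_waveform):
        bg = background_ensemble(5_000.0, 44, w_e=0.6, w_i=1.76)
        with pytest.raises(ValueError):
            measure_calcium_somatic_potential(params, regime_b_waveform, bg,
                                              trigger="random",
                                              event_rate=1.0, min_events=100)
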