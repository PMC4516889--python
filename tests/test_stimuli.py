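import math

import numpy as np
import pytest
from scipy import integrate as sintegrate
from scipy import stats

from caspike.stimuli import (InputEnsemble, StimulusEvent, StimulusProtocol,
                             alpha_kernel, beta_kernel, beta_peak_time,
                             invivo_ensemble, jitter_events,
                             mean_jittered_conductance, mip_ensemble,
                             poisson_train)
from conftest import pairwise_count_correlation


class TestAlphaKernel:
    def test_zero_at_onset_and_before(self):
        assert alpha_kernel(0.6, 1.0, 0.0) == 0.0
        assert alpha_kernel(0.6, 1.0, -5.0) == 0.0

    def test_peak_at_tau_equals_weight(self):
        for w, tau in [(0.6, 1.0), (2.9, 0.2), (12.0, 5.0)]:
            assert alpha_kernel(w, tau, tau) == pytest.approx(w)
            t = np.linspace(0, 20 * tau, 4001)
            assert alpha_kernel(w, tau, t).max() == pytest.approx(w, rel=1e-4)

    def test_integral_closed_form(self):
        val, _ = sintegrate.quad(lambda t: alpha_kernel(0.6, 1.0, t), 0, 200)
        assert val == pytest.approx(0.6 * math.e * 1.0, rel=1e-6)  # ~1.631 pF

    def test_invalid_tau(self):
        with pytest.raises(ValueError):
            alpha_kernel(1.0, 0.0, 1.0)


class TestBetaKernel:
    def test_zero_at_onset(self):
        assert beta_kernel(2200.0, 5.0, 1.0, 0.0) == 0.0

    def test_peak_normalization_and_argmax(self):
        t = np.arange(0, 60, 0.0005)
        y = beta_kernel(2200.0, 5.0, 1.0, t)
        assert y.max() == pytest.approx(2200.0, rel=1e-6)
        # numeric argmax oracle vs closed form (5*1/4)*ln 5 ~ 2.012 ms
        assert t[np.argmax(y)] == pytest.approx(beta_peak_time(5.0, 1.0), abs=2e-3)
        assert beta_peak_time(5.0, 1.0) == pytest.approx(1.25 * math.log(5.0))

    def test_invalid_time_constants(self):
        with pytest.raises(ValueError):
            beta_kernel(1.0, 1.0, 5.0, 1.0)


class TestPoissonTrain:
    def test_zero_rate_empty(self):
        assert len(poisson_train(0.0, 1e6, np.random.default_rng(0))) == 0

    def test_negative_rate(self):
        with pytest.raises(ValueError):
            poisson_train(-1.0, 100.0, np.random.default_rng(0))

    def test_count_statistics(self):
        train = poisson_train(1.0, 1e6, np.random.default_rng(42))
        assert abs(len(train) - 1000) < 4 * math.sqrt(1000)

    def test_isi_distribution(self):
        # KS test of inter-spike intervals against Exp(rate)
        train = poisson_train(100.0, 101_000.0, np.random.default_rng(7))
        isi = np.diff(train[train > 1000.0])
        assert len(isi) > 9000
        stat, pval = stats.kstest(isi, "expon", args=(0, 10.0))  # mean 10 ms
        assert pval > 0.01

    def test_reproducible_under_seed(self):
        a = poisson_train(5.0, 1e5, np.random.default_rng(3))
        b = poisson_train(5.0, 1e5, np.random.default_rng(3))
        np.testing.assert_array_equal(a, b)


class TestMipEnsemble:
    def test_p_one_copies_mother(self):
        ens = mip_ensemble(1.0, 1.0, 5, 0, 1e5, seed=1)
        mother = np.array(ens.meta["mother_times"])
        for s in ens.spikes:
            np.testing.assert_allclose(np.sort(np.unique(s))[:len(mother)],
                                       mother)

    def test_p_zero_rate_preserved(self):
        ens = mip_ensemble(1.0, 0.0, 10, 0, 1e6, seed=2)
        rates = ens.rates()
        assert abs(rates.mean() - 1.0) < 0.05
        assert pairwise_count_correlation(ens.spikes, 1e6) < 0.02

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            mip_ensemble(1.0, 1.5, 2, 0, 1000.0, seed=0)

    def test_rates_approach_nu(self):
        ens = mip_ensemble(1.0, 0.5, 20, 5, 1e6, seed=3)
        np.testing.assert_allclose(ens.rates().mean(), 1.0, atol=0.05)


class TestJitterEvents:
    def test_sigma_zero_exact_shift(self):
        rng = np.random.default_rng(0)
        times = np.array([1.0, 5.0, 9.0])
        np.testing.assert_allclose(jitter_events(times, 200.0, 0.0, rng),
                                   times + 200.0)

    def test_far_from_truncation(self):
        rng = np.random.default_rng(1)
        d = jitter_events(np.zeros(10_000), 200.0, 1.0, rng)
        se = 1.0 / math.sqrt(10_000)
        assert abs(d.mean() - 200.0) < 3 * se

    def test_truncated_distribution_matches_rejection_oracle(self):
        # mu = 2, sigma = 8: heavy truncation; compare with an independent
        # rejection sampler via a two-sample KS test
        rng = np.random.default_rng(2)
        ours = jitter_events(np.zeros(20_000), 2.0, 8.0, rng)
        oracle_rng = np.random.default_rng(99)
        oracle = []
        while len(oracle) < 20_000:
            x = oracle_rng.normal(2.0, 8.0, size=10_000)
            oracle.extend(x[x >= 0].tolist())
        oracle = np.array(oracle[:20_000])
        assert ours.min() >= 0.0
        _, pval = stats.ks_2samp(ours, oracle)
        assert pval > 0.01


class TestMeanJitteredConductance:
    def test_sigma_zero_is_shift(self):
        dt = 0.1
        kern = alpha_kernel(0.6, 1.0, np.arange(0, 20, dt))
        out = mean_jittered_conductance(kern, dt, mu=5.0, sigma=0.0)
        k = int(5.0 / dt)
        np.testing.assert_allclose(out[k: k + len(kern)], kern)

    def test_mass_preserved_and_peak_spread(self):
        dt = 0.1
        kern = alpha_kernel(0.6, 1.0, np.arange(0, 30, dt))
        out = mean_jittered_conductance(kern, dt, mu=200.0, sigma=8.0)
        assert out.sum() * dt == pytest.approx(kern.sum() * dt, rel=1e-3)
        assert out.max() < kern.max()

    def test_matches_monte_carlo_mean(self):
        # empirical mean over 10^4 jittered kernels, < 1% RMS of the peak
        dt, mu, sigma = 0.1, 200.0, 8.0
        kern = alpha_kernel(0.6, 1.0, np.arange(0, 30, dt))
        pred = mean_jittered_conductance(kern, dt, mu, sigma)
        rng = np.random.default_rng(5)
        delays = jitter_events(np.zeros(10_000), mu, sigma, rng)
        tt = np.arange(len(pred)) * dt
        emp = np.zeros(len(pred))
        for d in delays:
            emp += alpha_kernel(0.6, 1.0, tt - d)
        emp /= len(delays)
        rms = math.sqrt(np.mean((pred - emp) ** 2))
        assert rms / pred.max() < 0.01


class TestProtocolAndEnsembleIO:
    def test_protocol_json_roundtrip(self, tmp_path):
        prot = StimulusProtocol().add(
            StimulusEvent("s", "step", 1000.0, 20.0, duration=5.0),
            StimulusEvent("d", "beta", 1100.0, 24.0, tau=(5.0, 1.0)))
        path = tmp_path / "prot.json"
        prot.save(path)
        assert StimulusProtocol.load(path).events == prot.events

    @pytest.mark.parametrize("kw", [
        dict(compartment="x", kind="step", amplitude=1.0, onset=0.0),
        dict(compartment="d", kind="step", amplitude=1.0, onset=-1.0),
        dict(compartment="d", kind="beta", amplitude=1.0, onset=0.0,
             tau=(1.0, 5.0)),
        dict(compartment="d", kind="step", amplitude=math.inf, onset=0.0),
    ])
    def test_invalid_events(self, kw):
        with pytest.raises(ValueError):
            StimulusEvent(**kw)

    def test_ensemble_text_roundtrip(self, tmp_path):
        ens = mip_ensemble(5.0, 0.5, 4, 2, 2000.0, seed=11)
        path = tmp_path / "ens.tsv"
        ens.save(path)
        back = InputEnsemble.load(path)
        assert back.n_synapses() == ens.n_synapses()
        for a, b in zip(back.spikes, ens.spikes):
            np.testing.assert_allclose(a, b, atol=1e-3)  # written at 0.1 us precision
        np.testing.assert_array_equal(back.compartment, ens.compartment)

    def test_invivo_ensemble_composition(self):
        ens = invivo_ensemble(5000.0, 1, n_e=100, n_i=25, frac_corr=0.2)
        assert ens.n_synapses() == 3 * 125
        # 20 correlated + 80 background excitatory at the distal compartment
        distal_exc = (ens.compartment == 0) & ens.excitatory
        assert distal_exc.sum() == 100
        assert (~ens.excitatory).sum() == 75
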