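"""Approximations of the calcium-evoked somatic potential in the fluctuation regime.

Treating the triggered calcium current as a perturbation of the stationary
bombarded neuron, the deviation eps(t) of the three compartment voltages obeys
a linear system.  Three levels of approximation are provided:

  first order      eps(t) = int_0^t exp((t-s) M) (I_ca(s)/C^d, 0, 0) ds with M
                   built from the *mean* synaptic conductances.
  semi-analytic    an effective conductance per compartment obtained from the
                   measured integral of eps: the fluctuating conductances are
                   replaced by constants chosen so the integral identity of the
                   linear system holds exactly; requires one paired simulation.
  analytic         a variance-corrected effective conductance
                   g_eff = (<g_e> - sigma_e^2/G0 * tau_e/(tau_e+tau_0))
                         + (<g_i> - sigma_i^2/G0 * tau_i/(tau_i+tau_0))
                   applied per compartment; fully predictive (the conductance
                   statistics follow from Campbell's theorem for alpha-kernel
                   shot noise).

The corrections matter because the synaptic conductances multiply the voltage:
the mean of g(t)*eps(t) contains Cov(g, eps), which grows with synaptic weight
and makes the naive first-order result underestimate the simulated response.

``measure_calcium_somatic_potential`` provides the simulation ground truth:
an event-aligned average of the voltage difference between two frozen-noise
twins, one receiving the calcium waveform (randomly timed or threshold-
triggered) and one not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .params import ModelParams, resting_state, _coupling_matrix
from .reduction import CalciumWaveform
from .simulator import DEFAULT_DT, integrate, _render_inputs
from .stimuli import InputEnsemble

__all__ = [
    "LinearResponseModel",
    "FluctuationStats",
    "stationary_mean",
    "first_order_response",
    "measure_calcium_somatic_potential",
    "effective_conductance_semianalytic",
    "effective_conductance_analytic",
    "campbell_stats",
    "inhibitory_weight_for_target",
]


def _caps(params: ModelParams) -> np.ndarray:
    return np.array([params.C_d, params.C_p, params.C_s])


@dataclass
class LinearResponseModel:
    """Stationary linear system of the bombarded passive neuron.

    ``g_e``/``g_i`` are the per-compartment mean (or effective) synaptic
    conductances entering the diagonal of the conductance matrix.
    """

    params: ModelParams
    g_e: np.ndarray
    g_i: np.ndarray

    def __post_init__(self):
        self.g_e = np.asarray(self.g_e, dtype=float)
        self.g_i = np.asarray(self.g_i, dtype=float)

    @property
    def G(self) -> np.ndarray:
        """Conductance matrix (nS): C dV/dt = -G V + b."""
        return _coupling_matrix(self.params, extra_g=self.g_e + self.g_i)

    @property
    def M(self) -> np.ndarray:
        """System matrix (1/ms): d(eps)/dt = M eps + input."""
        return -self.G / _caps(self.params)[:, None]

    def stationary(self) -> np.ndarray:
        """Stationary mean voltages (mV)."""
        return resting_state(self.params, g_e=self.g_e, g_i=self.g_i)

    def is_stable(self) -> bool:
        return bool(np.all(np.linalg.eigvals(self.M).real < 0))

    def propagator(self, dt: float):
        """(E, S) with E = exp(M dt) and S = M^-1 (E - I) (step-input kernel)."""
        E = linalg.expm(self.M * dt)
        S = np.linalg.solve(self.M, E - np.eye(3))
        return E, S


def stationary_mean(params: ModelParams, g_e, g_i) -> np.ndarray:
    """Stationary voltages for given mean conductances (no calcium, no BAP)."""
    return LinearResponseModel(params, g_e, g_i).stationary()


def first_order_response(model: LinearResponseModel, waveform: CalciumWaveform,
                         *, tail: float = 500.0, rel_floor: float = 1e-3
                         ) -> np.ndarray:
    """Linear-response deviation eps(t), shape (3, n), for the injected waveform.

    Propagates eps exactly under a piecewise-constant input
    u_k = (I_ca[k]/C^d, 0, 0); the output is truncated once |eps| falls below
    ``rel_floor`` of its peak (cap ``tail`` ms after the waveform ends).
    """
    if not model.is_stable():
        raise ValueError("linear-response matrix has a non-negative eigenvalue")
    dt = waveform.dt
    n_wave = len(waveform.current)
    n = n_wave + int(round(tail / dt))
    E, S = model.propagator(dt)
    eps = np.zeros((3, n))
    x = np.zeros(3)
    u = np.zeros(3)
    C_d = model.params.C_d
    for k in range(1, n):
        u[0] = waveform.current[k - 1] / C_d if k - 1 < n_wave else 0.0
        x = E @ x + S @ u
        eps[:, k] = x
    peak = np.abs(eps).max()
    if peak > 0:
        alive = np.nonzero(np.abs(eps).max(axis=0) > rel_floor * peak)[0]
        n_keep = min(n, max(int(alive[-1]) + 1, n_wave))
        eps = eps[:, :n_keep]
    return eps


# ---------------------------------------------------------------------------
# simulation measurement
# ---------------------------------------------------------------------------

def measure_calcium_somatic_potential(
        params: ModelParams, waveform: CalciumWaveform,
        ensemble: InputEnsemble, *, trigger: str = "random",
        event_rate: float = 2.0, min_events: int = 100,
        window: float = 250.0, dt: float = DEFAULT_DT, seed: int = 0) -> dict:
    """Mean voltage deviation caused by the calcium waveform under bombardment.

    Two frozen-noise twins consume the identical ensemble; the active twin
    receives the stored waveform as a distal current, either at random
    (Poisson, ``event_rate`` Hz, independent of the state) or threshold-
    triggered at waveform.v_theta.  Returns the event-aligned mean deviation
    per compartment, the event-aligned mean conductances, and the event count.
    """
    duration = ensemble.duration
    n_steps = int(round(duration / dt)) + 1
    rendered = _render_inputs(params, None, ensemble, dt, n_steps)
    passive = integrate(params.without_calcium(), duration=duration, dt=dt,
                        mode="passive", spiking=False, _rendered=rendered)
    wave = waveform.current
    if trigger == "random":
        # state-independent trigger times with a minimum separation of one
        # analysis window, so event-aligned tails do not overlap neighbours
        rng = np.random.default_rng(seed)
        spacing = max(1000.0 / event_rate, window + 70.0)
        base = np.arange(500.0, duration - window - 1.0, spacing)
        times = base + rng.uniform(0.0, spacing - window - 50.0, size=len(base))
        times = times[times < duration - window - 1.0]
        i_inj = rendered[0].copy()
        for t0 in times:
            k = int(round(t0 / dt))
            i_inj[0, k: k + len(wave)] += wave[: max(0, n_steps - k)][:len(i_inj[0, k:k + len(wave)])]
        active = integrate(params.without_calcium(), duration=duration, dt=dt,
                           mode="passive", spiking=False,
                           _rendered=(i_inj,) + rendered[1:])
        event_times = times
    elif trigger == "threshold":
        active = integrate(params.without_calcium(), duration=duration, dt=dt,
                           mode="reduced", waveform=wave,
                           v_theta=waveform.v_theta, spiking=False,
                           _rendered=rendered)
        event_times = active.ca_trigger_times
        event_times = event_times[(event_times > 500.0)
                                  & (event_times < duration - window - 1.0)]
    else:
        raise ValueError("trigger must be 'random' or 'threshold'")
    if len(event_times) < min_events:
        raise ValueError(f"only {len(event_times)} events, need {min_events}")

    eps = active.V - passive.V
    k_win = int(round(window / dt))
    k_lead = int(round(20.0 / dt))
    acc = np.zeros((3, k_win))
    acc_ge = np.zeros((3, k_lead + k_win))
    acc_gi = np.zeros((3, k_lead + k_win))
    n_used = 0
    for t0 in event_times:
        k = int(round(t0 / dt))
        if k - k_lead < 0 or k + k_win > eps.shape[1]:
            continue
        # per-event baseline: residual tails of earlier events average out
        base = eps[:, k - k_lead: k].mean(axis=1)
        acc += eps[:, k: k + k_win] - base[:, None]
        acc_ge += active.g_e[:, k - k_lead: k + k_win]
        acc_gi += active.g_i[:, k - k_lead: k + k_win]
        n_used += 1
    eps_mean = acc / n_used
    # integrals truncated once the deviation falls below 1e-3 of its peak
    integrals = np.empty(3)
    for c in range(3):
        x = eps_mean[c]
        pk = np.abs(x).max()
        alive = np.nonzero(np.abs(x) > 1e-3 * pk)[0]
        end = int(alive[-1]) + 1 if len(alive) else len(x)
        integrals[c] = x[:end].sum() * dt
    return {
        "dt": dt,
        "eps_mean": eps_mean,                       # (3, k_win), event-aligned
        "g_e_mean": acc_ge / n_used,                # includes 20 ms lead-in
        "g_i_mean": acc_gi / n_used,
        "lead_ms": 20.0,
        "n_events": n_used,
        "event_times": event_times,
        "eps_integral": integrals,                  # per compartment (mV*ms)
        "peak_somatic": float(eps_mean[2].max()),
    }


# ---------------------------------------------------------------------------
# effective conductances
# ---------------------------------------------------------------------------

def _m0(params: ModelParams) -> np.ndarray:
    """Constant coupling matrix (leaks + axial couplings, no synapses), nS."""
    return _coupling_matrix(params)


def effective_conductance_semianalytic(eps_integral, A: float,
                                       params: ModelParams) -> np.ndarray:
    """Effective conductance per compartment from the measured eps integrals.

    Solves the integral identity of the linear system for constant effective
    conductances: g_eff = diag(1/int eps) [(A, 0, 0)^T - M0 int eps], with M0
    the synapse-free coupling matrix.  Rebuilding the linear-response model
    with these conductances reproduces the measured integrals exactly.
    """
    I = np.asarray(eps_integral, dtype=float)
    if np.any(I <= 0):
        raise ValueError("eps integrals must be positive")
    rhs = np.array([A, 0.0, 0.0]) - _m0(params) @ I
    return rhs / I


def effective_conductance_semianalytic_1c(eps_integral: float, A: float,
                                          g_l: float) -> float:
    """Single-compartment form: g_eff = A / int(eps) - g_l."""
    if eps_integral <= 0:
        raise ValueError("eps integral must be positive")
    return A / eps_integral - g_l


@dataclass
class FluctuationStats:
    """Synaptic conductance statistics of one compartment.

    ``g_l_total`` is the compartment's synapse-free input conductance (leak
    plus axial couplings), which enters G0 = g_l_total + <g_e> + <g_i>.
    """

    g_e_mean: float
    g_i_mean: float
    var_e: float
    var_i: float
    tau_e: float
    tau_i: float
    g_l_total: float
    C: float

    def __post_init__(self):
        if self.var_e < 0 or self.var_i < 0:
            raise ValueError("variances must be non-negative")

    @property
    def G0(self) -> float:
        return self.g_l_total + self.g_e_mean + self.g_i_mean

    @property
    def tau0(self) -> float:
        if self.G0 <= 0:
            raise ValueError("total conductance must be positive")
        return self.C / self.G0


def campbell_stats(params: ModelParams, compartment: int, w_e: float,
                   w_i: float, *, n_e: int = 2000, n_i: int = 500,
                   rate: float = 1.0) -> FluctuationStats:
    """Analytic shot-noise statistics for alpha-kernel Poisson input.

    Campbell's theorem for the alpha kernel w*(e/tau)*t*exp(-t/tau):
    mean = R w e tau, variance = R w^2 e^2 tau / 4 (R the summed rate in 1/ms).
    """
    r_e = n_e * rate / 1000.0
    r_i = n_i * rate / 1000.0
    te, ti = params.tau_e, params.tau_i
    g_l = (params.g_l_d, params.g_l_p, params.g_l_s)[compartment]
    coup = (params.g_pd, params.g_pd + params.g_sp, params.g_sp)[compartment]
    C = _caps(params)[compartment]
    return FluctuationStats(
        g_e_mean=r_e * w_e * math.e * te,
        g_i_mean=r_i * w_i * math.e * ti,
        var_e=r_e * w_e ** 2 * math.e ** 2 * te / 4.0,
        var_i=r_i * w_i ** 2 * math.e ** 2 * ti / 4.0,
        tau_e=te, tau_i=ti, g_l_total=g_l + coup, C=C)


def stats_from_trace(trace, params: ModelParams, compartment: int, *,
                     burn: float = 500.0) -> FluctuationStats:
    """Empirical conductance statistics from a simulated trace."""
    k0 = int(round(burn / trace.dt))
    ge = trace.g_e[compartment, k0:]
    gi = trace.g_i[compartment, k0:]
    g_l = (params.g_l_d, params.g_l_p, params.g_l_s)[compartment]
    coup = (params.g_pd, params.g_pd + params.g_sp, params.g_sp)[compartment]
    return FluctuationStats(
        g_e_mean=float(ge.mean()), g_i_mean=float(gi.mean()),
        var_e=float(ge.var()), var_i=float(gi.var()),
        tau_e=params.tau_e, tau_i=params.tau_i,
        g_l_total=g_l + coup, C=_caps(params)[compartment])


def effective_conductance_analytic(stats: FluctuationStats) -> float:
    """Variance-corrected effective conductance of one compartment.

    g_eff = (<g_e> - sigma_e^2/G0 * tau_e/(tau_e + tau_0))
          + (<g_i> - sigma_i^2/G0 * tau_i/(tau_i + tau_0));
    reduces to <g_e> + <g_i> at zero variance and decreases in both variances.
    """
    s = stats
    t0 = s.tau0
    return (s.g_e_mean - s.var_e / s.G0 * s.tau_e / (s.tau_e + t0)
            + s.g_i_mean - s.var_i / s.G0 * s.tau_i / (s.tau_i + t0))


def inhibitory_weight_for_target(params: ModelParams, w_e: float,
                                 target: float = -60.0, *, n_e: int = 2000,
                                 n_i: int = 500, rate: float = 1.0) -> float:
    """w_i that holds the stationary mean somatic potential at ``target``."""
    from scipy import optimize
    r_e = n_e * rate / 1000.0
    r_i = n_i * rate / 1000.0

    def vs(w_i):
        ge = r_e * w_e * math.e * params.tau_e
        gi = r_i * w_i * math.e * params.tau_i
        return stationary_mean(params, (ge,) * 3, (gi,) * 3)[2] - target

    return float(optimize.brentq(vs, 1e-3, 100.0, xtol=1e-5))
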