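"""Deterministic stimulus kernels and stochastic synaptic input ensembles.

Deterministic side: step, alpha, beta and delta current events plus alpha
conductance events, collected in a :class:`StimulusProtocol`.

Stochastic side: independent Poisson trains, the multiple interaction process
(MIP) for correlated trains -- a Poisson "mother" train at rate nu thinned
independently into each target train with copy probability p, topped up with
an independent Poisson train at (1-p)*nu so every train has total rate nu and
any pair has spike-count correlation p -- and truncated-Gaussian jittering of
synchronous events.  The analytic mean conductance of a jittered kernel is its
convolution with the Gaussian delay density.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "StimulusEvent",
    "StimulusProtocol",
    "InputEnsemble",
    "alpha_kernel",
    "beta_kernel",
    "beta_peak_time",
    "poisson_train",
    "mip_ensemble",
    "invivo_ensemble",
    "jitter_events",
    "mean_jittered_conductance",
]

_COMP = {"d": 0, "p": 1, "s": 2}


def alpha_kernel(w: float, tau_s: float, t):
    """Alpha function w*(e/tau_s)*t*exp(-t/tau_s); peak value w at t = tau_s.

    ``w`` is the synaptic strength and the maximum amplitude (nS for
    conductances, pA for currents); the time integral is w*e*tau_s.
    """
    if tau_s <= 0:
        raise ValueError("tau_s must be > 0")
    t = np.asarray(t, dtype=float)
    out = np.where(t >= 0, w * (math.e / tau_s) * t * np.exp(-np.minimum(t, 1e6) / tau_s), 0.0)
    return float(out) if out.ndim == 0 else out


def beta_peak_time(tau_decay: float, tau_rise: float) -> float:
    """Argmax of the difference of exponentials exp(-t/decay) - exp(-t/rise)."""
    return math.log(tau_decay / tau_rise) * tau_decay * tau_rise / (tau_decay - tau_rise)


def beta_kernel(amplitude: float, tau_decay: float, tau_rise: float, t):
    """Peak-normalized difference of exponentials; maximum equals ``amplitude``.

    The raw shape exp(-t/tau_decay) - exp(-t/tau_rise) peaks at
    t* = ln(tau_decay/tau_rise) * tau_decay*tau_rise/(tau_decay - tau_rise);
    the output is scaled so its maximum is exactly ``amplitude``.
    """
    if tau_decay <= tau_rise:
        raise ValueError("beta kernel requires tau_decay > tau_rise > 0")
    if tau_rise <= 0:
        raise ValueError("tau_rise must be > 0")
    t_star = beta_peak_time(tau_decay, tau_rise)
    norm = math.exp(-t_star / tau_decay) - math.exp(-t_star / tau_rise)
    t = np.asarray(t, dtype=float)
    raw = np.where(t >= 0, np.exp(-t / tau_decay) - np.exp(-t / tau_rise), 0.0)
    out = amplitude * raw / norm
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class StimulusEvent:
    """One deterministic stimulation event.

    kind: 'step' (current, pA, needs duration), 'alpha' (current, pA),
    'beta' (current, pA, tau = (decay, rise)), 'delta' (current; ``amplitude``
    is the injected charge in pA*ms), 'alpha_cond_e'/'alpha_cond_i'
    (conductance, nS, uses the model's tau_e/tau_i), or 'delta_cond_e'
    (instantaneous excitatory conductance of time-integral ``amplitude`` in
    nS*ms = pF, the delta-input limit of a shrinking synaptic kernel).
    """

    compartment: str  # 'd' | 'p' | 's'
    kind: str
    amplitude: float
    onset: float
    duration: float = 0.0          # step only
    tau: tuple = ()                # alpha: (tau_s,); beta: (tau_decay, tau_rise)

    def __post_init__(self):
        if self.compartment not in _COMP:
            raise ValueError("compartment must be one of 'd', 'p', 's'")
        if self.onset < 0:
            raise ValueError("onset must be >= 0")
        if not math.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")
        if self.kind == "beta" and self.tau[1] >= self.tau[0]:
            raise ValueError("beta kernel requires rise < decay")


@dataclass
class StimulusProtocol:
    """Ordered list of stimulation events applied during a run."""

    events: list = field(default_factory=list)

    def add(self, *events: StimulusEvent) -> "StimulusProtocol":
        self.events.extend(events)
        return self

    # --- JSON I/O ----------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps([asdict(e) for e in self.events], indent=1)

    @classmethod
    def from_json(cls, text: str) -> "StimulusProtocol":
        events = [StimulusEvent(**{**e, "tau": tuple(e.get("tau", ()))})
                  for e in json.loads(text)]
        return cls(events=events)

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path) -> "StimulusProtocol":
        return cls.from_json(Path(path).read_text())

    # --- compilation to per-step arrays (used by the simulator) ------------

    def compile(self, dt: float, n_steps: int):
        """Render events onto the integration grid.

        Returns (i_inj, exc_w, inh_w, q_jump, g_jump): injected current per
        compartment and step (pA), binned alpha-conductance impulse weights
        (nS), delta-current charges (pA*ms) and delta-conductance integrals
        (nS*ms), each of shape (3, n_steps).
        """
        i_inj = np.zeros((3, n_steps))
        exc_w = np.zeros((3, n_steps))
        inh_w = np.zeros((3, n_steps))
        q_jump = np.zeros((3, n_steps))
        g_jump = np.zeros((3, n_steps))
        # i_inj[:, k] is the current over [t_k, t_{k+1}); smooth kernels are
        # sampled at the step midpoint (midpoint quadrature, 2nd order)
        t = (np.arange(n_steps) + 0.5) * dt
        for ev in self.events:
            c = _COMP[ev.compartment]
            k0 = int(round(ev.onset / dt))
            if k0 >= n_steps:
                continue
            if ev.kind == "step":
                k1 = min(n_steps, int(round((ev.onset + ev.duration) / dt)))
                i_inj[c, k0:k1] += ev.amplitude
            elif ev.kind == "alpha":
                i_inj[c, k0:] += alpha_kernel(ev.amplitude, ev.tau[0], t[: n_steps - k0])
            elif ev.kind == "beta":
                i_inj[c, k0:] += beta_kernel(ev.amplitude, ev.tau[0], ev.tau[1],
                                             t[: n_steps - k0])
            elif ev.kind == "delta":
                q_jump[c, k0] += ev.amplitude
            elif ev.kind == "alpha_cond_e":
                exc_w[c, k0] += ev.amplitude
            elif ev.kind == "alpha_cond_i":
                inh_w[c, k0] += ev.amplitude
            elif ev.kind == "delta_cond_e":
                g_jump[c, k0] += ev.amplitude
            else:
                raise ValueError(f"unknown stimulus kind {ev.kind!r}")
        return i_inj, exc_w, inh_w, q_jump, g_jump


# ---------------------------------------------------------------------------
# stochastic ensembles
# ---------------------------------------------------------------------------

@dataclass
class InputEnsemble:
    """Per-synapse spike-time lists with generator metadata.

    ``spikes`` is a list of float arrays (ms, sorted); ``compartment``/
    ``excitatory``/``weight`` are per-synapse metadata arrays of equal length.
    """

    spikes: list
    compartment: np.ndarray        # int codes 0=d, 1=p, 2=s
    excitatory: np.ndarray         # bool
    weight: np.ndarray             # nS
    duration: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.spikes)
        if not (len(self.compartment) == len(self.excitatory) == len(self.weight) == n):
            raise ValueError("metadata arrays must match the number of synapses")
        for s in self.spikes:
            if len(s) and (np.any(np.diff(s) < 0) or s[0] < 0):
                raise ValueError("spike times must be sorted and non-negative")

    def n_synapses(self) -> int:
        return len(self.spikes)

    def rates(self) -> np.ndarray:
        """Realized per-synapse rate in spikes/s."""
        return np.array([len(s) for s in self.spikes]) / self.duration * 1000.0

    # --- delimited-text + JSON sidecar I/O ---------------------------------

    def save(self, path) -> None:
        path = Path(path)
        with path.open("w") as f:
            f.write("synapse_id\ttime_ms\n")
            for i, s in enumerate(self.spikes):
                for ts in s:
                    f.write(f"{i}\t{ts:.4f}\n")
        sidecar = {
            "n_synapses": self.n_synapses(),
            "duration_ms": self.duration,
            "compartment": self.compartment.tolist(),
            "excitatory": [bool(x) for x in self.excitatory],
            "weight_nS": self.weight.tolist(),
            "meta": self.meta,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def load(cls, path) -> "InputEnsemble":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        n = sidecar["n_synapses"]
        spikes = [[] for _ in range(n)]
        with path.open() as f:
            next(f)
            for line in f:
                i, ts = line.split("\t")
                spikes[int(i)].append(float(ts))
        return cls(
            spikes=[np.array(s) for s in spikes],
            compartment=np.array(sidecar["compartment"]),
            excitatory=np.array(sidecar["excitatory"], dtype=bool),
            weight=np.array(sidecar["weight_nS"]),
            duration=sidecar["duration_ms"],
            meta=sidecar.get("meta", {}),
        )


def poisson_train(rate: float, duration: float, rng) -> np.ndarray:
    """Homogeneous Poisson spike train; rate in spikes/s, duration in ms."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0 or duration <= 0:
        return np.empty(0)
    n = rng.poisson(rate * duration / 1000.0)
    return np.sort(rng.uniform(0.0, duration, size=n))


def mip_ensemble(nu: float, p: float, n_corr: int, n_uncorr: int, duration: float,
                 seed, *, compartment: str = "d", excitatory: bool = True,
                 weight: float = 0.6, jitter_mu: float = 0.0,
                 jitter_sigma: float = 0.0,
                 compensate_rate: bool = True) -> InputEnsemble:
    """Multiple-interaction-process ensemble plus independent background trains.

    Each of the ``n_corr`` correlated trains is a p-thinned copy of one shared
    mother Poisson train at rate ``nu``, merged (``compensate_rate``, the
    default) with an independent Poisson train at (1-p)*nu so that every train
    has total expected rate ``nu``; each of the ``n_uncorr`` trains is
    independent Poisson at ``nu``.  Pairwise spike-count correlations:
    the bare thinned process (``compensate_rate=False``, per-train rate nu*p)
    has correlation p; the rate-compensated trains have correlation p^2 — the
    independent top-up adds count variance without covariance.  If
    ``jitter_sigma`` > 0 (or ``jitter_mu`` != 0) each copied mother spike is
    delayed by an independent truncated-Gaussian draw, emulating imprecise
    synchrony.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("copy probability p must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    mother = poisson_train(nu, duration, rng)
    spikes = []
    for _ in range(n_corr):
        keep = mother[rng.random(len(mother)) < p]
        if jitter_sigma > 0 or jitter_mu != 0:
            keep = jitter_events(keep, jitter_mu, jitter_sigma, rng)
        if compensate_rate:
            indep = poisson_train((1.0 - p) * nu, duration, rng)
            keep = np.sort(np.concatenate([keep, indep]))
        spikes.append(keep)
    for _ in range(n_uncorr):
        spikes.append(poisson_train(nu, duration, rng))
    n = n_corr + n_uncorr
    return InputEnsemble(
        spikes=spikes,
        compartment=np.full(n, _COMP[compartment]),
        excitatory=np.full(n, excitatory, dtype=bool),
        weight=np.full(n, weight, dtype=float),
        duration=duration,
        meta={"nu": nu, "p": p, "n_corr": n_corr, "n_uncorr": n_uncorr,
              "compensate_rate": compensate_rate,
              "jitter_mu": jitter_mu, "jitter_sigma": jitter_sigma,
              "seed": int(seed) if np.isscalar(seed) else None,
              "mother_times": mother.tolist()},
    )


def invivo_ensemble(duration: float, seed, *, w_e: float = 0.6, w_i: float = 1.0,
                    n_e: int = 2000, n_i: int = 500, rate: float = 1.0,
                    frac_corr: float = 0.2, p_copy: float = 0.5,
                    mother_rate: float = 1.0, jitter_mu: float = 0.0,
                    jitter_sigma: float = 0.0) -> InputEnsemble:
    """The fluctuation-regime embedding: background bombardment plus synchrony.

    Every compartment receives ``n_e`` excitatory and ``n_i`` inhibitory
    independent Poisson synapses at ``rate`` spikes/s; a fraction ``frac_corr``
    of the *distal excitatory* synapses is instead driven by a multiple
    interaction process with copy probability ``p_copy`` (total per-synapse
    rate still ``rate``), optionally with truncated-Gaussian jitter of the
    copied mother spikes.  The mother spike times are stored in ``meta`` so
    synchronous events can be located afterwards.
    """
    rng = np.random.default_rng(seed)
    n_corr = int(round(frac_corr * n_e))
    mip = mip_ensemble(mother_rate, p_copy, n_corr, 0, duration,
                       rng.integers(2 ** 31), weight=w_e,
                       jitter_mu=jitter_mu, jitter_sigma=jitter_sigma) \
        if n_corr else None
    spikes = list(mip.spikes) if mip else []
    comp = [0] * n_corr
    exc = [True] * n_corr
    w = [w_e] * n_corr
    for c in range(3):
        ne = n_e - n_corr if c == 0 else n_e
        for _ in range(ne):
            spikes.append(poisson_train(rate, duration, rng))
            comp.append(c); exc.append(True); w.append(w_e)
        for _ in range(n_i):
            spikes.append(poisson_train(rate, duration, rng))
            comp.append(c); exc.append(False); w.append(w_i)
    return InputEnsemble(
        spikes=spikes, compartment=np.array(comp),
        excitatory=np.array(exc, dtype=bool), weight=np.array(w, dtype=float),
        duration=duration,
        meta={"rate": rate, "frac_corr": frac_corr, "p_copy": p_copy,
              "w_e": w_e, "w_i": w_i,
              "jitter_mu": jitter_mu, "jitter_sigma": jitter_sigma,
              "mother_times": mip.meta["mother_times"] if mip else []},
    )


def jitter_events(times, mu: float, sigma: float, rng) -> np.ndarray:
    """Delay each event by an independent Gaussian(mu, sigma) truncated at zero.

    Truncation is by rejection (resampling until the delay is >= 0), not by
    clipping, so no point mass accumulates at zero delay.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    times = np.asarray(times, dtype=float)
    if sigma == 0:
        return np.sort(times + mu)
    delays = rng.normal(mu, sigma, size=len(times))
    bad = delays < 0
    while np.any(bad):
        delays[bad] = rng.normal(mu, sigma, size=int(bad.sum()))
        bad = delays < 0
    return np.sort(times + delays)


def mean_jittered_conductance(kernel: np.ndarray, dt: float, mu: float,
                              sigma: float) -> np.ndarray:
    """Mean conductance of a jittered kernel: the kernel convolved with N(mu, sigma^2).

    Numeric convolution on the kernel's grid; mass is preserved (the output
    integral equals the input integral) and the peak can only spread.  The
    returned waveform is evaluated on an extended grid long enough to hold the
    shifted, broadened response; its length is len(kernel) + ceil((mu+6*sigma)/dt).
    """
    kernel = np.asarray(kernel, dtype=float)
    pad = int(math.ceil((mu + 6.0 * sigma) / dt)) + 1
    n_out = len(kernel) + pad
    if sigma == 0:
        out = np.zeros(n_out)
        shift = int(round(mu / dt))
        out[shift:shift + len(kernel)] = kernel[: max(0, n_out - shift)]
        return out
    tg = np.arange(-pad, pad + 1) * dt
    gauss = stats.norm.pdf(tg, loc=mu, scale=sigma)
    gauss /= gauss.sum() * dt  # exact discrete mass 1/dt per unit impulse
    out = np.convolve(kernel, gauss * dt, mode="full")[pad: pad + n_out]
    return out
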