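"""Fixed-step simulation of the model under protocols and input ensembles.

``integrate`` runs one model (kinetics, reduced, or passive) at a fixed step
(0.1 ms by default, matching the convention of grid-based spiking simulators),
``paired_run`` runs an active and a passive twin on the *identical realized
input* (frozen noise) and returns their voltage difference, and
``collect_events`` slices a difference trace into event-aligned segments.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _core
from .params import ModelParams, ModelState, gating_steady
from .stimuli import InputEnsemble, StimulusProtocol

__all__ = [
    "Trace",
    "DifferenceTrace",
    "IntegrationError",
    "integrate",
    "paired_run",
    "collect_events",
]

DEFAULT_DT = 0.1  # ms


class IntegrationError(RuntimeError):
    """Non-finite state encountered during integration."""


@dataclass
class Trace:
    """Uniformly sampled recording of one run."""

    dt: float
    V: np.ndarray            # (3, n): distal, proximal, somatic voltage (mV)
    I_ca: np.ndarray         # (n,) calcium (or injected waveform) current (pA)
    g_e: np.ndarray          # (3, n) total excitatory conductance (nS)
    g_i: np.ndarray          # (3, n)
    theta: np.ndarray        # (n,) adaptive threshold (mV)
    spike_times: np.ndarray  # (ms, on the grid)
    ca_trigger_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self):
        n = self.V.shape[1]
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if not (len(self.I_ca) == n and self.g_e.shape[1] == n
                and self.g_i.shape[1] == n and len(self.theta) == n):
            raise ValueError("trace channels must have equal length")

    @property
    def n(self) -> int:
        return self.V.shape[1]

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n) * self.dt

    @property
    def duration(self) -> float:
        return (self.n - 1) * self.dt

    def save_csv(self, path) -> None:
        cols = np.column_stack([
            self.time, self.V[0], self.V[1], self.V[2], self.I_ca,
            self.g_e[0], self.g_e[1], self.g_e[2],
            self.g_i[0], self.g_i[1], self.g_i[2], self.theta,
        ])
        header = ("time_ms,V_d_mV,V_p_mV,V_s_mV,I_ca_pA,"
                  "g_e_d_nS,g_e_p_nS,g_e_s_nS,g_i_d_nS,g_i_p_nS,g_i_s_nS,theta_mV")
        np.savetxt(path, cols, delimiter=",", header=header, comments="")
        side = {"dt_ms": self.dt,
                "spike_times_ms": self.spike_times.tolist(),
                "ca_trigger_times_ms": self.ca_trigger_times.tolist()}
        Path(str(path) + ".json").write_text(json.dumps(side))

    @classmethod
    def load_csv(cls, path) -> "Trace":
        data = np.loadtxt(path, delimiter=",", skiprows=1).T
        side = json.loads(Path(str(path) + ".json").read_text())
        return cls(dt=side["dt_ms"], V=data[1:4], I_ca=data[4],
                   g_e=data[5:8], g_i=data[8:11], theta=data[11],
                   spike_times=np.array(side["spike_times_ms"]),
                   ca_trigger_times=np.array(side["ca_trigger_times_ms"]))

    def save_h5(self, path) -> None:
        import h5py
        with h5py.File(path, "w") as f:
            f.attrs["dt_ms"] = self.dt
            for name in ("V", "I_ca", "g_e", "g_i", "theta",
                         "spike_times", "ca_trigger_times"):
                f.create_dataset(name, data=getattr(self, name))

    @classmethod
    def load_h5(cls, path) -> "Trace":
        import h5py
        with h5py.File(path, "r") as f:
            return cls(dt=float(f.attrs["dt_ms"]),
                       **{k: f[k][...] for k in ("V", "I_ca", "g_e", "g_i",
                                                 "theta", "spike_times",
                                                 "ca_trigger_times")})


@dataclass
class DifferenceTrace:
    """Voltage difference, active model minus passive model, per compartment."""

    dt: float
    eps: np.ndarray          # (3, n): eps_d, eps_p, eps_s (mV)
    event_times: np.ndarray  # known trigger/synchronous-event times (ms), may be empty

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.eps.shape[1]) * self.dt


def _bin_ensemble(ensemble: InputEnsemble | None, dt: float, n_steps: int):
    """Histogram ensemble spikes into per-step weighted impulse sums."""
    exc = np.zeros((3, n_steps))
    inh = np.zeros((3, n_steps))
    if ensemble is None:
        return exc, inh
    for c in range(3):
        for is_exc, target in ((True, exc), (False, inh)):
            sel = (ensemble.compartment == c) & (ensemble.excitatory == is_exc)
            idx = np.nonzero(sel)[0]
            if len(idx) == 0:
                continue
            times = np.concatenate([ensemble.spikes[i] for i in idx])
            weights = np.concatenate([
                np.full(len(ensemble.spikes[i]), ensemble.weight[i]) for i in idx
            ])
            bins = np.round(times / dt).astype(np.int64)
            ok = bins < n_steps
            target[c] += np.bincount(bins[ok], weights=weights[ok], minlength=n_steps)
    return exc, inh


def _render_inputs(params, protocol, ensemble, dt, n_steps):
    if protocol is not None:
        i_inj, exc_w, inh_w, q_jump, g_jump = protocol.compile(dt, n_steps)
    else:
        i_inj = np.zeros((3, n_steps))
        exc_w = np.zeros((3, n_steps))
        inh_w = np.zeros((3, n_steps))
        q_jump = np.zeros((3, n_steps))
        g_jump = np.zeros((3, n_steps))
    exc, inh = _bin_ensemble(ensemble, dt, n_steps)
    return i_inj, exc_w + exc, inh_w + inh, q_jump, g_jump


def integrate(params: ModelParams, protocol: StimulusProtocol | None = None,
              ensemble: InputEnsemble | None = None, *, duration: float = 200.0,
              dt: float = DEFAULT_DT, mode: str = "kinetics",
              waveform: np.ndarray | None = None, v_theta: float = np.nan,
              spiking: bool = True, v0=None, _rendered=None) -> Trace:
    """Integrate the model for ``duration`` ms and return a full Trace.

    ``mode`` is 'kinetics' (first-order calcium), 'reduced' (threshold-
    triggered fixed waveform; requires ``waveform`` and ``v_theta``), or
    'passive' (no calcium).  The run starts at rest unless ``v0`` is given.
    Raises :class:`IntegrationError` if the state diverges.
    """
    mode_code = {"kinetics": 0, "reduced": 1, "passive": 2}[mode]
    if mode == "reduced":
        if waveform is None or not np.isfinite(v_theta):
            raise ValueError("reduced mode requires waveform and v_theta")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n_steps = int(round(duration / dt)) + 1
    if _rendered is None:
        _rendered = _render_inputs(params, protocol, ensemble, dt, n_steps)
    i_inj, exc_imp, inh_imp, q_jump, g_jump = _rendered
    if v0 is None:
        v0 = np.array([params.U_l_d, params.U_l_p, params.U_l_s])
    else:
        v0 = np.asarray(v0, dtype=float)
    m0 = gating_steady(v0[0], params.m_slope, params.m_half)
    h0 = gating_steady(v0[0], params.h_slope, params.h_half)
    wave = waveform if waveform is not None else np.empty(0)
    out = _core.run_core(
        dt, n_steps, _core.pack_params(params),
        exc_imp, inh_imp, i_inj, q_jump, g_jump,
        mode_code, np.asarray(wave, dtype=float), float(v_theta),
        spiking, v0, m0, h0, params.theta_base,
    )
    V, ica, ge, gi, theta, spike_steps, trig_steps = out
    if not np.isfinite(V[:, -1]).all() or not np.isfinite(V).all():
        bad = np.nonzero(~np.isfinite(V).all(axis=0))[0]
        raise IntegrationError(f"integration diverged at t = {bad[0] * dt:.1f} ms")
    return Trace(dt=dt, V=V, I_ca=ica, g_e=ge, g_i=gi, theta=theta,
                 spike_times=spike_steps * dt,
                 ca_trigger_times=trig_steps * dt)


def paired_run(params_active: ModelParams, params_passive: ModelParams,
               protocol: StimulusProtocol | None = None,
               ensemble: InputEnsemble | None = None, *,
               duration: float = 200.0, dt: float = DEFAULT_DT,
               mode_active: str = "kinetics",
               waveform: np.ndarray | None = None, v_theta: float = np.nan,
               spiking: bool = False, event_times=None):
    """Frozen-noise pair: active and passive model on identical realized input.

    Both models consume the same rendered stimuli and the same spike times.
    Returns (active Trace, passive Trace, DifferenceTrace).  ``event_times``
    (optional) annotates the difference trace with known synchronous-event or
    trigger times; for the reduced model the realized trigger times are used
    when not given.
    """
    n_steps = int(round(duration / dt)) + 1
    rendered = _render_inputs(params_active, protocol, ensemble, dt, n_steps)
    active = integrate(params_active, duration=duration, dt=dt, mode=mode_active,
                       waveform=waveform, v_theta=v_theta, spiking=spiking,
                       _rendered=rendered)
    passive = integrate(params_passive, duration=duration, dt=dt, mode="passive",
                        spiking=spiking, _rendered=rendered)
    eps = active.V - passive.V
    if event_times is None:
        event_times = active.ca_trigger_times
    diff = DifferenceTrace(dt=dt, eps=eps, event_times=np.asarray(event_times, float))
    return active, passive, diff


def collect_events(diff: DifferenceTrace, *, floor: float = 0.001,
                   window: tuple = (-10.0, 150.0), event_times=None,
                   compartment: int = 0) -> list:
    """Event-aligned segments of the difference trace.

    If ``event_times`` (or ``diff.event_times``) is given, segments are aligned
    at those times; otherwise events are detected as contiguous excursions of
    the chosen compartment's difference above ``floor`` (mV) and aligned at the
    excursion onset.  Each segment is a dict with 't' (ms, relative), 'eps'
    (3, len) and 'amplitude' (max distal difference in the window).
    """
    eps = diff.eps
    n = eps.shape[1]
    if n == 0:
        raise ValueError("empty difference trace")
    dt = diff.dt
    if event_times is None and len(diff.event_times):
        event_times = diff.event_times
    if event_times is None:
        above = eps[compartment] > floor
        starts = np.nonzero(above & ~np.roll(above, 1))[0]
        if above[0]:
            starts = np.unique(np.concatenate([[0], starts]))
        event_times = starts * dt
    k_lo = int(round(window[0] / dt))
    k_hi = int(round(window[1] / dt))
    rel_t = np.arange(k_lo, k_hi) * dt
    segments = []
    for t0 in np.asarray(event_times, dtype=float):
        k = int(round(t0 / dt))
        if k + k_lo < 0 or k + k_hi > n:
            continue
        seg = eps[:, k + k_lo: k + k_hi]
        amp = float(seg[0].max())
        if amp <= floor:
            continue
        segments.append({"t": rel_t, "eps": seg, "amplitude": amp,
                         "onset_ms": t0})
    return segments
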