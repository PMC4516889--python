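"""Calcium-event detection, waveform extraction, thresholds, reduced model.

A calcium spike is detected when I_ca exceeds 1100 pA (strict), and classified
*full* when the distal voltage excursion (active minus passive) reaches 30 mV.
The fixed waveform of the reduced model is the pointwise mean of event-aligned
calcium currents; the trigger threshold V_theta is determined four ways:

  threshold_by_slope     V^d at the flattest point (minimal |dV/dt|) of the
                         minimal spike-triggering trajectory
  threshold_by_epsp      peak distal EPSP of the minimal triggering stimulus
                         with calcium disabled
  delta_input_threshold  analytic fixed point of the steady-state system with
                         adiabatic activation (m = m_inf, h = 1)
  threshold_by_rate_mse  the reduced-model threshold whose firing-rate-vs-
                         correlation curve best matches the kinetics model

The reduced model replaces the gated calcium current by injection of the
stored waveform whenever V^d crosses V_theta from below, with a lockout for
the waveform duration to prevent self-retriggering.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .params import ModelParams, _coupling_matrix, _coupling_offsets, gating_steady
from .simulator import DEFAULT_DT, Trace, integrate
from .stimuli import StimulusEvent, StimulusProtocol, invivo_ensemble

__all__ = [
    "CA_DETECTION_PA",
    "FULL_EVENT_MV",
    "CalciumWaveform",
    "ThresholdError",
    "detect_calcium_spike",
    "classify_event",
    "extract_waveform",
    "waveform_from_trace",
    "min_conductance_for_spike",
    "threshold_by_slope",
    "threshold_by_epsp",
    "threshold_by_rate_mse",
    "delta_input_threshold",
    "build_reduced_model",
    "ReducedModel",
]

CA_DETECTION_PA = 1100.0
FULL_EVENT_MV = 30.0


class ThresholdError(RuntimeError):
    """No threshold / no triggering stimulus found."""


@dataclass
class CalciumWaveform:
    """Sampled fixed calcium-current waveform with its trigger threshold."""

    dt: float
    current: np.ndarray          # pA, starting at the trigger time
    v_theta: float = np.nan      # mV
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        self.current = np.asarray(self.current, dtype=float)
        if np.isfinite(self.v_theta) and not -80.0 < self.v_theta < 40.0:
            raise ValueError("trigger threshold outside physiological range")

    @property
    def A(self) -> float:
        """Time integral of the current (pA*ms).

        The stored samples are step values on the integration grid (that is
        how the reduced model injects them), so the integral is the rectangle
        sum -- exactly the charge one triggered event delivers.
        """
        return float(self.current.sum() * self.dt)

    @property
    def duration(self) -> float:
        return len(self.current) * self.dt

    def scaled(self, factor: float) -> "CalciumWaveform":
        return CalciumWaveform(self.dt, self.current * factor, self.v_theta,
                               {**self.provenance, "scaled_by": factor})

    def save(self, path) -> None:
        path = Path(path)
        header = json.dumps({"dt_ms": self.dt, "V_theta_mV": self.v_theta,
                             "A_pA_ms": self.A, "provenance": self.provenance})
        t = np.arange(len(self.current)) * self.dt
        np.savetxt(path, np.column_stack([t, self.current]),
                   delimiter="\t", header=header, comments="# ")

    @classmethod
    def load(cls, path) -> "CalciumWaveform":
        path = Path(path)
        with path.open() as f:
            meta = json.loads(f.readline().lstrip("# ").strip())
        data = np.loadtxt(path, delimiter="\t")
        if meta["dt_ms"] <= 0:
            raise ValueError("waveform file has non-positive dt")
        return cls(dt=meta["dt_ms"], current=data[:, 1],
                   v_theta=meta.get("V_theta_mV", np.nan),
                   provenance=meta.get("provenance", {}))


# ---------------------------------------------------------------------------
# detection / classification / extraction
# ---------------------------------------------------------------------------

def detect_calcium_spike(i_ca: np.ndarray, dt: float = DEFAULT_DT,
                         threshold: float = CA_DETECTION_PA) -> np.ndarray:
    """Event times (ms): one per contiguous excursion strictly above threshold."""
    above = np.asarray(i_ca) > threshold
    if not above.any():
        return np.empty(0)
    onsets = np.nonzero(above & ~np.roll(above, 1))[0]
    if above[0]:
        onsets = np.unique(np.concatenate([[0], onsets]))
    return onsets * dt


def classify_event(max_excursion_mv: float) -> str:
    """'full' iff the distal voltage excursion reaches 30 mV (inclusive)."""
    return "full" if max_excursion_mv >= FULL_EVENT_MV else "partial"


def extract_waveform(segments, dt: float = DEFAULT_DT, *, v_theta: float = np.nan,
                     min_events: int = 10, provenance: dict | None = None
                     ) -> CalciumWaveform:
    """Pointwise mean of event-aligned calcium-current segments.

    ``segments`` is a sequence of equal-length arrays aligned at the trigger
    sample (baseline already subtracted).  The mean is truncated after its peak
    once it falls below 1 pA (cap 200 ms).
    """
    segments = np.asarray(list(segments), dtype=float)
    if len(segments) < min_events:
        raise ValueError(f"need at least {min_events} events, got {len(segments)}")
    mean = segments.mean(axis=0)
    pk = int(mean.argmax())
    below = np.nonzero(mean[pk:] < 1.0)[0]
    cut = pk + (int(below[0]) if len(below) else len(mean) - pk)
    cut = min(cut, int(round(200.0 / dt)))
    prov = dict(provenance or {})
    prov["n_events"] = int(len(segments))
    return CalciumWaveform(dt=dt, current=mean[:cut], v_theta=v_theta,
                           provenance=prov)


def event_segments(trace: Trace, *, lead: float = 10.0, length: float = 150.0,
                   align: str = "detection", v_theta: float = np.nan):
    """Baseline-subtracted I_ca segments around each detected calcium spike.

    ``align`` is 'detection' (first sample above 1100 pA) or 'crossing' (last
    upward crossing of ``v_theta`` by V^d before detection).  Segments start at
    the alignment sample; the baseline is the mean over the ``lead`` ms before
    it.  Returns (segments, lead_segments) where lead_segments include the
    lead-in (for stereotypy measures on the full window).
    """
    dt = trace.dt
    ica = trace.I_ca
    k_lead = int(round(lead / dt))
    k_len = int(round(length / dt))
    onsets = (detect_calcium_spike(ica, dt) / dt).astype(int)
    if align == "crossing":
        vd = trace.V[0]
        cross = np.nonzero((vd[:-1] < v_theta) & (vd[1:] >= v_theta))[0] + 1
    segs, lead_segs = [], []
    for k in onsets:
        if align == "crossing":
            prior = cross[cross <= k]
            if len(prior) == 0:
                continue
            k = int(prior[-1])
        if k - k_lead < 0 or k + k_len > len(ica):
            continue
        base = ica[k - k_lead: k].mean()
        segs.append(ica[k: k + k_len] - base)
        lead_segs.append(ica[k - k_lead: k + k_len] - base)
    return segs, lead_segs


def waveform_from_trace(trace: Trace, *, v_theta: float = np.nan,
                        align: str = "detection", lead: float = 10.0,
                        length: float = 150.0, min_events: int = 10,
                        provenance: dict | None = None) -> CalciumWaveform:
    """Extract the mean waveform from one simulation run."""
    segs, _ = event_segments(trace, lead=lead, length=length, align=align,
                             v_theta=v_theta)
    return extract_waveform(segs, trace.dt, v_theta=v_theta,
                            min_events=min_events, provenance=provenance)


# ---------------------------------------------------------------------------
# minimal triggering stimulus and thresholds
# ---------------------------------------------------------------------------

def _probe_protocol(tau_e: float, integral_pf: float, onset: float = 20.0
                    ) -> StimulusProtocol:
    """Distal excitatory conductance event of the given time integral (pF).

    tau_e = 0 denotes the delta-input limit (instantaneous conductance).
    """
    if tau_e == 0.0:
        ev = StimulusEvent("d", "delta_cond_e", integral_pf, onset)
    else:
        w = integral_pf / (math.e * tau_e)  # alpha integral = w*e*tau_e
        ev = StimulusEvent("d", "alpha_cond_e", w, onset)
    return StimulusProtocol().add(ev)


def _triggers(params: ModelParams, tau_e: float, integral_pf: float,
              duration: float = 300.0):
    """Full-calcium-spike indicator for a single distal conductance event.

    A probe counts as triggering when the calcium current exceeds the
    detection level *and* the distal voltage excursion relative to the
    calcium-free twin reaches the full-event classification (30 mV): for fast
    (delta-like) inputs the gating transient alone can graze the current
    detection level without a regenerative event.
    """
    p = params if (tau_e == 0.0 or params.tau_e == tau_e) \
        else params.replace(tau_e=tau_e)
    prot = _probe_protocol(tau_e, integral_pf)
    tr = integrate(p, prot, duration=duration, spiking=False)
    above = tr.I_ca > CA_DETECTION_PA
    if not above.any():
        return False, tr
    # longest contiguous run above the detection level, in ms
    edges = np.diff(np.concatenate([[0], above.astype(int), [0]]))
    runs = (np.nonzero(edges == -1)[0] - np.nonzero(edges == 1)[0]) * tr.dt
    return bool(runs.max() >= 2.0), tr


def min_conductance_for_spike(params: ModelParams, tau_e: float, *,
                              resolution: float = 1.0, lo: float = 1.0,
                              hi: float = 2000.0) -> float:
    """Smallest conductance integral (nS*ms = pF) triggering a calcium spike.

    Bisection on the integral of a single distal conductance event on a
    quiescent background, with the trigger indicator checked for monotonicity
    on the probe points actually visited.  Somatic spiking is disabled so the
    probe measures the calcium mechanism alone.
    """
    ok_hi, _ = _triggers(params, tau_e, hi)
    if not ok_hi:
        raise ThresholdError(f"no calcium spike up to integral {hi} pF")
    ok_lo, _ = _triggers(params, tau_e, lo)
    if ok_lo:
        raise ThresholdError(f"calcium spike already at integral {lo} pF")
    probes = [(lo, False), (hi, True)]
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        ok, _ = _triggers(params, tau_e, mid)
        probes.append((mid, ok))
        if ok:
            hi = mid
        else:
            lo = mid
    probes.sort()
    flags = [int(ok) for _, ok in probes]
    if flags != sorted(flags):
        raise ThresholdError("trigger indicator not monotone on probe points")
    return hi


def slope_threshold_from_trace(vd: np.ndarray, dt: float, onset: float,
                               detection: float) -> float:
    """V^d at the minimum of |dV/dt| between stimulus onset and detection.

    Centered finite differences on the grid; raises if the flattest point sits
    at the window boundary (monotone trajectory, no interior flattening).
    """
    k0 = int(round(onset / dt)) + 2
    k1 = int(round(detection / dt))
    if k1 - k0 < 3:
        raise ThresholdError("window too short to locate a flattening")
    dv = np.abs(np.gradient(vd, dt))
    k = k0 + int(np.argmin(dv[k0:k1]))
    if k <= k0 or k >= k1 - 1:
        raise ThresholdError("no interior flattening found (monotone trace)")
    return float(vd[k])


def threshold_by_slope(params: ModelParams, tau_e: float, *,
                       onset: float = 20.0) -> float:
    """Voltage-slope threshold: V^d at the flattest pre-spike trajectory point."""
    a_min = min_conductance_for_spike(params, tau_e)
    _, tr = _triggers(params, tau_e, a_min)
    # window ends at the calcium-current peak: for fast inputs the gating
    # transient can cross the detection level well before the excursion proper,
    # but the flattening always precedes the current maximum
    peak_t = float(np.argmax(tr.I_ca) * tr.dt)
    return slope_threshold_from_trace(tr.V[0], tr.dt, onset, peak_t)


def threshold_by_epsp(params: ModelParams, tau_e: float, *,
                      onset: float = 20.0) -> float:
    """EPSP threshold: peak distal EPSP of the minimal triggering stimulus.

    The minimal conductance event is found with calcium enabled; the EPSP is
    read from a calcium-disabled run with the identical stimulus (see
    :func:`threshold_by_epsp_beta` for the beta-current variant).
    """
    a_min = min_conductance_for_spike(params, tau_e)
    p = params if (tau_e == 0.0 or params.tau_e == tau_e) \
        else params.replace(tau_e=tau_e)
    tr0 = integrate(p.without_calcium(), _probe_protocol(tau_e, a_min),
                    duration=300.0, mode="passive", spiking=False)
    assert not (tr0.I_ca > CA_DETECTION_PA).any()
    return float(tr0.V[0].max())


def threshold_by_epsp_beta(params: ModelParams, *, tau=(5.0, 1.0),
                           onset: float = 20.0, lo: float = 10.0,
                           hi: float = 5000.0, resolution: float = 1.0) -> float:
    """EPSP threshold for a beta-current stimulus, bisected on peak amplitude."""
    def trig(amp):
        prot = StimulusProtocol().add(
            StimulusEvent("d", "beta", amp, onset, tau=tau))
        tr = integrate(params, prot, duration=300.0, spiking=False)
        return bool((tr.I_ca > CA_DETECTION_PA).any())

    if not trig(hi):
        raise ThresholdError("no calcium spike at the amplitude upper bound")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if trig(mid):
            hi = mid
        else:
            lo = mid
    prot = StimulusProtocol().add(StimulusEvent("d", "beta", hi, onset, tau=tau))
    tr0 = integrate(params.without_calcium(), prot, duration=300.0,
                    mode="passive", spiking=False)
    return float(tr0.V[0].max())


def delta_input_threshold(params: ModelParams, *, n_grid: int = 10_000) -> float:
    """Analytic delta-input threshold: fixed point of the steady-state system.

    With adiabatic activation (m = m_inf) and h = 1, the stationary voltages
    solve a 3x3 linear system for each m; the threshold is the first upward
    intersection of m_inf(V^d(m)) with m on (0, 1), refined by bisection.
    """
    p = params

    def vd_of_m(m):
        G = _coupling_matrix(p, extra_g=(p.g_ca * m, 0.0, 0.0))
        b = np.array([p.g_l_d * p.U_l_d + p.g_ca * m * p.U_ca,
                      p.g_l_p * p.U_l_p, p.g_l_s * p.U_l_s])
        b += _coupling_offsets(p)
        return np.linalg.solve(G, b)[0]

    def g(m):
        return gating_steady(vd_of_m(m), p.m_slope, p.m_half) - m

    ms = np.linspace(1e-9, 1.0 - 1e-9, n_grid)
    gs = np.array([g(m) for m in ms])
    rising = np.nonzero((gs[:-1] < 0) & (gs[1:] >= 0))[0]
    if len(rising) == 0:
        raise ThresholdError("no unstable fixed point in (0, 1): "
                             "no calcium threshold exists")
    a, b = ms[rising[0]], ms[rising[0] + 1]
    for _ in range(60):
        mid = 0.5 * (a + b)
        if g(mid) < 0:
            a = mid
        else:
            b = mid
    return float(vd_of_m(0.5 * (a + b)))


# ---------------------------------------------------------------------------
# reduced model
# ---------------------------------------------------------------------------

@dataclass
class ReducedModel:
    """Threshold-triggered fixed-waveform variant of the neuron model.

    The first-order calcium kinetics (g_ca, m, h) are removed; an upward
    crossing of V^d through ``waveform.v_theta`` (outside an ongoing waveform)
    injects the stored current into the distal compartment.  All other
    parameters are shared with the kinetics model.
    """

    params: ModelParams
    waveform: CalciumWaveform

    def integrate(self, protocol=None, ensemble=None, **kw) -> Trace:
        return integrate(self.params, protocol, ensemble, mode="reduced",
                         waveform=self.waveform.current,
                         v_theta=self.waveform.v_theta, **kw)


def build_reduced_model(params: ModelParams, waveform: CalciumWaveform
                        ) -> ReducedModel:
    if waveform is None or len(waveform.current) == 0:
        raise ValueError("reduced model requires a non-empty waveform")
    if not np.isfinite(waveform.v_theta):
        raise ValueError("waveform has no trigger threshold set")
    return ReducedModel(params=params, waveform=waveform)


def threshold_by_rate_mse(params: ModelParams, waveform: CalciumWaveform,
                          threshold_grid, *, p_grid=(0.1, 0.3, 0.5, 0.7),
                          duration: float = 20_000.0, seed: int = 0,
                          frac_corr: float = 0.3, w_e: float | None = None,
                          w_i: float | None = None) -> float:
    """Trigger threshold minimizing the firing-rate-curve MSE.

    Simulates the somatic firing rate against the input pairwise correlation
    (30% of distal excitatory synapses on a 1 spike/s mother process) for the
    kinetics model, then for the reduced model at each candidate threshold;
    returns the argmin-MSE threshold.  Frozen noise: both models consume the
    same realized ensembles.
    """
    threshold_grid = list(threshold_grid)
    if len(threshold_grid) == 0:
        raise ValueError("empty threshold grid")
    if w_e is None:
        w_e = 0.6 / params.tau_e
    rates_kin = []
    rates_red = {th: [] for th in threshold_grid}
    for i, p_copy in enumerate(p_grid):
        ens = invivo_ensemble(duration, seed + 1000 * i, w_e=w_e,
                              w_i=1.0 if w_i is None else w_i,
                              frac_corr=frac_corr, p_copy=p_copy)
        tr = integrate(params, ensemble=ens, duration=duration)
        rates_kin.append(len(tr.spike_times) / duration * 1000.0)
        for th in threshold_grid:
            red = ReducedModel(params, CalciumWaveform(
                waveform.dt, waveform.current, th, waveform.provenance))
            trr = red.integrate(ensemble=ens, duration=duration)
            rates_red[th].append(len(trr.spike_times) / duration * 1000.0)
    rates_kin = np.array(rates_kin)
    mses = {th: float(np.mean((np.array(r) - rates_kin) ** 2))
            for th, r in rates_red.items()}
    return min(mses, key=mses.get)
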