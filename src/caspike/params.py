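"""Model state, parameters, and the right-hand side of the three-compartment system.

The neuron is three coupled isopotential compartments -- distal tuft (d),
proximal apical dendrite (p) and soma with basal dendrites (s) -- each obeying

    C^x dV^x/dt = -g_l^x (V^x - U_l^x) - g_e^x (V^x - U_e) - g_i^x (V^x - U_i)
                  + coupling + I_ca (distal only) + I_AP (proximal/distal) + I_inj

with the coupling between compartments x and y written as
g_xy ((V^x - U_l^x) - (V^y - U_l^y)), so that with no synaptic or active
currents every compartment rests exactly at its own leak reversal.

The distal compartment carries a regenerative calcium current

    I_ca = g_ca * m * h * (U_ca - V^d)

with first-order gating: a fast activation variable m and a slow inactivation
variable h, each relaxing toward a sigmoid of the distal voltage.  The soma
spikes when V^s crosses an adaptive threshold; each spike raises the threshold
by theta_plus (exponential relaxation back to theta_base with tau_th), jumps
V^s to V_peak, and swaps the somatic leak to a large refractory value g_ref for
t_ref so the potential comes back down passively.  A spike also schedules
alpha-shaped back-propagating currents into the proximal (after 1 ms) and
distal (after 2 ms) compartments.

Unit system is closed: {pF, nS, mV, ms, pA}; pA/pF = mV/ms and nS*mV = pA,
so no conversion factors appear anywhere in the dynamics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "ModelParams",
    "ModelState",
    "DegenerateParametersError",
    "gating_steady",
    "calcium_current",
    "resting_state",
    "derivative",
    "apply_spike",
]


class DegenerateParametersError(ValueError):
    """Raised when the passive system is singular (e.g. all conductances zero)."""


# JSON key = f"{field}_{unit}"; unit suffixes follow the closed unit system.
_UNITS = {
    "C_d": "pF", "C_p": "pF", "C_s": "pF",
    "g_l_d": "nS", "g_l_p": "nS", "g_l_s": "nS",
    "U_l_d": "mV", "U_l_p": "mV", "U_l_s": "mV",
    "g_pd": "nS", "g_sp": "nS",
    "U_e": "mV", "U_i": "mV",
    "tau_e": "ms", "tau_i": "ms",
    "g_ca": "nS", "U_ca": "mV",
    "tau_m": "ms", "tau_h": "ms",
    "m_slope": "per_mV", "m_half": "mV",
    "h_slope": "per_mV", "h_half": "mV",
    "theta_base": "mV", "theta_plus": "mV", "tau_th": "ms",
    "t_ref": "ms", "V_peak": "mV", "g_ref": "nS",
    "J_ap_p": "pA", "J_ap_d": "pA", "tau_ap": "ms",
    "bap_delay_p": "ms", "bap_delay_d": "ms",
}


@dataclass(frozen=True)
class ModelParams:
    """All constants of the three-compartment model.

    Capacitances in pF, conductances in nS, voltages in mV, times in ms,
    currents in pA.  ``m_slope`` and ``h_slope`` parameterize the gating
    sigmoids 1/(1+exp(slope*(V-half))); they must have opposite signs so that
    activation m_inf increases with depolarization (m_slope < 0 in this
    parameterization) while inactivation h_inf decreases (h_slope > 0).
    """

    # passive compartments
    C_d: float = 150.0
    C_p: float = 150.0
    C_s: float = 150.0
    g_l_d: float = 10.0
    g_l_p: float = 10.0
    g_l_s: float = 10.0
    U_l_d: float = -70.0
    U_l_p: float = -70.0
    U_l_s: float = -70.0
    g_pd: float = 30.0
    g_sp: float = 30.0
    # synapses
    U_e: float = 0.0
    U_i: float = -80.0
    tau_e: float = 1.0
    tau_i: float = 2.0
    # calcium block
    g_ca: float = 45.0
    U_ca: float = 50.0
    tau_m: float = 0.5
    tau_h: float = 40.0
    m_slope: float = -0.5
    m_half: float = -21.0
    h_slope: float = 0.5
    h_half: float = -24.0
    # spike block
    theta_base: float = -55.0
    theta_plus: float = 15.0
    tau_th: float = 30.0
    t_ref: float = 2.0
    V_peak: float = 30.0
    g_ref: float = 150.0
    # back-propagating action potential block
    J_ap_p: float = 500.0
    J_ap_d: float = 1500.0
    tau_ap: float = 1.0
    bap_delay_p: float = 1.0
    bap_delay_d: float = 2.0

    def __post_init__(self):
        for name in ("C_d", "C_p", "C_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("g_l_d", "g_l_p", "g_l_s", "g_pd", "g_sp", "g_ca", "g_ref"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("tau_m", "tau_h", "tau_th", "tau_e", "tau_i", "tau_ap", "t_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.m_slope * self.h_slope >= 0:
            raise ValueError(
                "m_slope and h_slope must be nonzero and of opposite sign "
                "(activation and inactivation gate in opposite directions)"
            )

    # ---- config I/O (flat keyed JSON, symbol_unit keys) -------------------

    def to_dict(self) -> dict:
        return {f"{k}_{u}": getattr(self, k) for k, u in _UNITS.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        kwargs = {}
        for k, u in _UNITS.items():
            key = f"{k}_{u}"
            if key in d:
                kwargs[k] = float(d[key])
            elif k in d:  # tolerate bare symbol names
                kwargs[k] = float(d[k])
        return cls(**kwargs)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def load(cls, path) -> "ModelParams":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)

    def without_calcium(self) -> "ModelParams":
        """Passive twin: calcium conductance removed, everything else shared."""
        return self.replace(g_ca=0.0)


@dataclass
class ModelState:
    """Dynamic state of the model at one instant.

    ``g/z`` pairs are the two-state representation of the alpha-shaped
    conductances per compartment and synapse type; ``bap`` holds the pending
    back-propagating current events as (delivery time, amplitude, compartment
    index) tuples, and ``i_ap`` the two alpha-current filter pairs.
    """

    V: np.ndarray = field(default_factory=lambda: np.full(3, -70.0))  # d, p, s
    m: float = 0.0
    h: float = 1.0
    theta: float = -55.0
    g_e: np.ndarray = field(default_factory=lambda: np.zeros(3))
    z_e: np.ndarray = field(default_factory=lambda: np.zeros(3))
    g_i: np.ndarray = field(default_factory=lambda: np.zeros(3))
    z_i: np.ndarray = field(default_factory=lambda: np.zeros(3))
    i_ap: np.ndarray = field(default_factory=lambda: np.zeros(2))   # p, d currents
    z_ap: np.ndarray = field(default_factory=lambda: np.zeros(2))
    refractory: float = 0.0
    pending_bap: list = field(default_factory=list)
    spike_times: list = field(default_factory=list)

    @classmethod
    def at_rest(cls, params: ModelParams) -> "ModelState":
        vd = params.U_l_d
        return cls(
            V=np.array([params.U_l_d, params.U_l_p, params.U_l_s]),
            m=gating_steady(vd, params.m_slope, params.m_half),
            h=gating_steady(vd, params.h_slope, params.h_half),
            theta=params.theta_base,
        )


def gating_steady(V: float, slope: float, half: float):
    """Steady-state gating sigmoid 1/(1+exp(slope*(V-half))).

    Strictly decreasing in V for slope > 0, increasing for slope < 0; equals
    0.5 at V = half.  Saturates to {0, 1} without overflow for extreme V.
    """
    x = slope * (np.asarray(V, dtype=float) - half)
    # clip the exponent: exp(±40) already saturates the sigmoid to 1 part in 1e17
    out = 1.0 / (1.0 + np.exp(np.clip(x, -40.0, 40.0)))
    return float(out) if np.isscalar(V) or np.ndim(V) == 0 else out


def calcium_current(V_d: float, m: float, h: float, params: ModelParams) -> float:
    """I_ca = g_ca * m * h * (U_ca - V^d) in pA; sign follows the driving force."""
    return params.g_ca * m * h * (params.U_ca - V_d)


def _coupling_matrix(params: ModelParams, extra_g=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Conductance matrix G of the passive system, C dV/dt = -G V + b.

    ``extra_g`` adds constant per-compartment conductances (e.g. mean synaptic
    or calcium conductances) to the diagonal.
    """
    p = params
    return np.array([
        [p.g_l_d + p.g_pd + extra_g[0], -p.g_pd, 0.0],
        [-p.g_pd, p.g_l_p + p.g_pd + p.g_sp + extra_g[1], -p.g_sp],
        [0.0, -p.g_sp, p.g_l_s + p.g_sp + extra_g[2]],
    ])


def _coupling_offsets(params: ModelParams) -> np.ndarray:
    """Constant currents from the (V^x - U_l^x) - (V^y - U_l^y) coupling convention."""
    p = params
    return np.array([
        p.g_pd * (p.U_l_d - p.U_l_p),
        p.g_pd * (p.U_l_p - p.U_l_d) + p.g_sp * (p.U_l_p - p.U_l_s),
        p.g_sp * (p.U_l_s - p.U_l_p),
    ])


def resting_state(params: ModelParams, g_e=(0.0, 0.0, 0.0), g_i=(0.0, 0.0, 0.0),
                  I_inj=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Stationary compartment voltages (mV) of the passive system.

    Solves the 3x3 linear system with I_ca = I_AP = 0 and frozen (constant)
    synaptic conductances.  With g_e = g_i = 0 each compartment rests exactly
    at its own leak reversal by the coupling-offset construction.
    """
    p = params
    g_e = np.asarray(g_e, dtype=float)
    g_i = np.asarray(g_i, dtype=float)
    G = _coupling_matrix(p, extra_g=g_e + g_i)
    b = np.array([
        p.g_l_d * p.U_l_d, p.g_l_p * p.U_l_p, p.g_l_s * p.U_l_s,
    ]) + g_e * p.U_e + g_i * p.U_i + _coupling_offsets(p) + np.asarray(I_inj, float)
    if abs(np.linalg.det(G)) < 1e-12:
        raise DegenerateParametersError("passive system is singular (all conductances zero?)")
    return np.linalg.solve(G, b)


def derivative(state: ModelState, params: ModelParams,
               I_inj=(0.0, 0.0, 0.0)) -> dict:
    """Right-hand side of the full system at the given state.

    Returns a dict with ``dV`` (mV/ms, length 3, order d/p/s), ``dm``, ``dh``,
    ``dtheta`` and the instantaneous ``I_ca`` (pA).  External currents
    ``I_inj`` are added per compartment; synaptic conductances and the
    back-propagating alpha currents are read from the state.  During
    refractoriness the somatic leak is the large clamp value ``g_ref``.
    """
    p = params
    I_inj = np.asarray(I_inj, dtype=float)
    if I_inj.shape != (3,):
        raise ValueError("I_inj must have one entry per compartment")
    if np.any(state.g_e < 0) or np.any(state.g_i < 0):
        raise ValueError("negative synaptic conductance")
    V = state.V
    i_ca = calcium_current(V[0], state.m, state.h, p)
    g_l_s = p.g_ref if state.refractory > 0 else p.g_l_s
    dV = np.empty(3)
    dV[0] = (
        -p.g_l_d * (V[0] - p.U_l_d)
        - state.g_e[0] * (V[0] - p.U_e) - state.g_i[0] * (V[0] - p.U_i)
        - p.g_pd * ((V[0] - p.U_l_d) - (V[1] - p.U_l_p))
        + i_ca + state.i_ap[1] + I_inj[0]
    ) / p.C_d
    dV[1] = (
        -p.g_l_p * (V[1] - p.U_l_p)
        - state.g_e[1] * (V[1] - p.U_e) - state.g_i[1] * (V[1] - p.U_i)
        - p.g_pd * ((V[1] - p.U_l_p) - (V[0] - p.U_l_d))
        - p.g_sp * ((V[1] - p.U_l_p) - (V[2] - p.U_l_s))
        + state.i_ap[0] + I_inj[1]
    ) / p.C_p
    dV[2] = (
        -g_l_s * (V[2] - p.U_l_s)
        - state.g_e[2] * (V[2] - p.U_e) - state.g_i[2] * (V[2] - p.U_i)
        - p.g_sp * ((V[2] - p.U_l_s) - (V[1] - p.U_l_p))
        + I_inj[2]
    ) / p.C_s
    dm = (gating_steady(V[0], p.m_slope, p.m_half) - state.m) / p.tau_m
    dh = (gating_steady(V[0], p.h_slope, p.h_half) - state.h) / p.tau_h
    dtheta = (p.theta_base - state.theta) / p.tau_th
    return {"dV": dV, "dm": dm, "dh": dh, "dtheta": dtheta, "I_ca": i_ca}


def apply_spike(state: ModelState, params: ModelParams, t: float) -> ModelState:
    """Somatic spike side effects at time t (state is modified in place).

    No-op while refractory (spiking is disabled then).  Otherwise: records the
    spike, jumps V^s to V_peak, raises the adaptive threshold by theta_plus,
    starts the t_ref refractory clamp, and schedules the proximal and distal
    back-propagating alpha currents at t + 1 ms and t + 2 ms.
    """
    p = params
    if state.refractory > 0:
        return state
    state.spike_times.append(t)
    state.V[2] = p.V_peak
    state.theta += p.theta_plus
    state.refractory = p.t_ref
    state.pending_bap.append((t + p.bap_delay_p, p.J_ap_p, "p"))
    state.pending_bap.append((t + p.bap_delay_d, p.J_ap_d, "d"))
    return state
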