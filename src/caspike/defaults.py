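"""Default and reference parameter sets.

``default_params()`` loads the parameter set shipped with the package, the
output of the three-stage fitting procedure (see :mod:`caspike.calibration`)
run on the reference design point below: it reproduces the full in-vitro
protocol battery and is reduction-consistent.

``reference_params()`` is the calibration's design point: the center of the
stage-2 +/-20% kinetics box and the provisional spike/back-propagation block.
Its calcium values play the role of the externally supplied reference kinetics
the fitting procedure requires; they are the package's own choice (documented
in docs/methods.md), picked for a sharp activation gate around -21 mV, a slow
inactivation gate around -24 mV and a high calcium reversal.
"""

from __future__ import annotations

from importlib import resources

from .params import ModelParams

__all__ = ["default_params", "reference_params"]


def default_params() -> ModelParams:
    """The fitted parameter set shipped with the package."""
    with resources.files("caspike.data").joinpath("default_params.json").open() as f:
        import json
        return ModelParams.from_dict(json.load(f))


def reference_params() -> ModelParams:
    """The calibration design point (stage-2 box center, provisional blocks)."""
    return ModelParams(
        C_d=100.0, C_p=150.0, C_s=80.0,
        g_l_d=10.0, g_l_p=10.0, g_l_s=10.0,
        g_pd=20.0, g_sp=30.0,
        U_e=0.0, U_i=-80.0, tau_e=1.0, tau_i=2.0,
        g_ca=20.0, U_ca=120.0, tau_m=0.5, tau_h=15.0,
        m_slope=-1.0, m_half=-21.0, h_slope=0.5, h_half=-24.0,
        theta_base=-45.0, theta_plus=6.0, tau_th=15.0,
        J_ap_p=500.0, J_ap_d=1500.0,
    )
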