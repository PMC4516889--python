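"""The standard in-vitro stimulation battery.

Four protocols reproduce the classic layer-5 pyramidal neuron experiments:

  somatic_step      1 nA / 5 ms step at the soma          -> one action potential
  distal_beta       2.2 nA beta current (tau 5/1 ms) at   -> calcium spike and a
                    the distal compartment                   two-spike burst
  bac_coincidence   somatic step + half-amplitude (1.1 nA) -> calcium spike and
                    beta 4 ms after step onset               three action potentials
  proximal_block    -0.2 nA / 50 ms proximal step, beta    -> calcium spike but no
                    2.2 nA 30 ms after hyperpol. onset       action potentials

Onset defaults to 20 ms to let the model settle visually; all timings are
relative to that onset.
"""

from __future__ import annotations

from .stimuli import StimulusEvent, StimulusProtocol

__all__ = [
    "somatic_step",
    "distal_beta",
    "bac_coincidence",
    "proximal_block",
    "figure_battery",
    "EXPECTED_SPIKE_COUNTS",
]

BETA_TAU = (5.0, 1.0)  # ms (decay, rise)

# protocol name -> (somatic spike count, calcium spike expected)
EXPECTED_SPIKE_COUNTS = {
    "somatic_step": (1, False),
    "distal_beta": (2, True),
    "bac_coincidence": (3, True),
    "proximal_block": (0, True),
}


def somatic_step(onset: float = 20.0, amplitude: float = 1000.0) -> StimulusProtocol:
    return StimulusProtocol().add(
        StimulusEvent("s", "step", amplitude, onset, duration=5.0))


def distal_beta(onset: float = 20.0, amplitude: float = 2200.0) -> StimulusProtocol:
    return StimulusProtocol().add(
        StimulusEvent("d", "beta", amplitude, onset, tau=BETA_TAU))


def bac_coincidence(onset: float = 20.0, beta_amplitude: float = 1100.0) -> StimulusProtocol:
    return StimulusProtocol().add(
        StimulusEvent("s", "step", 1000.0, onset, duration=5.0),
        StimulusEvent("d", "beta", beta_amplitude, onset + 4.0, tau=BETA_TAU))


def proximal_block(onset: float = 20.0) -> StimulusProtocol:
    return StimulusProtocol().add(
        StimulusEvent("p", "step", -200.0, onset, duration=50.0),
        StimulusEvent("d", "beta", 2200.0, onset + 30.0, tau=BETA_TAU))


def figure_battery(onset: float = 20.0) -> dict:
    """All four protocols keyed by name, in presentation order."""
    return {
        "somatic_step": somatic_step(onset),
        "distal_beta": distal_beta(onset),
        "bac_coincidence": bac_coincidence(onset),
        "proximal_block": proximal_block(onset),
    }
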