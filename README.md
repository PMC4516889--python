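# caspike

Dendritic calcium spikes in a three-compartment layer-5 pyramidal neuron:
a fast conductance-based model, its reduction to a threshold-triggered fixed
current waveform, and analytic predictions of the calcium-evoked somatic
potential under fluctuating synaptic input.

## The problem

Layer-5 pyramidal neurons carry a regenerative calcium conductance near the
apical bifurcation. A strong synchronous input to the distal tuft — or a
back-propagating somatic action potential coinciding with a weaker distal
input — triggers a long-lasting *calcium spike* that depolarizes the soma and
produces a burst of action potentials. Morphologically detailed models capture
this, but they are neither analytically tractable nor cheap enough for large
network simulations. `caspike` is for modelers who want both: a minimal model
that still reproduces the classic in-vitro phenomenology, and a reduction
simple enough to reason about with pencil and paper.

## The model

Three coupled isopotential compartments — distal tuft `d`, proximal apical
dendrite `p`, soma `s`:

    C^x dV^x/dt = − g_l^x (V^x − U_l^x) − g_e^x (V^x − U_e) − g_i^x (V^x − U_i)
                  + g_xy ((V^y − U_l^y) − (V^x − U_l^x)) + I_ca + I_AP + I_inj

with alpha-function synaptic conductances and, in the distal compartment only,
a calcium current with first-order gating

    I_ca = g_ca · m · h · (U_ca − V^d),      τ_m ṁ = m∞(V^d) − m,   τ_h ḣ = h∞(V^d) − h,

where `m` is fast activation (half −21 mV) and `h` slow inactivation (half
−24 mV). The soma fires on crossing an adaptive threshold (jump `Θ_+`,
relaxation `τ_th`), with a 2 ms refractory leak clamp instead of a hard reset,
and each spike sends delayed alpha-shaped back-propagating currents into the
dendritic compartments. Units are closed over {pF, nS, mV, ms, pA}.

In the regime of low background fluctuation with occasional large synchronous
events, the calcium spike behaves as an all-or-nothing event with a
stereotyped current waveform. The package therefore also provides the
**reduced model**: the eight gating-related state variables are replaced by a
stored waveform injected whenever `V^d` crosses a trigger threshold `V_θ` from
below, plus the machinery to extract the waveform and determine `V_θ` (voltage
slope, EPSP amplitude, analytic fixed point, firing-rate MSE). For the
fluctuation regime, `caspike.approx` predicts the mean somatic excursion
caused by a triggered calcium spike: first-order linear response on the mean
conductances, and two effective-conductance corrections (semi-analytic and
analytic) that account for the covariance between synaptic conductances and
the membrane potential,

    g_eff = (⟨g_e⟩ − σ_e²/G₀ · τ_e/(τ_e+τ₀)) + (⟨g_i⟩ − σ_i²/G₀ · τ_i/(τ_i+τ₀)).

The shipped default parameters are produced by the three-stage fitting
procedure in `caspike.calibration` (see `docs/methods.md` for the full account
of the model, the numerics and the design choices).

## Worked example

```python
from caspike import default_params, figure_battery, integrate

params = default_params()
for name, protocol in figure_battery().items():
    trace = integrate(params, protocol, duration=200.0)
    print(name, len(trace.spike_times), trace.spike_times)
```

prints

    somatic_step     1 [22.9]
    distal_beta      2 [31.6 37.7]
    bac_coincidence  3 [22.9 34.9 42. ]
    proximal_block   0 []

i.e. a 1 nA/5 ms somatic step fires one action potential; a 2.2 nA distal beta
current triggers a calcium spike that drives a two-spike burst; the same
somatic step followed 4 ms later by a *half-amplitude* distal input still
triggers the calcium spike via the back-propagating action potential (BAC
firing, three spikes total); and a −200 pA proximal hyperpolarization lets the
calcium spike occur distally but blocks its somatic burst. Building the
reduced model on top:

```python
from caspike import build_reduced_model, distal_beta, waveform_from_trace
from caspike.reduction import threshold_by_epsp_beta

v_theta = threshold_by_epsp_beta(params)              # -24.31 mV
source = integrate(params, distal_beta(), duration=300.0)
wf = waveform_from_trace(source, v_theta=v_theta, align="crossing", min_events=1)
reduced = build_reduced_model(params, wf)             # A = 21388 pA*ms
```

reproduces the same spike counts on all four protocols with spike times within
a few milliseconds — one stored waveform and one threshold instead of the
gating dynamics.

The `examples/` directory holds one short narrative script per capability
(protocol battery, synchrony detection under bombardment, trigger thresholds,
the reduced model, and the somatic-potential approximations); each prints the
numbers it computes and what they mean. The same experiments are available
from the shell: `caspike experiment battery --seed 1`, `caspike fit`,
`caspike reduce`, `caspike calibrate`, `caspike simulate`.

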