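"""The four classic in-vitro stimulation experiments.

Runs the fitted three-compartment model through the protocol battery:
a somatic current step, a large distal beta current, the coincidence of a
somatic step with a half-amplitude distal input (BAC firing), and the
proximal hyperpolarization that decouples the calcium spike from the soma.
"""

from caspike import default_params, figure_battery, integrate

params = default_params()

print(f"{'protocol':18s} {'somatic spikes':>14s} {'calcium spike':>14s}  spike times (ms)")
for name, protocol in figure_battery().items():
    trace = integrate(params, protocol, duration=200.0)
    ca = bool((trace.I_ca > 1100.0).any())
    times = ", ".join(f"{t:.1f}" for t in trace.spike_times)
    print(f"{name:18s} {len(trace.spike_times):14d} {str(ca):>14s}  [{times}]")

print()
print("Expected: 1 spike / no calcium; 2 spikes / calcium; 3 spikes / calcium;")
print("0 spikes / calcium.  The last row shows that a -200 pA proximal")
print("hyperpolarization lets the calcium spike happen distally but stops it")
print("from driving somatic action potentials.")
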