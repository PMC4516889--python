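"""Experiment recipes tying the other modules together.

``run_experiment`` executes a named end-to-end protocol and writes a run
manifest (parameters, seed) plus a machine-readable summary JSON into the
output directory.  Experiment ids:

  battery         the four-protocol in-vitro battery (spike counts, traces)
  regimes         the four stochastic input regimes (calcium event statistics)
  bifurcation     maximum distal voltage vs. integral synaptic conductance
  jitter          full/partial calcium events under jittered synchrony and the
                  analytic mean jittered conductance check
  thresholds      slope / EPSP / analytic trigger thresholds across tau_e
  reduced-check   kinetics vs. fixed-waveform model on the battery
  approximations  first-order / semi-analytic / analytic somatic-potential
                  ratios at weak and strong synaptic weights
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .approx import (LinearResponseModel, campbell_stats,
                     effective_conductance_analytic,
                     effective_conductance_semianalytic, first_order_response,
                     inhibitory_weight_for_target,
                     measure_calcium_somatic_potential)
from .calibration import background_ensemble, mean_conductances
from .defaults import default_params
from .params import ModelParams
from .protocols import EXPECTED_SPIKE_COUNTS, distal_beta, figure_battery
from .reduction import (CA_DETECTION_PA, build_reduced_model,
                        delta_input_threshold, detect_calcium_spike,
                        min_conductance_for_spike, threshold_by_epsp,
                        threshold_by_epsp_beta, threshold_by_slope,
                        waveform_from_trace)
from .simulator import collect_events, integrate, paired_run
from .stimuli import (StimulusEvent, StimulusProtocol, alpha_kernel,
                      invivo_ensemble, jitter_events,
                      mean_jittered_conductance)

__all__ = ["ExperimentConfig", "run_experiment", "EXPERIMENTS"]


@dataclass
class ExperimentConfig:
    experiment: str
    params_file: str | None = None   # None -> packaged default parameters
    seed: int = 0
    out_dir: str | None = None       # None -> no files written
    overrides: dict = field(default_factory=dict)  # dot-free parameter patches
    save_traces: bool = False

    def load_params(self) -> ModelParams:
        p = (ModelParams.load(self.params_file) if self.params_file
             else default_params())
        if self.overrides:
            p = p.replace(**self.overrides)
        return p


def _regime_b_waveform(params, seed, duration=40_000.0):
    ens = invivo_ensemble(duration, seed, w_e=0.6, w_i=1.0)
    tr = integrate(params, ensemble=ens, duration=duration, mode="kinetics")
    v_theta = threshold_by_epsp_beta(params)
    return waveform_from_trace(tr, v_theta=v_theta, align="crossing",
                               provenance={"regime": "B", "seed": seed})


def _exp_battery(params, seed, out, save_traces):
    counts = {}
    for name, prot in figure_battery().items():
        tr = integrate(params, prot, duration=200.0)
        counts[name] = {
            "spikes": len(tr.spike_times),
            "spike_times_ms": tr.spike_times.tolist(),
            "calcium_spike": bool((tr.I_ca > CA_DETECTION_PA).any()),
            "expected": EXPECTED_SPIKE_COUNTS[name],
        }
        if out and save_traces:
            tr.save_csv(out / f"battery_{name}.csv")
    return {"protocols": counts,
            "all_as_expected": all(
                v["spikes"] == v["expected"][0]
                and v["calcium_spike"] == v["expected"][1]
                for v in counts.values())}


_REGIMES = {  # fraction correlated, copy probability, w_e, w_i
    "A": (0.10, 0.3, 0.6, 1.0),
    "B": (0.20, 0.5, 0.6, 1.0),
    "C": (0.0, 0.0, 5.0, 21.2),
    "D": (0.0, 0.0, 12.0, 54.4),
}


def _exp_regimes(params, seed, out, save_traces, duration=30_000.0):
    summary = {}
    for name, (frac, p_copy, w_e, w_i) in _REGIMES.items():
        ens = invivo_ensemble(duration, seed + hash(name) % 1000, w_e=w_e,
                              w_i=w_i, frac_corr=frac, p_copy=p_copy)
        tr = integrate(params, ensemble=ens, duration=duration)
        events = detect_calcium_spike(tr.I_ca, tr.dt)
        peaks = []
        for t0 in events:
            k = int(t0 / tr.dt)
            peaks.append(float(tr.I_ca[k: k + 500].max()))
        summary[name] = {
            "n_calcium_events": len(events),
            "n_somatic_spikes": len(tr.spike_times),
            "peak_mean_pA": float(np.mean(peaks)) if peaks else None,
            "peak_cv": float(np.std(peaks) / np.mean(peaks)) if peaks else None,
        }
    return summary


def _exp_bifurcation(params, seed, out, save_traces,
                     integrals=None, tau_e=1.0):
    a_min = min_conductance_for_spike(params, tau_e)
    if integrals is None:
        integrals = np.linspace(0.6 * a_min, 1.6 * a_min, 26)
    vmax = []
    for a in integrals:
        w = a / (np.e * tau_e)
        prot = StimulusProtocol().add(StimulusEvent("d", "alpha_cond_e", w, 20.0))
        tr = integrate(params.replace(tau_e=tau_e), prot, duration=300.0,
                       spiking=False)
        vmax.append(float(tr.V[0].max()))
    vmax = np.array(vmax)
    jump = float(np.diff(vmax).max())
    return {"tau_e_ms": tau_e, "min_integral_pF": a_min,
            "integral_pF": list(map(float, integrals)),
            "max_distal_mV": vmax.tolist(),
            "largest_step_mV": jump,
            "all_or_nothing": bool(jump > 10.0)}


def _exp_jitter(params, seed, out, save_traces, sigmas=(1.0, 2.5, 4.0, 8.0),
                duration=60_000.0):
    res = {}
    for sigma in sigmas:
        ens = invivo_ensemble(duration, seed, w_e=0.6, w_i=1.0,
                              jitter_mu=20.0, jitter_sigma=sigma)
        act, pas, diff = paired_run(params, params.without_calcium(),
                                    ensemble=ens, duration=duration,
                                    spiking=True)
        ev = np.array(ens.meta["mother_times"]) + 20.0
        segs = collect_events(diff, event_times=ev, window=(-10.0, 150.0))
        amps = np.array([s["amplitude"] for s in segs])
        res[f"sigma_{sigma}"] = {
            "n_events": len(ev),
            "n_full": int((amps >= 30.0).sum()),
            "n_partial": int(((amps > 0.001) & (amps < 30.0)).sum()),
        }
    # analytic mean jittered conductance vs Monte Carlo (one kernel)
    rng = np.random.default_rng(seed)
    dt, mu, sigma = 0.1, 200.0, 8.0
    t = np.arange(0, 30.0, dt)
    kern = alpha_kernel(0.6, params.tau_e, t)
    pred = mean_jittered_conductance(kern, dt, mu, sigma)
    tt = np.arange(len(pred)) * dt
    acc = np.zeros(len(pred))
    n_mc = 4000
    for d in jitter_events(np.zeros(n_mc), mu, sigma, rng):
        acc += alpha_kernel(0.6, params.tau_e, tt - d)
    emp = acc / n_mc
    res["convolution"] = {
        "rms_over_peak": float(np.sqrt(np.mean((pred - emp) ** 2)) / pred.max()),
        "integral_ratio": float(pred.sum() / kern.sum()),
    }
    return res


def _exp_thresholds(params, seed, out, save_traces,
                    tau_e_grid=(0.0, 0.2, 0.5, 1.0, 2.0, 5.0)):
    rows = []
    for te in tau_e_grid:
        rows.append({
            "tau_e_ms": te,
            "min_integral_pF": float(min_conductance_for_spike(params, te)),
            "slope_threshold_mV": float(threshold_by_slope(params, te)),
            "epsp_threshold_mV": float(threshold_by_epsp(params, te)),
        })
    return {
        "per_tau_e": rows,
        "delta_fixed_point_mV": float(delta_input_threshold(params)),
        "epsp_beta_threshold_mV": float(threshold_by_epsp_beta(params)),
    }


def _exp_reduced_check(params, seed, out, save_traces):
    v_theta = threshold_by_epsp_beta(params)
    tr = integrate(params, distal_beta(), duration=300.0, mode="kinetics")
    wf = waveform_from_trace(tr, v_theta=v_theta, align="crossing",
                             min_events=1,
                             provenance={"source": "distal_beta_protocol"})
    red = build_reduced_model(params, wf)
    if out:
        wf.save(out / "waveform.tsv")
    rows = {}
    for name, prot in figure_battery().items():
        trk = integrate(params, prot, duration=200.0)
        trr = red.integrate(prot, duration=200.0)
        rows[name] = {
            "kinetics_spikes": trk.spike_times.tolist(),
            "reduced_spikes": trr.spike_times.tolist(),
            "counts_equal": len(trk.spike_times) == len(trr.spike_times),
        }
    return {"v_theta_mV": v_theta, "A_pA_ms": wf.A, "protocols": rows,
            "all_counts_equal": all(r["counts_equal"] for r in rows.values())}


def _exp_approximations(params, seed, out, save_traces,
                        weights=(0.6, 12.0), duration=100_000.0):
    wf = _regime_b_waveform(params, seed)
    res = {"waveform_A_pA_ms": wf.A, "v_theta_mV": wf.v_theta}
    for w_e in weights:
        w_i = inhibitory_weight_for_target(params, w_e)
        bg = background_ensemble(duration, seed + 17, w_e=w_e, w_i=w_i)
        meas = measure_calcium_somatic_potential(params, wf, bg,
                                                 trigger="random",
                                                 event_rate=3.0, seed=seed)
        ge, gi = mean_conductances(params, w_e, w_i)
        eps1 = first_order_response(
            LinearResponseModel(params, (ge,) * 3, (gi,) * 3), wf)
        g_semi = effective_conductance_semianalytic(meas["eps_integral"],
                                                    wf.A, params)
        eps_semi = first_order_response(
            LinearResponseModel(params, g_semi, np.zeros(3)), wf)
        g_ana = np.array([effective_conductance_analytic(
            campbell_stats(params, c, w_e, w_i)) for c in range(3)])
        eps_ana = first_order_response(
            LinearResponseModel(params, g_ana, np.zeros(3)), wf)
        pk = meas["peak_somatic"]
        res[f"w_e_{w_e}"] = {
            "w_i_nS": w_i,
            "n_events": meas["n_events"],
            "simulated_peak_mV": pk,
            "ratio_first_order": float(eps1[2].max() / pk),
            "ratio_semianalytic": float(eps_semi[2].max() / pk),
            "ratio_analytic": float(eps_ana[2].max() / pk),
        }
    return res


def io_roundtrip(artifact, path):
    """Write an artifact to ``path`` and read it back (write-then-read check).

    Supports ModelParams, StimulusProtocol, InputEnsemble, Trace and
    CalciumWaveform; returns the reloaded artifact.
    """
    from .reduction import CalciumWaveform
    from .simulator import Trace
    from .stimuli import InputEnsemble, StimulusProtocol
    table = {ModelParams: ModelParams.load,
             StimulusProtocol: StimulusProtocol.load,
             InputEnsemble: InputEnsemble.load,
             CalciumWaveform: CalciumWaveform.load}
    if isinstance(artifact, Trace):
        artifact.save_csv(path)
        return Trace.load_csv(path)
    for cls, loader in table.items():
        if isinstance(artifact, cls):
            artifact.save(path)
            return loader(path)
    raise TypeError(f"no serialization for {type(artifact).__name__}")


EXPERIMENTS = {
    "battery": _exp_battery,
    "regimes": _exp_regimes,
    "bifurcation": _exp_bifurcation,
    "jitter": _exp_jitter,
    "thresholds": _exp_thresholds,
    "reduced-check": _exp_reduced_check,
    "approximations": _exp_approximations,
}


def run_experiment(config: ExperimentConfig) -> dict:
    """Execute one named experiment; returns (and optionally writes) a summary."""
    if config.experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment id {config.experiment!r}; "
                         f"known: {sorted(EXPERIMENTS)}")
    params = config.load_params()
    out = None
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
    summary = EXPERIMENTS[config.experiment](params, config.seed, out,
                                             config.save_traces)
    manifest = {
        "experiment": config.experiment,
        "seed": config.seed,
        "version": __version__,
        "overrides": config.overrides,
        "params": params.to_dict(),
        "summary": summary,
    }
    if out is not None:
        (out / f"{config.experiment}_summary.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
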