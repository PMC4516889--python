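import numpy as np
import pytest

from caspike import default_params, distal_beta, integrate, invivo_ensemble
from caspike.reduction import threshold_by_epsp_beta, waveform_from_trace


@pytest.fixture(scope="session")
def params():
    """The packaged fitted parameter set."""
    return default_params()


@pytest.fixture(scope="session")
def v_theta(params):
    """EPSP-defined trigger threshold for the 5/1 ms beta stimulus."""
    return threshold_by_epsp_beta(params)


@pytest.fixture(scope="session")
def beta_waveform(params, v_theta):
    """Calcium waveform evoked by the 2.2 nA beta protocol (trigger-aligned)."""
    tr = integrate(params, distal_beta(), duration=300.0, mode="kinetics")
    return waveform_from_trace(tr, v_theta=v_theta, align="crossing",
                               min_events=1,
                               provenance={"source": "distal_beta"})


@pytest.fixture(scope="session")
def regime_b(params):
    """40 s of the low-fluctuation / large-synchronous-event embedding."""
    ens = invivo_ensemble(40_000.0, 7, w_e=0.6, w_i=1.0,
                          frac_corr=0.2, p_copy=0.5)
    tr = integrate(params, ensemble=ens, duration=40_000.0, mode="kinetics")
    return ens, tr


@pytest.fixture(scope="session")
def regime_b_waveform(params, regime_b, v_theta):
    """Mean calcium waveform extracted from the regime-B embedding."""
    _, tr = regime_b
    return waveform_from_trace(tr, v_theta=v_theta, align="crossing",
                               provenance={"regime": "B"})


def pairwise_count_correlation(spikes, duration, bin_ms=2.0):
    """Mean pairwise Pearson correlation of binned spike counts."""
    nb = int(duration / bin_ms)
    counts = np.array([
        np.bincount(np.minimum((np.asarray(s) / bin_ms).astype(int), nb - 1),
                    minlength=nb)[:nb]
        for s in spikes
    ])
    c = np.corrcoef(counts)
    iu = np.triu_indices(len(spikes), 1)
    return float(c[iu].mean())
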