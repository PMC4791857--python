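import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from plovermeta import encounter as enc


def make_setting(S, T, stratum_names=None, hf_interval=None, post_interval=None,
                 success=None, distances=None):
    """A minimal covariate/distance setting for S strata and T occasions."""
    names = stratum_names or [f"S{i}" for i in range(S)]
    ni = T - 1
    hf = np.zeros(ni)
    post = np.zeros(ni)
    if hf_interval is not None:
        hf[hf_interval] = 1
    if post_interval is not None:
        post[post_interval] = 1
    succ = np.zeros((ni, S)) if success is None else np.asarray(success)
    cov = enc.OccasionCovariates(list(range(2000, 2000 + T)), names, succ,
                                 hf, post, flow_stratum=names[min(1, S - 1)])
    if distances is None:
        D = np.abs(np.subtract.outer(np.arange(S), np.arange(S))) * 50.0
    else:
        D = np.asarray(distances, dtype=float)
    return names, cov, D


def random_parameter_tensors(rng, n, T, S):
    """Random well-behaved (phi, p, psi) tensors for oracle comparisons."""
    phi = rng.uniform(0.2, 0.95, size=(n, T - 1, S))
    p = rng.uniform(0.2, 0.95, size=(n, T - 1, S))
    raw = rng.uniform(0.05, 1.0, size=(n, T - 1, S, S))
    psi = raw / raw.sum(axis=-1, keepdims=True)
    return phi, p, psi


@pytest.fixture(scope="session")
def study_data():
    """One study-scale synthetic data set shared by estimation tests."""
    from plovermeta import synth
    spec, beta_true, truth, scen = synth.generating_model()
    hist, cov = synth.simulate_histories(truth, scen, seed=20260101)
    return {"spec": spec, "beta_true": beta_true, "truth": truth,
            "scenario": scen, "hist": hist, "cov": cov,
            "dist": scen.distances}
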