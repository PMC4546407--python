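"""Shared fixtures: small trained networks reused across test modules."""

import numpy as np
import pytest

import threetlr as t


@pytest.fixture(scope="session")
def dense_trained():
    """A dense-regime network (N=300, f=0.5, gamma=6, eps=1.2) trained on
    alpha=0.2 random patterns; well below capacity so training reaches its
    fixed point quickly."""
    N, eps, alpha = 300, 1.2, 0.15
    pats = t.generate_patterns(N, int(alpha * N), 0.5, seed=101)
    W0 = t.initialize_weights(N, seed=102)
    params = t.NetworkParams.standard(N, mean_w=W0.mean_w, std_w=W0.std_w)
    config = t.LearningConfig.for_params(params, eps)
    result = t.train_3tlr(W0, pats, params, config, seed=103)
    return {
        "result": result,
        "patterns": pats,
        "params": result.params,
        "config": config,
        "W0": W0,
        "eps": eps,
    }


@pytest.fixture(scope="session")
def tiny_params():
    """Hand-built parameters for an N=8 network with moderate inhibition."""
    N = 8
    return t.NetworkParams(
        N=N, f=0.5, theta=(N - 1) * 0.35, psi=0.35, lam=1.0,
        gamma=6.0, H0=2.0, H1=1.5,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
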