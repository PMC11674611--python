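import numpy as np
import pytest

from hbnet.config import PipelineConfig, SimConfig
from hbnet.synthetic import simulate_var_sources


@pytest.fixture
def rng():
    return np.random.default_rng(20240)


@pytest.fixture
def chain_adjacency():
    """8-node VAR adjacency with 6 true directed cross edges (column drives row)."""
    c = 8
    A = np.eye(c) * 0.4
    edges = [(0, 1), (1, 2), (2, 3), (4, 5), (5, 6), (6, 7)]
    for src, dst in edges:
        A[dst, src] = 0.35
    return A, edges


@pytest.fixture
def var_sources(chain_adjacency):
    A, _ = chain_adjacency
    return simulate_var_sources(A, var_order=2, n=6000, fs=200.0, noise_sd=1.0, seed=11)


@pytest.fixture(scope="session")
def tiny_pipeline_config():
    """Small but complete pipeline config for orchestration tests."""
    cfg = PipelineConfig(
        seed=7,
        sim=SimConfig(
            c=4, d=2, u=6, v=8, n_classes=2, trials_per_class=3,
            trial_s=9.0, n_edges=3,
        ),
    )
    cfg.granger.fixed_p = 2
    cfg.evaluate.classifiers = ["svm_linear"]
    cfg.evaluate.repeats = 1
    return cfg
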