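"""Shared fixtures.

The repeated-split protocol runs (20 training repeats each) are
session-scoped so the signal-recovery and robustness tests share one
computation.  Everything is seeded; the heavy fixtures use the package
defaults (generator seed 0, protocol seed 0).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from omicsgcn.evaluation import (
    ExperimentConfig,
    from_synthetic,
    repeated_eval,
    run_k_sweep,
)
from omicsgcn.model import GraphSet, init_params
from omicsgcn.simulate import SyntheticSpec, generate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_normalized_graphs(rng, p, q):
    """Random normalized intra graphs + bipartite blocks for 2 omics."""
    from omicsgcn.graphs import (
        BipartiteGraph,
        FeatureGraph,
        assemble_and_normalize_bipartite,
        normalize_sym,
    )

    def random_adj(d):
        a = (rng.random((d, d)) < 0.4).astype(np.int8)
        a = np.triu(a, k=1)
        return a + a.T

    intra = {
        "u": normalize_sym(FeatureGraph("u", [f"u{i}" for i in range(p)], random_adj(p), 0.5)),
        "v": normalize_sym(FeatureGraph("v", [f"v{i}" for i in range(q)], random_adj(q), 0.5)),
    }
    bip = BipartiteGraph(
        [f"u{i}" for i in range(p)],
        [f"v{i}" for i in range(q)],
        (rng.random((p, q)) < 0.4).astype(np.int8),
    )
    return GraphSet.from_normalized(intra, {("u", "v"): assemble_and_normalize_bipartite(bip)})


@pytest.fixture
def tiny_problem(rng):
    """Small two-omics instance: params, graphs and inputs."""
    p, q, n = 4, 3, 6
    graphs = random_normalized_graphs(rng, p, q)
    params = init_params({"u": p, "v": q}, L=2, k=0.5, seed=rng)
    X = {"u": rng.normal(size=(n, p)), "v": rng.normal(size=(n, q))}
    y = (rng.random(n) < 0.5).astype(int)
    y[:2] = [0, 1]  # both classes present
    return params, graphs, X, y


# ---------------------------------------------------------------------------
# Protocol-scale fixtures (package defaults, shared across tests)


@pytest.fixture(scope="session")
def default_dataset():
    return from_synthetic(generate(SyntheticSpec()))


@pytest.fixture(scope="session")
def protocol_config():
    return ExperimentConfig()


@pytest.fixture(scope="session")
def both_report(default_dataset, protocol_config):
    return repeated_eval(default_dataset, protocol_config)


@pytest.fixture(scope="session")
def inter_only_report(default_dataset, protocol_config):
    return repeated_eval(default_dataset, replace(protocol_config, mode="inter_only"))


@pytest.fixture(scope="session")
def null_report(protocol_config):
    null_data = from_synthetic(generate(SyntheticSpec(effect=0.0)))
    return repeated_eval(null_data, protocol_config)


@pytest.fixture(scope="session")
def k_curve(default_dataset, protocol_config):
    return run_k_sweep(
        default_dataset,
        replace(protocol_config, n_repeats=10),
        (0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0),
    )
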