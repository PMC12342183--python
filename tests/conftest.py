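import numpy as np
import pytest

import sccontrast as sc

# training budget for the 400-cell benchmark experiments
FIXTURE_EPOCHS = 200
SEEDS = range(5)


@pytest.fixture(scope="session")
def fixture_data():
    """Canonical synthetic benchmark: counts, truth labels, marker map."""
    return sc.default_fixture()


@pytest.fixture(scope="session")
def processed(fixture_data):
    m, truth, markers = fixture_data
    proc = sc.preprocess(m)
    graph = sc.build_knn_graph(proc, k=15)
    return proc, graph, truth, markers


@pytest.fixture(scope="session")
def multi_seed_runs(processed):
    """Five full-model and five APS-ablated fits on the benchmark."""
    proc, graph, _, _ = processed
    runs = {}
    for seed in SEEDS:
        full = sc.fit(
            proc, graph,
            sc.EncoderConfig(n_clusters=4),
            sc.TrainConfig(max_epochs=FIXTURE_EPOCHS, seed=seed),
        )
        ablated = sc.fit(
            proc, graph,
            sc.EncoderConfig(n_clusters=4),
            sc.TrainConfig(max_epochs=FIXTURE_EPOCHS, seed=seed),
            aps_cfg=sc.ApsConfig(enabled=False),
        )
        runs[seed] = (full, ablated)
    return runs


@pytest.fixture(scope="session")
def trained(multi_seed_runs):
    """One converged full-model fit (seed 0)."""
    return multi_seed_runs[0][0]


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
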