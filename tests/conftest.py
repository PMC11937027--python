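"""Shared fixtures.

The expensive pieces — the synthetic training benchmark and the fitted
detector — are session-scoped and reused by the property and acceptance
tests; everything is generated programmatically from fixed seeds.
"""

import numpy as np
import pytest

import eegcorr as ec

TRAIN_SEED = 11


@pytest.fixture(scope="session")
def generator_spec():
    return ec.GeneratorSpec()


@pytest.fixture(scope="session")
def train_benchmark(generator_spec):
    """50 averaged normal clips (1750 raw clips, window 35), no injection."""
    return ec.make_benchmark(
        generator_spec, n_clips=1750, window=35, p_inject=0.0, seed=TRAIN_SEED
    )


@pytest.fixture(scope="session")
def trained(train_benchmark):
    """Detector fitted for 200 epochs on the normal training benchmark."""
    model = ec.GraphCorrelationModel(train_benchmark.graphs)
    return model.fit(epochs=200, seed=TRAIN_SEED)


@pytest.fixture(scope="session")
def epoch0(train_benchmark):
    """Same detector at its initialization (zero learning rate)."""
    model = ec.GraphCorrelationModel(train_benchmark.graphs)
    return model.fit(epochs=1, lr=0.0, seed=TRAIN_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_graph(rng):
    """An 8-channel correlation graph over random features."""
    X = ec.FeatureMatrix(rng.standard_normal((8, 16)))
    return ec.build_graph("corr", X)
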