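"""Shared fixtures.

Heavy artifacts (the default synthetic corpus, its feature/label table and a
trained partition model) are session-scoped so the classifier tests and the
acceptance checks share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

import odehybrid as oh
from odehybrid.classifier import build_training_table, train_partition_model
from odehybrid.zoo import build_birth_death_chain


@pytest.fixture(scope="session")
def benchmark_model() -> oh.OdeModel:
    return oh.make_benchmark_model()


@pytest.fixture(scope="session")
def benchmark_network(benchmark_model):
    return oh.network_from_decomposition(benchmark_model)


@pytest.fixture()
def immigration_death_model() -> oh.OdeModel:
    """One-species immigration-death process (k=5, d=1): stationarily Poisson(5)."""
    return build_birth_death_chain(5.0, [], [1.0])


@pytest.fixture(scope="session")
def default_corpus() -> oh.Corpus:
    return oh.generate_corpus(oh.CorpusSpec(seed=0))


@pytest.fixture(scope="session")
def corpus_table(default_corpus):
    table = build_training_table(default_corpus)
    assert table.attrs["skipped_models"] == []
    return table


@pytest.fixture(scope="session")
def partition_model(corpus_table):
    return train_partition_model(corpus_table, n_trees=300, seed=0,
                                 calibration_n_trees=100)


@pytest.fixture(scope="session")
def corpus_final_states(default_corpus) -> dict[str, np.ndarray]:
    """End-of-horizon deterministic state per corpus model (stationary proxy)."""
    finals = {}
    for model in default_corpus.models:
        traj = oh.run_presim(model, horizon=default_corpus.spec.presim_horizon,
                             n_grid=501)
        finals[model.name] = traj.states[-1]
    return finals
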