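"""Shared fixtures: a scaled-down synthetic experiment and its fitted results.

The scaled experiment keeps the study's structure (2x2 design, 3 replicates,
three organisms with >99% host reads, six planted response patterns
including the XOR cluster) while shrinking the catalog and library so the
whole suite runs quickly; per-gene read depth is kept in the same regime as
the full-size defaults.
"""

from __future__ import annotations

import pytest

from mhbcircuit.model import TripartiteCircuitModel
from mhbcircuit.synthetic import SyntheticConfig, generate_experiment

SMALL_GENES = {"host": 300, "fungus": 40, "bacterium": 20}


def small_config(seed: int = 11, **overrides) -> SyntheticConfig:
    params = dict(
        n_genes_per_organism=dict(SMALL_GENES),
        genes_per_cluster=20,
        library_size=60_000,
        seed=seed,
    )
    params.update(overrides)
    return SyntheticConfig(**params)


def fit_small(model: TripartiteCircuitModel, seed: int = 11, **overrides):
    params = dict(
        iterations=200,
        n_perm=499,
        k_max=8,
        bn_restarts=10,
        kmeans_restarts=10,
        seed=seed,
    )
    params.update(overrides)
    return model.fit(**params)


@pytest.fixture(scope="session")
def small_experiment():
    return generate_experiment(small_config())


@pytest.fixture(scope="session")
def small_model(small_experiment):
    exp = small_experiment
    model = TripartiteCircuitModel(
        exp.alignments, exp.catalog, exp.design, exp.annotations, exp.phenotype
    )
    model.truth = exp.truth
    return model


@pytest.fixture(scope="session")
def fitted(small_model):
    return fit_small(small_model)
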