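"""Shared fixtures: seeded synthetic datasets reused across the suite."""

from __future__ import annotations

import pytest

from cernaforge import expression as expr
from cernaforge.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def dataset():
    """Default study-condition dataset (150 coding, 60 lncRNA, 10 triads)."""
    return generate_dataset(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def null_dataset():
    """2,000 features with no planted structure: no DE, triads or co-expression."""
    return generate_dataset(
        SimulationConfig(
            n_coding_genes=1000,
            n_lncrnas=1000,
            n_mirnas=0,
            n_true_triads=0,
            n_de_features_per_contrast=0,
            cis_pair_fraction=0.0,
            seed=0,
        )
    )


@pytest.fixture(scope="session")
def fpkm(dataset):
    matrix = expr.ExpressionMatrix(dataset.counts, dataset.design, unit="count")
    return expr.compute_fpkm(matrix, dataset.feature_lengths())


@pytest.fixture(scope="session")
def null_fpkm(null_dataset):
    matrix = expr.ExpressionMatrix(null_dataset.counts, null_dataset.design, unit="count")
    return expr.compute_fpkm(matrix, null_dataset.feature_lengths())
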