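import numpy as np
import pytest

from pertbarcode.io import ExpressionMatrix, SampleMetadata
from pertbarcode.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix(rng):
    values = rng.normal(size=(20, 10))
    return ExpressionMatrix([f"g{i}" for i in range(20)],
                            [f"s{j}" for j in range(10)], values)


@pytest.fixture
def duplicate_metadata():
    """Six compounds, each profiled in duplicate, across three batches."""
    records = []
    for c in range(6):
        for r in range(2):
            records.append(SampleMetadata(
                sample_id=f"c{c}_r{r}", compound_id=f"cpd{c}",
                replicate_group_id=f"rg{c}", batch_id=f"b{(c + r) % 3}",
                cell_line="PC3", dose=10.0))
    return records


@pytest.fixture(scope="session")
def tiny_dataset():
    """Small synthetic dataset reused by cheap downstream tests."""
    config = SimulationConfig(n_genes=100, n_compounds=40, n_batches=6,
                              compounds_per_target_mean=8.0, seed=42)
    return simulate_dataset(config)
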