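import numpy as np
import pytest

from filterfdr import ExpressionDataset, SimulationConfig, generate_dataset


@pytest.fixture
def toy_dataset() -> ExpressionDataset:
    """Tiny 3-feature, 4-sample dataset with hand-checkable statistics."""
    values = np.array([
        [2.0, 2.0, 4.0, 4.0],   # group means 2 and 4
        [0.0, 0.0, 0.0, 0.0],   # constant feature
        [1.0, 3.0, 1.0, 3.0],   # equal group means
    ])
    return ExpressionDataset(values, ["g1", "g2", "g3"], ["s1", "s2", "s3", "s4"],
                             np.array(["A", "A", "B", "B"]))


@pytest.fixture
def random_dataset() -> ExpressionDataset:
    """Moderate null-plus-alternative dataset (m=400, pi0=0.8, nX=nY=5)."""
    cfg = SimulationConfig(m=400, n_datasets=1, seed=0)
    ds, _ = generate_dataset(cfg, 42)
    return ds


@pytest.fixture
def standard_dataset_truth():
    """One default-scale simulated dataset (m=1000) with its truth vector."""
    cfg = SimulationConfig()
    return generate_dataset(cfg, 2024)
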