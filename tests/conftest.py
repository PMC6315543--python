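import numpy as np
import pandas as pd
import pytest

from pcafe.containers import ExpressionMatrix, make_labels
from pcafe.synthetic import SimulationConfig, generate_dataset, generate_probe_annotation


@pytest.fixture(scope="session")
def default_dataset():
    """One default-configuration synthetic study, shared across tests."""
    config = SimulationConfig(seed=1)
    matrix, truth = generate_dataset(config)
    annotation = generate_probe_annotation(config)
    return config, matrix, truth, annotation


@pytest.fixture()
def small_matrix():
    """A small labelled random matrix for I/O and shape tests."""
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.normal(size=(30, 12)),
        index=[f"P{i:03d}" for i in range(30)],
        columns=[f"S{j:02d}" for j in range(12)],
    )
    labels = make_labels(values.columns, ["control"] * 6 + ["case"] * 6)
    return ExpressionMatrix(values, labels)
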