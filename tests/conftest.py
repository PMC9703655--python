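import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from omicsfusion.datatypes import (
    DrugResponseTable,
    MultiOmicsDataset,
    OmicsMatrix,
)

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_tiny_dataset(seed=0, n_cells=40, n_drugs=5, missing_rate=0.1):
    """Small hand-rolled multi-omics dataset for mechanics tests."""
    rng = np.random.default_rng(seed)
    cells = [f"c{i:02d}" for i in range(n_cells)]
    blocks = [
        OmicsMatrix("expression", cells, [f"G{j}" for j in range(8)],
                    rng.standard_normal((n_cells, 8)), "dense"),
        OmicsMatrix("mutation", cells, [f"M{j}" for j in range(6)],
                    (rng.random((n_cells, 6)) < 0.3).astype(float), "dense"),
    ]
    y = rng.standard_normal((n_cells, n_drugs))
    mask = rng.random((n_cells, n_drugs)) >= missing_rate
    resp = DrugResponseTable(cells, [f"d{j}" for j in range(n_drugs)], y, mask)
    return MultiOmicsDataset(blocks, resp)


@pytest.fixture
def tiny_dataset():
    return make_tiny_dataset()
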