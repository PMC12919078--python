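import numpy as np
import pandas as pd
import pytest

from ctxbench import (SimConfig, sample_ground_truth, simulate_cells,
                      ExpressionDataset)


@pytest.fixture(scope="session")
def tiny_config():
    """A small but non-trivial screen used by several suites."""
    return SimConfig(n_genes=300, n_perturbations=12, n_donors=2,
                     n_timepoints=2, cells_per_config=60,
                     control_cells_per_context=60,
                     targets_per_perturbation=20,
                     mechanism_shift=0.5, seed=101)


@pytest.fixture(scope="session")
def tiny_screen(tiny_config):
    gt = sample_ground_truth(tiny_config)
    ds = simulate_cells(gt, tiny_config)
    return tiny_config, gt, ds


@pytest.fixture
def toy_dataset():
    """A hand-built 6-cell, 4-gene dataset with two contexts."""
    counts = np.array([
        [10, 0, 5, 1],
        [8, 2, 4, 0],
        [0, 9, 3, 2],
        [1, 7, 2, 4],
        [5, 5, 5, 5],
        [2, 2, 2, 2],
    ], dtype=np.int32)
    obs = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(6)],
        "donor": ["d1", "d1", "d1", "d1", "d2", "d2"],
        "timepoint": ["t1"] * 6,
        "perturbation": ["pA", "pA", "ctrl", "ctrl", "pB", "ctrl"],
    })
    return ExpressionDataset(counts=counts,
                             genes=np.array(["g1", "g2", "g3", "g4"]),
                             obs=obs)
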