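import numpy as np
import pandas as pd
import pytest

from hkrank import ExpressionDataset, SimulationConfig, simulate_collection


def make_dataset(values, gene_ids=None, sample_ids=None, groups=None,
                 scale="linear", dataset_id="ds", organism="mouse"):
    """Build a small ExpressionDataset from a nested list / array."""
    arr = np.asarray(values, dtype=float)
    n_genes, n_samples = arr.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j}" for j in range(n_samples)]
    values = pd.DataFrame(arr, index=gene_ids, columns=sample_ids)
    if groups is not None:
        groups = pd.Series(list(groups), index=sample_ids)
    return ExpressionDataset(dataset_id=dataset_id, values=values, scale=scale,
                             groups=groups, organism=organism)


@pytest.fixture(scope="session")
def default_collection():
    """One simulated compendium at the default study conditions (seed 7)."""
    return simulate_collection(SimulationConfig(seed=7))


@pytest.fixture
def two_group_labels():
    return ["condition", "condition", "control", "control"]
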