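import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from earlens.io import ConditionProfile
from earlens.preprocess import (
    collapse_probes,
    condition_means,
    filter_detected,
    log2_transform,
    quantile_normalize,
)
from earlens.simulate import SimulationConfig, generate_dataset

settings.register_profile(
    "suite", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_dataset():
    """The full study-condition dataset: 12000 genes, 4x2x3 design, seed 1."""
    return generate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def processed(default_dataset):
    """Standard preprocessing products of the default dataset."""
    ds = default_dataset
    filtered = filter_detected(ds.matrix)
    normalized = quantile_normalize(filtered)
    gene_log2 = collapse_probes(log2_transform(normalized))
    gene_linear = collapse_probes(normalized)
    profile = condition_means(gene_log2)
    return {
        "filtered": filtered,
        "gene_log2": gene_log2,
        "gene_linear": gene_linear,
        "profile": profile,
    }


@pytest.fixture(scope="session")
def small_dataset():
    """A lighter dataset for stages that do not need the full design."""
    return generate_dataset(SimulationConfig(
        n_genes=3000, markers_per_type=100, targets_per_family=80, seed=7))


def make_profile(values: np.ndarray, genes=None) -> ConditionProfile:
    """Condition profile over a synthetic 4x2 design from a plain array."""
    values = np.asarray(values, dtype=float)
    n, c = values.shape
    cts = ["sensory", "neuronal", "endothelial", "mesenchymal"]
    organs = ["cochlea", "vestibule"]
    conds = [(ct, org) for ct in cts for org in organs][:c]
    cols = pd.MultiIndex.from_tuples(conds, names=["cell_type", "organ"])
    idx = genes if genes is not None else [f"g{i}" for i in range(n)]
    return ConditionProfile(means=pd.DataFrame(values, index=idx, columns=cols))
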