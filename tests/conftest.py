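import numpy as np
import pandas as pd
import pytest

from phenoinfer import (
    CategoricalColumn,
    ExpressionMatrix,
    PhenotypeTable,
    Region,
    SimulationSpec,
    simulate_categorical_dataset,
)
from phenoinfer.phenotypes import SEX_SYNONYMS


@pytest.fixture
def tiny_matrix():
    """3 regions x 4 samples with simple values."""
    regions = [Region("chr1", 0, 100), Region("chr1", 200, 300), Region("chr2", 0, 50)]
    values = np.array(
        [[1.0, 2.0, 3.0, 4.0], [0.0, 0.5, 1.0, 1.5], [5.0, 5.0, 5.0, 5.0]]
    )
    return ExpressionMatrix(regions, ["a", "b", "c", "d"], values, transformed=True)


@pytest.fixture
def sex_table():
    """Messy raw sex labels covering synonyms, placeholders and blanks."""
    raw = pd.DataFrame({"sex": ["M", "Female", "f", "not collected", "", "male"]})
    samples = [f"s{i}" for i in range(6)]
    schema = CategoricalColumn(name="sex", synonyms=dict(SEX_SYNONYMS))
    return PhenotypeTable(samples, {"sex": schema}, raw)


@pytest.fixture(scope="session")
def planted_dataset():
    """Reference two-level dataset: 20 markers/level at a 3-sigma shift."""
    return simulate_categorical_dataset(SimulationSpec(seed=101))


def split_halves(m, pheno, seed=0):
    """Random half split of samples (unstratified), as used for training."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(m.samples))
    half = len(order) // 2
    tr = [m.samples[i] for i in order[:half]]
    te = [m.samples[i] for i in order[half:]]
    return (
        m.subset_samples(tr),
        pheno.subset(tr),
        m.subset_samples(te),
        pheno.subset(te),
        order[:half],
        order[half:],
    )
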