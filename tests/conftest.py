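import numpy as np
import pandas as pd
import pytest

from flavornet import SyntheticConfig, simulate_dataset
from flavornet.datatypes import CountMatrix


@pytest.fixture(scope="session")
def default_dataset():
    """One default synthetic study (3 modules x 60 genes + 400 background)."""
    return simulate_dataset(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def small_config():
    """A fast, smaller configuration for structural tests."""
    return SyntheticConfig(
        n_genes=200,
        module_sizes=(50, 50),
        stage_profiles=((-2.0, 0.0, 2.0), (0.0, 2.0, -2.0)),
        trait_loadings={"sucrose": (1, 30.33, 63.7, 12.0), "malic_acid": (1, -6.675, 21.75, 2.7)},
        seed=7,
    )


def toy_count_matrix(counts: dict, lengths=None, stages=("S1", "S2")) -> CountMatrix:
    """Two-library count matrix from {gene: (x, y)} pairs."""
    genes = list(counts)
    df = pd.DataFrame(
        {f"{stages[0]}_R1": [counts[g][0] for g in genes],
         f"{stages[1]}_R1": [counts[g][1] for g in genes]},
        index=pd.Index(genes, name="gene_id"),
    )
    lens = pd.Series(lengths or {g: 1000 for g in genes}, name="length_bp")
    samples = pd.DataFrame(
        {"stage": list(stages), "replicate": [1, 1]},
        index=pd.Index(df.columns, name="library_id"),
    )
    return CountMatrix(counts=df, lengths=lens, samples=samples)
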