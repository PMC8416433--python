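import numpy as np
import pandas as pd
import pytest

from dilipred.ranking import GeneRanking
from dilipred.synthetic import SimConfig, simulate_study


def ranking_from_order(order, drug="d0", source="s0"):
    """GeneRanking where order[i] is the gene holding rank i+1."""
    ranks = pd.Series(
        {gene: i + 1 for i, gene in enumerate(order)}
    )
    return GeneRanking(drug_id=drug, source=source, ranks=ranks)


def random_ranking(rng, genes, drug="d0", source="s0"):
    perm = rng.permutation(len(genes)) + 1
    return GeneRanking(drug_id=drug, source=source, ranks=pd.Series(perm, index=genes))


@pytest.fixture(scope="session")
def tiny_config():
    """A study small enough for second-scale end-to-end runs."""
    return SimConfig(
        n_drugs=60,
        n_genes=200,
        n_cell_lines=3,
        n_informative_genes=16,
        gene_effect=3.0,
        n_tabular_features=10,
        n_informative_features=3,
        feature_effect=1.5,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_config):
    return simulate_study(tiny_config)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
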