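import numpy as np
import pytest

from sigmatch.data_io import ExpressionExperiment
from sigmatch.synthetic_data import SyntheticConfig


def make_experiment(values, n_control, gene_ids=None):
    """ExpressionExperiment from a genes x samples array; first columns are controls."""
    values = np.asarray(values, dtype=float)
    g, s = values.shape
    gene_ids = gene_ids or [f"g{i}" for i in range(g)]
    sample_ids = [f"s{i}" for i in range(s)]
    classes = ["control"] * n_control + ["treatment"] * (s - n_control)
    return ExpressionExperiment(gene_ids, sample_ids, values, classes)


@pytest.fixture
def small_config():
    """Desk-scale-but-fast study conditions for pipeline-level tests."""
    return SyntheticConfig(
        seed=7,
        n_genes=200,
        deg_fraction=0.05,
        n_drugs=40,
        conditions_per_drug=2,
        n_planted_reversers=3,
        planted_moa_size=5,
        n_bbb_high=4,
        n_moa_terms=5,
    )
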