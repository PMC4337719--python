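import numpy as np
import pandas as pd
import pytest

from cncnet import ExpressionMatrix, SyntheticConfig, simulate
from cncnet.config import PipelineConfig


def make_matrix(values, gene_ids=None, n_disease=None):
    """Small ExpressionMatrix helper: first half of columns = disease."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    n_disease = n_disease if n_disease is not None else n_samples // 2
    gene_ids = gene_ids or [f"g{i}" for i in range(n_genes)]
    samples = [f"d{i}" for i in range(n_disease)] + \
              [f"c{i}" for i in range(n_samples - n_disease)]
    groups = pd.Series(["disease"] * n_disease +
                       ["control"] * (n_samples - n_disease), index=samples)
    return ExpressionMatrix(pd.DataFrame(values, index=gene_ids,
                                         columns=samples), groups)


@pytest.fixture(scope="session")
def small_synth_config():
    return SyntheticConfig(
        n_mrna=400, n_lnc=100, n_planted_pairs_per_category=5,
        frac_de=0.1, n_modules=1, module_size=8,
        n_chromosomes=6, chrom_length=30_000_000, seed=42)


@pytest.fixture(scope="session")
def small_bundle(small_synth_config):
    return simulate(small_synth_config)


@pytest.fixture()
def pipeline_config():
    return PipelineConfig()
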