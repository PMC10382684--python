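from __future__ import annotations

import numpy as np
import pytest

from cl2pt.datasets_io import DomainDataset, ExpressionMatrix, ResponseLabels
from cl2pt.predictors import TrainingConfig
from cl2pt.synthetic import SyntheticConfig, generate_domain_pair


def make_dataset(values, y, domain="source", gene_ids=None, prefix="s"):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"G{i}" for i in range(values.shape[0])]
    sample_ids = [f"{prefix}{j}" for j in range(values.shape[1])]
    expr = ExpressionMatrix(gene_ids, sample_ids, values)
    return DomainDataset(expr, ResponseLabels(sample_ids, np.asarray(y)), domain)


@pytest.fixture(scope="session")
def small_pair():
    """A modest synthetic two-domain pair with all three gene roles."""
    cfg = SyntheticConfig(
        n_source=150,
        n_target=100,
        n_invariant_informative=30,
        n_invariant_null=40,
        n_shifted=60,
        effect_size=1.0,
        shift_size=3.0,
        seed=7,
    )
    return generate_domain_pair(cfg)


@pytest.fixture()
def tiny_training():
    """A deliberately small training config so tests stay fast."""
    return TrainingConfig(
        p_grid=(5, 10),
        repeats=2,
        seed=11,
        lambda_stage1_exponents=(-2.0, -1.0, 0.0),
        k_grid=(3, 5, 7),
    )
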