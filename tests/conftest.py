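import numpy as np
import pandas as pd
import pytest

import txstress as tx


@pytest.fixture
def small_catalog() -> tx.GeneCatalog:
    return tx.simulate_gene_catalog(500, seed=11)


@pytest.fixture
def toy_survival() -> pd.DataFrame:
    """4-animal toy: group A events at weeks 1,2; group B at 3,4."""
    return pd.DataFrame(
        {
            "animal_id": ["a1", "a2", "b1", "b2"],
            "group": ["A", "A", "B", "B"],
            "sex": ["F", "M", "F", "M"],
            "time_weeks": [1.0, 2.0, 3.0, 4.0],
            "event": [1, 1, 1, 1],
        }
    )


def null_expression(n_genes: int, n_per_group: int, seed: int, noise_sd: float = 0.25):
    """Two identical-parameter groups with no lesion load and no programmed DE."""
    catalog = tx.simulate_gene_catalog(n_genes, seed=seed)
    params = dict(
        lambda_per_kb=0.0,
        noise_sd_log2=noise_sd,
        n_samples_per_group=n_per_group,
        seed=seed,
    )
    expr, design, _ = tx.simulate_expression(
        catalog,
        [("g1", tx.LesionModelParams(**params)), ("g2", tx.LesionModelParams(**params))],
    )
    return catalog, expr, design
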