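import numpy as np
import pandas as pd
import pytest

from loopmed import ExpressionMatrix, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix():
    """4 entities x 8 samples (4 injured + 4 sham at one time point)."""
    rng = np.random.default_rng(0)
    sample_ids = [f"inj{i}" for i in range(4)] + [f"sham{i}" for i in range(4)]
    meta = pd.DataFrame(
        {
            "time_point": ["24h"] * 8,
            "condition": ["injured"] * 4 + ["sham"] * 4,
            "replicate": [1, 2, 3, 4] * 2,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    values = pd.DataFrame(
        rng.uniform(1.0, 20.0, size=(4, 8)),
        index=[f"e{i}" for i in range(4)],
        columns=sample_ids,
    )
    return ExpressionMatrix(values, meta)


@pytest.fixture(scope="session")
def default_dataset():
    """One small mixed-class dataset reused by read-only tests."""
    return generate_dataset(
        {"M_T": 3, "M_M": 3, "M_TM": 3, "NULL": 3},
        n_decoy_edges=10,
        n_samples=30,
        noise_sd=0.5,
        seed=7,
    )


def injured_rows(ds, spec):
    """(x, m, y) injured-condition vectors for one planted triad."""
    x = ds.mirna_expr.subset_samples(condition="injured").row(spec.mirna_id)
    m = ds.tf_expr.subset_samples(condition="injured").row(spec.tf_id)
    y = ds.gene_expr.subset_samples(condition="injured").row(spec.gene_id)
    return x, m, y
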