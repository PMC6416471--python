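import numpy as np
import pandas as pd
import pytest

from erp import expression, synthetic


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic expression dataset (fixed seed) with truth."""
    return synthetic.generate_expression(synthetic.ExpressionConfig(seed=42))


@pytest.fixture(scope="session")
def noise_free_dataset():
    return synthetic.generate_expression(
        synthetic.ExpressionConfig(seed=7, noise_sd=0.0)
    )


@pytest.fixture()
def small_matrix():
    """3 genes x WT ribo controls/treatment, hand-checkable."""
    values = pd.DataFrame(
        {
            "c0": [4.0, 16.0, 10.0],
            "c1": [8.0, 4.0, 10.0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    metas = [
        expression.SampleMeta("c0", "WT", 0.0, "ribo"),
        expression.SampleMeta("c1", "WT", 1.0, "ribo"),
    ]
    return expression.ExpressionMatrix(values, metas)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
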