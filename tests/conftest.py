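import numpy as np
import pandas as pd
import pytest

from txcoord.io import ExpressionMatrix, SampleMetadata


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def counts_expr(rng):
    """50 random genes x 12 samples of raw counts, two groups of 6."""
    data = pd.DataFrame(
        rng.poisson(lam=rng.uniform(0.5, 60, size=(50, 1)), size=(50, 12)).astype(float),
        index=[f"g{i:03d}" for i in range(50)],
        columns=[f"s{j:02d}" for j in range(12)],
    )
    return ExpressionMatrix(data, units="raw_counts")


@pytest.fixture
def two_group_meta(counts_expr):
    ids = counts_expr.sample_ids
    return SampleMetadata(pd.Series(["A"] * 6 + ["B"] * 6, index=ids))


def pearson_scalar(x, y):
    """Textbook Pearson correlation, scalar loop — independent oracle."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx * vy) ** 0.5
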