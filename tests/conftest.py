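import numpy as np
import pytest

from harp.harmonize import normalize_columns
from harp.matrixio import CompositionMatrix, ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_expression():
    """3 genes x 2 samples, values 1..6."""
    return ExpressionMatrix(
        np.arange(1.0, 7.0).reshape(3, 2),
        ["g1", "g2", "g3"], ["s1", "s2"])


def make_consistent_instance(rng, g=30, q=3, n=8, noise=0.0):
    """Random (Y, X, C) with Y = XC (optionally times mild noise).

    X columns are normalized to sum to g and C columns live on the simplex,
    so the triple is scale-coherent by construction.
    """
    x = ExpressionMatrix(
        rng.uniform(0.2, 3.0, (g, q)),
        [f"g{i}" for i in range(g)],
        [f"ct{j}" for j in range(q)])
    x = normalize_columns(x)
    c = CompositionMatrix(
        rng.dirichlet(np.ones(q) * 5.0, n).T,
        list(x.column_ids), [f"s{m}" for m in range(n)])
    y_vals = x.values @ c.values
    if noise > 0:
        y_vals = y_vals * np.maximum(rng.normal(1.0, noise, y_vals.shape), 0.05)
    y = ExpressionMatrix(y_vals, list(x.gene_ids), list(c.sample_ids))
    return y, x, c


@pytest.fixture
def consistent_instance(rng):
    return make_consistent_instance(rng)
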