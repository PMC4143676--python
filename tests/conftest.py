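import numpy as np
import pytest

from towgene.adjust import ResidualData


def brute_force_tow(y, X):
    """Explicit-loop TOW oracle: optimal weights and statistic by direct sums.

    Independent of the package's vectorized path; used to freeze expected
    values on small instances.
    """
    y = [float(v) for v in y]
    n = len(y)
    M = len(X[0])
    ybar = sum(y) / n
    weights = []
    for m in range(M):
        col = [float(X[i][m]) for i in range(n)]
        xbar = sum(col) / n
        num = sum((y[i] - ybar) * (col[i] - xbar) for i in range(n))
        den = sum((col[i] - xbar) ** 2 for i in range(n))
        weights.append(num / den if den > 0 else 0.0)
    xo = [sum(weights[m] * float(X[i][m]) for m in range(M)) for i in range(n)]
    xobar = sum(xo) / n
    stat = sum((y[i] - ybar) * (xo[i] - xobar) for i in range(n))
    return stat, weights


@pytest.fixture
def make_resid():
    """Factory for ResidualData straight from raw (already adjusted) arrays."""

    def _make(y, X, trait="y"):
        return ResidualData(
            y_resid=np.asarray(y, dtype=float),
            x_resid=np.asarray(X, dtype=float),
            trait_name=trait,
        )

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
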