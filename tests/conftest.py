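import numpy as np
import pandas as pd
import pytest

from crossnet.preprocessing import ExpressionMatrix


def kkt_violation(X, y, coef, penalty, mixing):
    """Independent stationarity (KKT) check of an elastic-net solution.

    For the objective ||y - Xw - b||²/(2T) + s(λ||w||₁ + (1-λ)/2 ||w||₂²)
    with a fitted intercept, optimality requires, on centered data,
    x_j'r/T = s(λ sign(w_j) + (1-λ) w_j) for active coordinates and
    |x_j'r/T| ≤ sλ for inactive ones. Returns the worst violation.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    T = len(y)
    g = Xc.T @ (yc - Xc @ coef) / T
    active = coef != 0
    worst = 0.0
    if active.any():
        worst = np.max(
            np.abs(g[active] - penalty * (mixing * np.sign(coef[active])
                                          + (1 - mixing) * coef[active]))
        )
    if (~active).any():
        worst = max(worst, float(np.max(np.abs(g[~active])) - penalty * mixing))
    return worst


def make_matrix(values, genes=None, samples=None, condition="WT", stage="raw"):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), condition, stage
    )


@pytest.fixture
def toy_matrix():
    return make_matrix([[1.0, 2.0, 6.0], [4.0, 4.0, 4.0], [0.0, 0.0, 7.0]],
                       genes=["dyn", "flat", "burst"])
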