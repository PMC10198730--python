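import numpy as np
import pytest

from circdeconv import ExpressionMatrix, ProportionMatrix


def brute_force_nnls(X, y):
    """Support-enumeration NNLS oracle.

    Solves unconstrained least squares on every subset of predictors, keeps
    the best feasible (non-negative) solution. Exponential in k — usable
    only for tiny instances, which is exactly why it is a trustworthy
    reference for the active-set solver.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    best_obj = np.linalg.norm(y)  # empty support
    best_beta = np.zeros(k)
    for mask in range(1, 2**k):
        idx = [j for j in range(k) if mask >> j & 1]
        sol, *_ = np.linalg.lstsq(X[:, idx], y, rcond=None)
        if np.any(sol < 0):
            continue
        beta = np.zeros(k)
        beta[idx] = sol
        obj = np.linalg.norm(X @ beta - y)
        if obj < best_obj:
            best_obj, best_beta = obj, beta
    return best_beta, best_obj


@pytest.fixture
def small_expression():
    return ExpressionMatrix(
        ["t1", "t2", "t3"],
        ["s1", "s2"],
        [[1.0, 0.0], [0.5, 2.0], [3.0, 4.0]],
        "TPM",
    )


@pytest.fixture
def two_type_proportions():
    return ProportionMatrix(
        ["T", "B"], ["s1", "s2"], [[0.6, 0.3], [0.4, 0.7]]
    )
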