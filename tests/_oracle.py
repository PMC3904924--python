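"""Independent oracles used by the tests.

The epigraph-form LP below is constructed independently of the package's
split-variable formulation (different variables, different constraint
matrix, interior-point solver) and serves as the reference optimum for the
CPL criteria. The feasibility oracle checks linear separability directly as
an LP feasibility problem, without any criterion function.
"""

import numpy as np
from scipy.optimize import linprog


def oracle_min_psi(X, y, alpha, gamma, lam, delta=1.0):
    """Reference optimum of Psi_lambda via an epigraph formulation:
    variables [w (free), t >= |w|, theta (free), xi >= hinge]."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    m, n = X.shape
    # variable order: w(n), t(n), theta(1), xi(m)
    c = np.concatenate([np.zeros(n), lam * np.asarray(gamma, float), [0.0],
                        np.asarray(alpha, float)])
    rows = []
    rhs = []
    # t_i >= w_i  ->  w_i - t_i <= 0 ;  t_i >= -w_i -> -w_i - t_i <= 0
    for i in range(n):
        r = np.zeros(2 * n + 1 + m)
        r[i] = 1.0
        r[n + i] = -1.0
        rows.append(r)
        rhs.append(0.0)
        r2 = np.zeros(2 * n + 1 + m)
        r2[i] = -1.0
        r2[n + i] = -1.0
        rows.append(r2)
        rhs.append(0.0)
    # xi_j >= delta - y_j (w.x_j - theta)
    for j in range(m):
        r = np.zeros(2 * n + 1 + m)
        r[:n] = -y[j] * X[j]
        r[2 * n] = y[j]
        r[2 * n + 1 + j] = -1.0
        rows.append(r)
        rhs.append(-delta)
    bounds = ([(None, None)] * n + [(0, None)] * n + [(None, None)]
              + [(0, None)] * m)
    res = linprog(c, A_ub=np.array(rows), b_ub=np.array(rhs), bounds=bounds,
                  method="highs-ipm")
    assert res.status == 0, res.message
    return float(res.fun)


def oracle_separable(X, y):
    """LP feasibility of y_j (w.x_j - theta) >= 1 for all j; feasible iff
    the two classes are strictly linearly separable."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    m, n = X.shape
    A = np.hstack([-y[:, None] * X, y[:, None]])
    b = -np.ones(m)
    res = linprog(np.zeros(n + 1), A_ub=A, b_ub=b,
                  bounds=[(None, None)] * (n + 1), method="highs")
    return res.status == 0


def random_instance(rng, m_max=40, n_max=8):
    """A small random two-class instance with both classes non-empty."""
    m = int(rng.integers(4, m_max + 1))
    n = int(rng.integers(1, n_max + 1))
    X = rng.normal(size=(m, n))
    while True:
        y = rng.choice([-1, 1], size=m)
        if (y == 1).any() and (y == -1).any():
            break
    return X, y
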