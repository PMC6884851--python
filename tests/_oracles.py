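"""Independent oracles for the test suite.

These deliberately avoid the package's inference path: the frequentist
check-loss minimizer is solved as a linear program, and scalar
quantile-loss minimization by grid search.
"""

import numpy as np
from scipy.optimize import linprog


def lp_quantreg(y, X, tau):
    """Exact check-loss minimizer via the standard LP formulation.

    min tau * 1'u + (1 - tau) * 1'w  s.t.  X b + u - w = y, u, w >= 0.
    """
    n, p = X.shape
    c = np.concatenate([np.zeros(p), tau * np.ones(n), (1 - tau) * np.ones(n)])
    A_eq = np.hstack([X, np.eye(n), -np.eye(n)])
    bounds = [(None, None)] * p + [(0, None)] * (2 * n)
    res = linprog(c, A_eq=A_eq, b_eq=y, bounds=bounds, method="highs")
    if not res.success:
        raise RuntimeError(f"LP oracle failed: {res.message}")
    return res.x[:p]


def grid_argmin_loss(y, tau, loss, grid=None):
    """Scalar minimizer of sum_i loss(y_i - c) by brute-force grid."""
    if grid is None:
        grid = np.linspace(y.min(), y.max(), 20001)
    totals = np.array([loss(y - c, tau).sum() for c in grid])
    return grid[int(np.argmin(totals))]
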