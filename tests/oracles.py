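"""Independent brute-force oracles shared by the test suite.

These deliberately avoid the package's own code paths: the projection
oracle enumerates a grid over the feasible region, and the partial-
likelihood oracle maximizes the one-dimensional Cox likelihood directly.
"""

import numpy as np
from scipy.optimize import minimize_scalar


def grid_projection_objective(x: np.ndarray, y: np.ndarray, step: float = 0.005):
    """Minimum of ||y - Xw||^2 over the grid {w >= 0, sum w <= 1}.

    Supports up to 4 mixture components by nested enumeration of all grid
    points with the given step.
    """
    k = x.shape[1]
    vals = np.arange(0.0, 1.0 + step / 2, step)
    best = np.inf

    def recurse(prefix, remaining):
        nonlocal best
        if len(prefix) == k - 1:
            w_last = vals[vals <= remaining + 1e-12]
            w = np.tile(prefix, (len(w_last), 1))
            w = np.column_stack([w, w_last])
            resid = y[None, :] - w @ x.T
            best = min(best, float((resid**2).sum(axis=1).min()))
            return
        for v in vals[vals <= remaining + 1e-12]:
            recurse(prefix + [v], remaining - v)

    recurse([], 1.0)
    return best


def cox_partial_loglik_1d(beta: float, time, event, x) -> float:
    """Breslow partial log-likelihood for one covariate (no tied times)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    ll = 0.0
    for i in np.where(event == 1)[0]:
        at_risk = time >= time[i]
        ll += beta * x[i] - np.log(np.exp(beta * x[at_risk]).sum())
    return ll


def cox_mle_1d(time, event, x) -> float:
    """Brute-force maximizer of the 1-D partial likelihood."""
    res = minimize_scalar(
        lambda b: -cox_partial_loglik_1d(b, time, event, x),
        bounds=(-10, 10),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)
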