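"""Independent reference implementations used only to cross-check results.

These deliberately avoid the package's own solver paths: the penalized
logistic objective is minimized by a general-purpose bound-constrained
quasi-Newton method on the positive/negative-part splitting of the L1 term.
"""

import numpy as np
from scipy.optimize import minimize


def l1_logistic_min_objective(X: np.ndarray, y: np.ndarray, lam: float) -> float:
    """Minimum of (1/n)*neg-loglik + lam*||beta||_1 (unpenalized intercept),
    found with L-BFGS-B on the split beta = beta_plus - beta_minus."""
    n, d = X.shape

    def objective(params):
        b0 = params[0]
        beta = params[1 : 1 + d] - params[1 + d :]
        eta = b0 + X @ beta
        nll = -np.sum(y * eta - np.logaddexp(0.0, eta)) / n
        return nll + lam * params[1:].sum()

    res = minimize(
        objective,
        np.zeros(1 + 2 * d),
        method="L-BFGS-B",
        bounds=[(None, None)] + [(0.0, None)] * (2 * d),
        options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-10},
    )
    return float(res.fun)


def penalized_objective(X, y, lam, intercept, beta) -> float:
    """Evaluate the node-wise objective at a given solution."""
    n = X.shape[0]
    eta = intercept + X @ beta
    nll = -np.sum(y * eta - np.logaddexp(0.0, eta)) / n
    return float(nll + lam * np.abs(beta).sum())
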