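"""Sparse Ising network estimation via node-wise L1 logistic regression.

Each item is regressed on all remaining items over a descending grid of
penalty values; the per-node penalty is chosen by the Extended Bayesian
Information Criterion (EBIC) and directed coefficients are combined into a
symmetric edge-weight matrix with the AND (default) or OR rule.  Binary
0/1 coding is used throughout, so weights read as log-odds interaction
effects and intercepts as node thresholds.

Internally the data matrix is collapsed to unique response patterns with
frequency counts before solving, which makes the fit cost depend on the
number of distinct patterns rather than the subject count — the estimates
are identical to fitting the raw rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._solver import compress_binary, lambda_max, logistic_lasso_path
from .datatypes import BinaryMatrix, IsingNetwork
from .errors import DegenerateNodeWarning, InvalidSpecError

__all__ = [
    "RegularizationConfig",
    "NodewiseFit",
    "ebic",
    "fit_nodewise",
    "fit_node_path",
    "select_lambda",
    "combine_edges",
    "estimate_network",
    "estimate_network_from_patterns",
]

_INTERCEPT_CAP = 30.0


@dataclass(frozen=True)
class RegularizationConfig:
    """Penalty-grid and model-selection settings for the node-wise fits.

    ``n_lambda`` penalties are spaced (log by default) from each node's
    own lambda_max down to ``lambda_max * lambda_min_ratio``.  ``gamma``
    is the EBIC density-prior weight; 0 recovers plain BIC.
    """

    n_lambda: int = 100
    gamma: float = 0.25
    lambda_min_ratio: float = 0.01
    combine_rule: str = "AND"
    spacing: str = "log"  # or "linear"
    standardize: bool = False
    tol: float = 1e-7

    def __post_init__(self) -> None:
        if self.n_lambda < 2:
            raise InvalidSpecError("n_lambda must be >= 2")
        if not 0.0 <= self.gamma <= 1.0:
            raise InvalidSpecError("gamma must lie in [0, 1]")
        if not 0.0 < self.lambda_min_ratio < 1.0:
            raise InvalidSpecError("lambda_min_ratio must lie in (0, 1)")
        if self.combine_rule not in ("AND", "OR"):
            raise InvalidSpecError("combine_rule must be 'AND' or 'OR'")
        if self.spacing not in ("log", "linear"):
            raise InvalidSpecError("spacing must be 'log' or 'linear'")


@dataclass
class NodewiseFit:
    """Regularization path of one node's logistic regression.

    ``coefficients`` has one row per penalty (neighbors in data order,
    the node itself excluded); ``selected`` indexes the EBIC-chosen row.
    The path is stored with ``lambda_path`` descending, so index 0 is the
    sparsest (largest penalty) model.
    """

    node: str
    neighbor_codes: list[str]
    lambda_path: np.ndarray
    coefficients: np.ndarray
    intercepts: np.ndarray
    loglik: np.ndarray
    ebic: np.ndarray
    selected: int
    degenerate: bool = False

    @property
    def selected_coefficients(self) -> np.ndarray:
        return self.coefficients[self.selected]

    @property
    def selected_intercept(self) -> float:
        return float(self.intercepts[self.selected])


def ebic(loglik: float, k: int, n: int, p: int, gamma: float) -> float:
    """Extended BIC: ``-2*loglik + k*log(n) + 2*gamma*k*log(p - 1)``.

    ``k`` is the number of nonzero neighbor coefficients and ``p - 1`` the
    size of each node's candidate-predictor set; ``gamma=0`` reduces to BIC.
    """
    return float(-2.0 * loglik + k * np.log(n) + 2.0 * gamma * k * np.log(p - 1))


def _lambda_grid(lam_max: float, config: RegularizationConfig) -> np.ndarray:
    # The top of the grid sits exactly on the null-model KKT boundary; a
    # hair of upward slack keeps round-off from letting a ~1e-16 coefficient
    # enter there, which would deny EBIC a true k=0 candidate.
    lam_top = lam_max * (1.0 + 1e-6)
    lam_min = lam_max * config.lambda_min_ratio
    if config.spacing == "log":
        return np.geomspace(lam_top, lam_min, config.n_lambda)
    return np.linspace(lam_top, lam_min, config.n_lambda)


def fit_nodewise(
    binary: BinaryMatrix, node: str, lam: float, tol: float = 1e-8
) -> tuple[np.ndarray, float, float]:
    """Single-penalty L1 logistic fit of one node on all remaining items.

    Returns ``(coefficients, intercept, loglik)`` where ``loglik`` is the
    total logistic log-likelihood at the solution.  A constant response
    column yields the degenerate all-zero fit with a capped intercept.
    """
    j = binary.item_codes.index(node)
    patterns, counts = compress_binary(binary.values)
    y = patterns[:, j].copy()
    X = np.ascontiguousarray(np.delete(patterns, j, axis=1))
    if y.min() == y.max() or (counts @ y) in (0.0, counts.sum()):
        warnings.warn(f"node {node!r} is constant; fit degenerate", DegenerateNodeWarning)
    intercepts, coefs, logliks = logistic_lasso_path(
        X, y, counts, np.array([lam]), tol=tol, max_outer=200, max_inner=500
    )
    intercept = float(np.clip(intercepts[0], -_INTERCEPT_CAP, _INTERCEPT_CAP))
    return coefs[0], intercept, float(logliks[0])


def _fit_path_from_patterns(
    patterns: np.ndarray,
    counts: np.ndarray,
    codes: list[str],
    j: int,
    config: RegularizationConfig,
) -> NodewiseFit:
    y = patterns[:, j].copy()
    X = np.ascontiguousarray(np.delete(patterns, j, axis=1))
    neighbor_codes = [c for i, c in enumerate(codes) if i != j]
    n = int(round(counts.sum()))
    d = X.shape[1]
    p = d + 1

    scale = np.ones(d)
    if config.standardize:
        mean = (counts @ X) / counts.sum()
        var = (counts @ (X - mean) ** 2) / counts.sum()
        scale = np.sqrt(var)
        scale[scale == 0.0] = 1.0
        X = np.ascontiguousarray(X / scale)

    ysum = counts @ y
    degenerate = ysum == 0.0 or ysum == counts.sum()
    if degenerate:
        warnings.warn(f"node {codes[j]!r} is constant; isolated", DegenerateNodeWarning)

    lam_max = lambda_max(X, y, counts)
    if lam_max <= 0.0:
        lam_max = 1.0  # degenerate response: grid is arbitrary, fits are null
    grid = _lambda_grid(lam_max, config)
    intercepts, coefs, logliks = logistic_lasso_path(
        X, y, counts, grid, tol=config.tol
    )
    coefs = coefs / scale  # undo standardization on the coefficient scale
    intercepts = np.clip(intercepts, -_INTERCEPT_CAP, _INTERCEPT_CAP)
    k = np.count_nonzero(coefs, axis=1)
    ebics = np.array(
        [ebic(logliks[i], int(k[i]), n, p, config.gamma) for i in range(len(grid))]
    )
    fit = NodewiseFit(
        node=codes[j],
        neighbor_codes=neighbor_codes,
        lambda_path=grid,
        coefficients=coefs,
        intercepts=intercepts,
        loglik=logliks,
        ebic=ebics,
        selected=0,
        degenerate=degenerate,
    )
    fit.selected = select_lambda(fit)
    return fit


def fit_node_path(
    binary: BinaryMatrix, node: str, config: RegularizationConfig | None = None
) -> NodewiseFit:
    """Full penalty path + EBIC selection for one node."""
    config = config or RegularizationConfig()
    patterns, counts = compress_binary(binary.values)
    j = binary.item_codes.index(node)
    return _fit_path_from_patterns(patterns, counts, list(binary.item_codes), j, config)


def select_lambda(fit: NodewiseFit) -> int:
    """Index of the EBIC-minimizing penalty; ties go to the larger penalty.

    The path is stored descending in lambda, so the first minimum is the
    sparsest of the tied models.
    """
    return int(np.argmin(fit.ebic))


def combine_edges(fits: dict[str, NodewiseFit], rule: str = "AND") -> IsingNetwork:
    """Symmetrize directed node-wise coefficients into an edge-weight matrix.

    AND rule: an edge exists only if both directed coefficients are
    nonzero; its weight is their mean.  OR rule: an edge exists if either
    is nonzero; its weight is the mean of the nonzero estimates.
    """
    if rule not in ("AND", "OR"):
        raise InvalidSpecError("rule must be 'AND' or 'OR'")
    codes = list(fits.keys())
    p = len(codes)
    pos = {c: i for i, c in enumerate(codes)}
    directed = np.zeros((p, p))
    thresholds = np.zeros(p)
    for i, node in enumerate(codes):
        fit = fits[node]
        thresholds[i] = fit.selected_intercept
        for nb, b in zip(fit.neighbor_codes, fit.selected_coefficients):
            directed[i, pos[nb]] = b
    W = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            a, b = directed[i, j], directed[j, i]
            if rule == "AND":
                w = (a + b) / 2.0 if (a != 0.0 and b != 0.0) else 0.0
            else:
                if a != 0.0 and b != 0.0:
                    w = (a + b) / 2.0
                else:
                    w = a + b  # at most one is nonzero
            W[i, j] = W[j, i] = w
    return IsingNetwork(codes, W, thresholds)


def estimate_network_from_patterns(
    patterns: np.ndarray,
    counts: np.ndarray,
    codes: list[str],
    config: RegularizationConfig | None = None,
) -> IsingNetwork:
    """Estimate a network from pre-compressed unique patterns and counts.

    This is the workhorse used by the bootstrap and permutation loops,
    where the pattern set is fixed and only the counts change.
    """
    config = config or RegularizationConfig()
    keep = counts > 0
    patterns, counts = np.ascontiguousarray(patterns[keep]), counts[keep]
    fits = {
        code: _fit_path_from_patterns(patterns, counts, codes, j, config)
        for j, code in enumerate(codes)
    }
    return combine_edges(fits, config.combine_rule)


def estimate_network(
    binary: BinaryMatrix, config: RegularizationConfig | None = None
) -> IsingNetwork:
    """Estimate the full Ising symptom network from a binary data matrix.

    Runs the per-node penalty path with EBIC selection for every item and
    combines the directed coefficients under the configured rule.
    Deterministic given data and configuration.
    """
    config = config or RegularizationConfig()
    if binary.n_items < 2:
        raise InvalidSpecError("need at least 2 items to estimate a network")
    patterns, counts = compress_binary(binary.values)
    return estimate_network_from_patterns(
        patterns, counts, list(binary.item_codes), config
    )
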