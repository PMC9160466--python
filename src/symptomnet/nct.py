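"""Permutation comparison of two estimated symptom networks.

Group labels are permuted over the pooled subjects (group sizes are
preserved exactly) and both networks are re-estimated from scratch for
every permutation with the same regularization settings.  Three null
hypotheses are probed: network-structure invariance (statistic M, the
maximum absolute edge difference), global-strength invariance (statistic
S, the absolute difference of summed absolute edge weights), and equality
of each individual edge, with the per-edge permutation p-values adjusted
by the Holm-Bonferroni step-down procedure.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datatypes import BinaryMatrix, IsingNetwork
from .elasso import RegularizationConfig, estimate_network_from_patterns
from .errors import (
    DegenerateNodeWarning,
    IncompatibleDatasetsError,
    InvalidPValueError,
)
from .inference import _compress_with_inverse

__all__ = ["NCTResult", "global_strength", "holm_adjust", "network_comparison_test"]


def global_strength(network: IsingNetwork, signed: bool = False) -> float:
    """Total network strength: the sum of (absolute) edge weights.

    Absolute values are the default convention; ``signed=True`` sums the
    raw weights instead.
    """
    iu = np.triu_indices(network.n_items, k=1)
    w = network.weights[iu]
    return float(w.sum() if signed else np.abs(w).sum())


def holm_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values, capped at 1.

    Sorted p-values are multiplied by decreasing factors (m, m-1, ..., 1)
    with a cumulative maximum enforcing monotonicity; the output order
    matches the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0.0) | (p > 1.0)):
        raise InvalidPValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="holm")[1]


@dataclass
class NCTResult:
    """Observed statistics and permutation p-values of a two-network comparison."""

    item_codes: list[str]
    m_statistic: float
    s_statistic: float
    p_structure: float
    p_strength: float
    edge_table: pd.DataFrame
    global_strength_1: float
    global_strength_2: float
    n_perm: int
    seed: int

    @property
    def per_edge_p(self) -> pd.DataFrame:
        return self.edge_table

    def to_json(self, path: str | Path) -> None:
        payload = {
            "item_codes": self.item_codes,
            "m_statistic": self.m_statistic,
            "s_statistic": self.s_statistic,
            "p_structure": self.p_structure,
            "p_strength": self.p_strength,
            "global_strength_1": self.global_strength_1,
            "global_strength_2": self.global_strength_2,
            "n_perm": self.n_perm,
            "seed": self.seed,
            "edges": self.edge_table.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def _pattern_counts(inverse: np.ndarray, idx: np.ndarray, n_patterns: int) -> np.ndarray:
    return np.bincount(inverse[idx], minlength=n_patterns).astype(float)


def network_comparison_test(
    data1: BinaryMatrix,
    data2: BinaryMatrix,
    reg: RegularizationConfig | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> NCTResult:
    """Permutation test of structure, strength and per-edge invariance.

    Permutation p-values use the add-one estimator
    ``(1 + #{perm >= observed}) / (1 + n_perm)``, so the smallest
    attainable p is ``1/(n_perm + 1)``.
    """
    if list(data1.item_codes) != list(data2.item_codes):
        raise IncompatibleDatasetsError(
            f"item sets differ: {data1.item_codes} vs {data2.item_codes}"
        )
    reg = reg or RegularizationConfig()
    codes = list(data1.item_codes)
    p = len(codes)
    n1, n2 = data1.n_subjects, data2.n_subjects
    pooled = np.vstack([data1.values, data2.values])
    patterns, _, inverse = _compress_with_inverse(pooled)
    n_patterns = patterns.shape[0]
    iu = np.triu_indices(p, k=1)

    def estimate_pair(idx1: np.ndarray, idx2: np.ndarray):
        c1 = _pattern_counts(inverse, idx1, n_patterns)
        c2 = _pattern_counts(inverse, idx2, n_patterns)
        net1 = estimate_network_from_patterns(patterns, c1, codes, reg)
        net2 = estimate_network_from_patterns(patterns, c2, codes, reg)
        return net1, net2

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateNodeWarning)
        net1, net2 = estimate_pair(np.arange(n1), np.arange(n1, n1 + n2))
        obs_diff = np.abs(net1.weights - net2.weights)[iu]
        obs_m = float(obs_diff.max())
        s1, s2 = global_strength(net1), global_strength(net2)
        obs_s = abs(s1 - s2)

        rng = np.random.default_rng(seed)
        count_m = 0
        count_s = 0
        count_edges = np.zeros(len(iu[0]), dtype=np.int64)
        for _ in range(n_perm):
            perm = rng.permutation(n1 + n2)
            g1, g2 = estimate_pair(perm[:n1], perm[n1:])
            diff = np.abs(g1.weights - g2.weights)[iu]
            if diff.max() >= obs_m:
                count_m += 1
            if abs(global_strength(g1) - global_strength(g2)) >= obs_s:
                count_s += 1
            count_edges += diff >= obs_diff

    p_structure = (1 + count_m) / (1 + n_perm)
    p_strength = (1 + count_s) / (1 + n_perm)
    p_edges = (1 + count_edges) / (1 + n_perm)
    edge_table = pd.DataFrame(
        {
            "item_a": [codes[i] for i in iu[0]],
            "item_b": [codes[j] for j in iu[1]],
            "observed_diff": obs_diff,
            "p_uncorrected": p_edges,
            "p_holm": holm_adjust(p_edges),
        }
    )
    return NCTResult(
        item_codes=codes,
        m_statistic=obs_m,
        s_statistic=obs_s,
        p_structure=p_structure,
        p_strength=p_strength,
        edge_table=edge_table,
        global_strength_1=s1,
        global_strength_2=s2,
        n_perm=n_perm,
        seed=seed,
    )
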