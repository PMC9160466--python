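"""Contrast statistic and nonparametric bootstrap inference.

The primary quantity is the probe symptom's summed edge weight to the
revised-learned-helplessness items minus its summed edge weight to the
reduced-positive-affect items,

    sum_w_RLH = w(probe,SB) + w(probe,HL) + w(probe,GU)
    sum_w_RPA = w(probe,LS) + w(probe,LE) + w(probe,NI)
    delta     = sum_w_RLH - sum_w_RPA

with percentile bootstrap confidence limits: subjects are resampled with
replacement and the entire network estimation (penalty grid + EBIC
selection) is re-run on every resample.  Pairwise edge-difference tests
reuse the same bootstrap ensemble at a Bonferroni-corrected level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import BinaryMatrix, IsingNetwork
from .elasso import RegularizationConfig, estimate_network, estimate_network_from_patterns
from .errors import DegenerateNodeWarning, InvalidSpecError, MissingItemError

__all__ = [
    "ContrastSpec",
    "ContrastResult",
    "BootstrapConfig",
    "BootstrapEnsemble",
    "EdgeDifferenceResult",
    "PrimaryHypothesisResult",
    "default_contrast_spec",
    "contrast",
    "bootstrap_networks",
    "percentile_ci",
    "edge_difference_test",
    "run_primary_hypothesis",
]


@dataclass(frozen=True)
class ContrastSpec:
    """Probe symptom and the two symptom sets it is contrasted between."""

    probe: str = "WL"
    rlh_items: tuple[str, ...] = ("SB", "HL", "GU")
    rpa_items: tuple[str, ...] = ("LS", "LE", "NI")

    def __post_init__(self) -> None:
        rlh, rpa = set(self.rlh_items), set(self.rpa_items)
        if len(rlh) != len(self.rlh_items) or len(rpa) != len(self.rpa_items):
            raise InvalidSpecError("contrast item sets contain duplicates")
        if rlh & rpa:
            raise InvalidSpecError(
                f"contrast item sets must be disjoint; shared: {sorted(rlh & rpa)}"
            )
        if self.probe in rlh or self.probe in rpa:
            raise InvalidSpecError("probe item may not appear in either contrast set")

    @property
    def codes(self) -> list[str]:
        return [self.probe, *self.rlh_items, *self.rpa_items]


def default_contrast_spec() -> ContrastSpec:
    return ContrastSpec()


@dataclass
class ContrastResult:
    """Observed contrast quantities with percentile bootstrap CIs."""

    sum_rlh: float
    sum_rpa: float
    delta: float
    ci_sum_rlh: tuple[float, float] | None = None
    ci_sum_rpa: tuple[float, float] | None = None
    ci_delta: tuple[float, float] | None = None

    @property
    def significant(self) -> bool | None:
        """Whether the delta CI excludes zero."""
        if self.ci_delta is None:
            return None
        lo, hi = self.ci_delta
        return bool(lo > 0.0 or hi < 0.0)


@dataclass(frozen=True)
class BootstrapConfig:
    """Resample count, CI width, pairwise alpha and master seed.

    The default pairwise alpha of 0.05/18 Bonferroni-corrects the nine
    edge-pair comparisons across two study samples (9 x 2 = 18 tests).
    """

    n_boot: int = 10_000
    ci_width: float = 0.975
    alpha_pairwise: float = 0.05 / 18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_boot < 1:
            raise InvalidSpecError("n_boot must be >= 1")
        if not 0.0 < self.ci_width < 1.0:
            raise InvalidSpecError("ci_width must lie in (0, 1)")
        if not 0.0 < self.alpha_pairwise < 1.0:
            raise InvalidSpecError("alpha_pairwise must lie in (0, 1)")


@dataclass
class BootstrapEnsemble:
    """Stack of networks re-estimated on case resamples of one dataset.

    ``weights`` has shape ``(n_boot, p, p)``.  ``constant_item_events``
    counts (resample, item) pairs where the resample left an item constant;
    such nodes are isolated in that resample rather than redrawn.
    """

    item_codes: list[str]
    weights: np.ndarray
    thresholds: np.ndarray
    seed: int
    distinct_fractions: np.ndarray
    constant_item_events: int = 0

    def __len__(self) -> int:
        return self.weights.shape[0]

    def __getitem__(self, b: int) -> IsingNetwork:
        return IsingNetwork(self.item_codes, self.weights[b], self.thresholds[b])

    def edge_values(self, code_a: str, code_b: str) -> np.ndarray:
        """Bootstrap distribution of one edge weight."""
        i = self._index(code_a)
        j = self._index(code_b)
        return self.weights[:, i, j]

    def _index(self, code: str) -> int:
        try:
            return self.item_codes.index(code)
        except ValueError:
            raise MissingItemError(f"item {code!r} not in ensemble") from None


def contrast(network: IsingNetwork, spec: ContrastSpec) -> tuple[float, float, float]:
    """Evaluate ``(sum_w_RLH, sum_w_RPA, delta)`` on a network.

    Works on any network object exposing ``edge(code_a, code_b)``
    (Ising edge weights or GGM partial correlations).
    """
    sum_rlh = sum(network.edge(spec.probe, c) for c in spec.rlh_items)
    sum_rpa = sum(network.edge(spec.probe, c) for c in spec.rpa_items)
    return sum_rlh, sum_rpa, sum_rlh - sum_rpa


def _resample_counts(n: int, rng: np.random.Generator) -> np.ndarray:
    """Per-subject multiplicities of one case resample of size n.

    Drawing counts ~ Multinomial(n, 1/n each) is exactly drawing n subject
    indices with replacement, aggregated.
    """
    return rng.multinomial(n, np.full(n, 1.0 / n))


def bootstrap_networks(
    binary: BinaryMatrix,
    reg: RegularizationConfig | None = None,
    boot: BootstrapConfig | None = None,
) -> BootstrapEnsemble:
    """Re-estimate the network on ``n_boot`` case resamples.

    Each resample draws ``n`` subjects with replacement and repeats the
    full estimation (per-node penalty grid + EBIC selection).  Per-resample
    random streams are spawned from the master seed, so enlarging
    ``n_boot`` never reshuffles earlier resamples.
    """
    reg = reg or RegularizationConfig()
    boot = boot or BootstrapConfig()
    n, p = binary.n_subjects, binary.n_items
    patterns, counts, inverse = _compress_with_inverse(binary.values)
    weights = np.empty((boot.n_boot, p, p))
    thresholds = np.empty((boot.n_boot, p))
    distinct = np.empty(boot.n_boot)
    events = 0
    streams = np.random.SeedSequence(boot.seed).spawn(boot.n_boot)
    codes = list(binary.item_codes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateNodeWarning)
        for b in range(boot.n_boot):
            rng = np.random.default_rng(streams[b])
            subject_counts = _resample_counts(n, rng)
            distinct[b] = np.count_nonzero(subject_counts) / n
            pat_counts = np.bincount(
                inverse, weights=subject_counts, minlength=patterns.shape[0]
            )
            ones = pat_counts @ patterns
            events += int(np.sum((ones == 0) | (ones == n)))
            net = estimate_network_from_patterns(patterns, pat_counts, codes, reg)
            weights[b] = net.weights
            thresholds[b] = net.thresholds
    return BootstrapEnsemble(
        item_codes=codes,
        weights=weights,
        thresholds=thresholds,
        seed=boot.seed,
        distinct_fractions=distinct,
        constant_item_events=events,
    )


def _compress_with_inverse(values: np.ndarray):
    n, p = values.shape
    codes = values.astype(np.uint64) @ (np.uint64(1) << np.arange(p, dtype=np.uint64))
    uniq, inverse, counts = np.unique(codes, return_inverse=True, return_counts=True)
    patterns = ((uniq[:, None] >> np.arange(p, dtype=np.uint64)) & 1).astype(np.float64)
    return np.ascontiguousarray(patterns), counts.astype(float), inverse


def percentile_ci(values: np.ndarray, ci_width: float = 0.975) -> tuple[float, float]:
    """Percentile bootstrap interval: empirical quantiles at the two tails.

    For ``ci_width`` 0.975 these are the 0.0125 and 0.9875 quantiles,
    computed with linear interpolation between order statistics.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InvalidSpecError("need at least 2 bootstrap values for a CI")
    if not 0.0 < ci_width < 1.0:
        raise InvalidSpecError("ci_width must lie in (0, 1)")
    alpha = 1.0 - ci_width
    lo, hi = np.quantile(values, [alpha / 2.0, 1.0 - alpha / 2.0], method="linear")
    return float(lo), float(hi)


@dataclass
class EdgeDifferenceResult:
    """Bootstrap test of the difference between two edge weights."""

    edge_a: tuple[str, str]
    edge_b: tuple[str, str]
    observed: float
    ci: tuple[float, float]
    alpha: float
    significant: bool


def edge_difference_test(
    ensemble: BootstrapEnsemble,
    observed_network: IsingNetwork,
    edge_a: tuple[str, str],
    edge_b: tuple[str, str],
    alpha: float = 0.05 / 18,
) -> EdgeDifferenceResult:
    """Percentile CI for ``w(edge_a) - w(edge_b)`` at level ``1 - alpha``.

    Significant when the interval excludes zero.  An edge compared with
    itself gives a degenerate (0, 0) interval and is never significant.
    """
    obs = observed_network.edge(*edge_a) - observed_network.edge(*edge_b)
    diffs = ensemble.edge_values(*edge_a) - ensemble.edge_values(*edge_b)
    if set(map(frozenset, [edge_a, edge_b])) == {frozenset(edge_a)}:
        lo = hi = 0.0
    else:
        lo, hi = percentile_ci(diffs, 1.0 - alpha)
    return EdgeDifferenceResult(
        edge_a=edge_a,
        edge_b=edge_b,
        observed=obs,
        ci=(lo, hi),
        alpha=alpha,
        significant=bool(lo > 0.0 or hi < 0.0),
    )


@dataclass
class PrimaryHypothesisResult:
    """Full inferential table for one dataset: 3 + 6 + 9 = 18 rows."""

    spec: ContrastSpec
    network: IsingNetwork
    contrast: ContrastResult
    component_edges: dict[str, tuple[float, tuple[float, float]]]
    pairwise: list[EdgeDifferenceResult]
    ensemble: BootstrapEnsemble = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        """Tabular report: quantity, description, observed, CI, significance."""
        rows = []
        c = self.contrast
        rows.append(("delta", "RLH - RPA", c.delta, *c.ci_delta,
                     c.ci_delta[0] > 0 or c.ci_delta[1] < 0))
        rows.append(("sum_rlh", "Edge Sum RLH", c.sum_rlh, *c.ci_sum_rlh,
                     c.ci_sum_rlh[0] > 0 or c.ci_sum_rlh[1] < 0))
        rows.append(("sum_rpa", "Edge Sum RPA", c.sum_rpa, *c.ci_sum_rpa,
                     c.ci_sum_rpa[0] > 0 or c.ci_sum_rpa[1] < 0))
        for code, (obs, (lo, hi)) in self.component_edges.items():
            group = "RLH" if code in self.spec.rlh_items else "RPA"
            rows.append((f"w_{self.spec.probe}-{code}", f"{group}: {code}",
                         obs, lo, hi, lo > 0 or hi < 0))
        for r in self.pairwise:
            name = f"w_{r.edge_a[0]}-{r.edge_a[1]} - w_{r.edge_b[0]}-{r.edge_b[1]}"
            rows.append((name, f"{r.edge_a[1]} vs {r.edge_b[1]}",
                         r.observed, r.ci[0], r.ci[1], r.significant))
        return pd.DataFrame(
            rows,
            columns=["quantity", "description", "observed", "ci_lower", "ci_upper",
                     "significant"],
        )


def run_primary_hypothesis(
    binary: BinaryMatrix,
    spec: ContrastSpec | None = None,
    reg: RegularizationConfig | None = None,
    boot: BootstrapConfig | None = None,
    ensemble: BootstrapEnsemble | None = None,
) -> PrimaryHypothesisResult:
    """Estimate the network, bootstrap it, and assemble the full contrast table.

    Produces the observed contrast quantities with percentile CIs at the
    configured width, CIs for the six component edges, and the nine
    pairwise edge-difference tests at the Bonferroni-corrected level.  A
    pre-computed ensemble may be passed to avoid re-bootstrapping.
    """
    spec = spec or ContrastSpec()
    reg = reg or RegularizationConfig()
    boot = boot or BootstrapConfig()
    missing = [c for c in spec.codes if c not in binary.item_codes]
    if missing:
        raise MissingItemError(f"contrast items absent from data: {missing}")

    network = estimate_network(binary, reg)
    if ensemble is None:
        ensemble = bootstrap_networks(binary, reg, boot)

    def boot_stats(weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        i = ensemble._index(spec.probe)
        rlh = sum(weights[:, i, ensemble._index(c)] for c in spec.rlh_items)
        rpa = sum(weights[:, i, ensemble._index(c)] for c in spec.rpa_items)
        return rlh, rpa

    rlh_b, rpa_b = boot_stats(ensemble.weights)
    sum_rlh, sum_rpa, delta = contrast(network, spec)
    result = ContrastResult(
        sum_rlh=sum_rlh,
        sum_rpa=sum_rpa,
        delta=delta,
        ci_sum_rlh=percentile_ci(rlh_b, boot.ci_width),
        ci_sum_rpa=percentile_ci(rpa_b, boot.ci_width),
        ci_delta=percentile_ci(rlh_b - rpa_b, boot.ci_width),
    )
    component = {}
    for code in (*spec.rlh_items, *spec.rpa_items):
        obs = network.edge(spec.probe, code)
        ci = percentile_ci(ensemble.edge_values(spec.probe, code), boot.ci_width)
        component[code] = (obs, ci)
    pairwise = [
        edge_difference_test(
            ensemble,
            network,
            (spec.probe, a),
            (spec.probe, b),
            alpha=boot.alpha_pairwise,
        )
        for a in spec.rlh_items
        for b in spec.rpa_items
    ]
    return PrimaryHypothesisResult(
        spec=spec,
        network=network,
        contrast=result,
        component_edges=component,
        pairwise=pairwise,
        ensemble=ensemble,
    )
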