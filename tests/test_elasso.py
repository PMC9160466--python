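"""Node-wise L1 logistic estimation, EBIC selection and edge combination."""

import numpy as np
import pytest

import symptomnet as sn
from symptomnet._solver import lambda_max
from symptomnet.elasso import (
    NodewiseFit,
    RegularizationConfig,
    combine_edges,
    ebic,
    estimate_network,
    fit_node_path,
    fit_nodewise,
    select_lambda,
)
from symptomnet.errors import InvalidSpecError

from conftest import CODES7, subnetwork
from oracles import l1_logistic_min_objective, penalized_objective


class TestEbic:
    def test_gamma_zero_reduces_to_bic(self):
        for ll, k, n, p in [(-50.0, 2, 100, 14), (-123.4, 7, 999, 10)]:
            assert ebic(ll, k, n, p, 0.0) == pytest.approx(-2 * ll + k * np.log(n))

    def test_null_model_ignores_gamma(self):
        assert ebic(-50.0, 0, 100, 14, 0.0) == ebic(-50.0, 0, 100, 14, 1.0) == 100.0

    def test_worked_value(self):
        # -2*(-50) + 2*ln(100) + 0.5*2*ln(13)
        expected = 100.0 + 2.0 * np.log(100.0) + 0.5 * 2.0 * np.log(13.0)
        assert ebic(-50.0, 2, 100, 14, 0.25) == pytest.approx(expected)
        assert expected == pytest.approx(111.7752, abs=1e-4)


class TestNodewiseFit:
    def test_penalty_at_lambda_max_gives_null_model(self, data7):
        j = 0
        B = data7.values.astype(float)
        lam_hi = lambda_max(np.delete(B, j, axis=1), B[:, j])
        coef, _, _ = fit_nodewise(data7, data7.item_codes[j], lam_hi * 1.0001)
        assert np.all(coef == 0.0)

    def test_objective_matches_independent_convex_solver(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            p = int(rng.integers(4, 7))
            W = np.triu(rng.normal(0, 0.8, (p, p)), 1)
            W = W + W.T
            net = sn.PlantedNetwork([f"I{i}" for i in range(p)], W,
                                    rng.uniform(-1, 0.5, p))
            data = sn.sample_ising(net, 200, seed=int(rng.integers(2**31)))
            lam = 0.05
            coef, b0, _ = fit_nodewise(data, "I0", lam, tol=1e-10)
            X = np.delete(data.values, 0, axis=1).astype(float)
            y = data.values[:, 0].astype(float)
            mine = penalized_objective(X, y, lam, b0, coef)
            reference = l1_logistic_min_objective(X, y, lam)
            assert mine == pytest.approx(reference, abs=1e-5)

    def test_independent_predictor_is_shrunk_to_zero(self):
        rng = np.random.default_rng(7)
        n = 5000
        x_noise = rng.integers(0, 2, n)
        x_signal = rng.integers(0, 2, n)
        logits = -1.0 + 1.5 * x_signal
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        data = sn.BinaryMatrix(np.column_stack([y, x_signal, x_noise]),
                               ["Y", "S", "N"])
        coef, _, _ = fit_nodewise(data, "Y", 0.05)
        assert coef[1] == 0.0  # noise column
        assert coef[0] > 0.5  # signal column

    def test_loglik_nonincreasing_and_support_shrinks_with_penalty(self, data7):
        fit = fit_node_path(data7, "WL")
        assert np.all(np.diff(fit.loglik) >= -1e-3)  # lambda decreases along path
        k = np.count_nonzero(fit.coefficients, axis=1)
        # support grows (within one-step tolerance) as the penalty relaxes
        assert np.all(np.diff(k) >= -1)


class TestSelectLambda:
    def _fit_with_ebic(self, values):
        L = len(values)
        return NodewiseFit(
            node="A", neighbor_codes=["B"], lambda_path=np.geomspace(1, 0.01, L),
            coefficients=np.zeros((L, 1)), intercepts=np.zeros(L),
            loglik=np.zeros(L), ebic=np.asarray(values, dtype=float), selected=0,
        )

    def test_unique_minimum(self):
        assert select_lambda(self._fit_with_ebic([5.0, 2.0, 3.0])) == 1

    def test_tie_breaks_to_larger_penalty(self):
        # path is descending, so the earlier index is the sparser model
        assert select_lambda(self._fit_with_ebic([4.0, 2.0, 2.0, 3.0])) == 1

    def test_null_data_selects_empty_model(self):
        """Independent coins: EBIC should pick the null model nearly always."""
        rng = np.random.default_rng(11)
        empty = 0
        reps = 40
        for _ in range(reps):
            values = (rng.random((1000, 5)) < 0.4).astype(int)
            data = sn.BinaryMatrix(values, list("ABCDE"))
            fit = fit_node_path(data, "A")
            empty += np.count_nonzero(fit.selected_coefficients) == 0
        assert empty >= 0.95 * reps


class TestCombineEdges:
    def _fit(self, node, neighbors, coefs):
        return NodewiseFit(
            node=node, neighbor_codes=neighbors, lambda_path=np.array([0.1]),
            coefficients=np.array([coefs], dtype=float), intercepts=np.zeros(1),
            loglik=np.zeros(1), ebic=np.zeros(1), selected=0,
        )

    def test_and_rule_gates_on_both_directions(self):
        fits = {"A": self._fit("A", ["B"], [0.4]), "B": self._fit("B", ["A"], [0.0])}
        assert combine_edges(fits, "AND").edge("A", "B") == 0.0
        assert combine_edges(fits, "OR").edge("A", "B") == pytest.approx(0.4)

    def test_and_rule_averages(self):
        fits = {"A": self._fit("A", ["B"], [0.4]), "B": self._fit("B", ["A"], [0.6])}
        assert combine_edges(fits, "AND").edge("A", "B") == pytest.approx(0.5)

    def test_all_empty_fits_give_empty_network(self):
        fits = {
            "A": self._fit("A", ["B", "C"], [0.0, 0.0]),
            "B": self._fit("B", ["A", "C"], [0.0, 0.0]),
            "C": self._fit("C", ["A", "B"], [0.0, 0.0]),
        }
        assert combine_edges(fits).density == 0.0


class TestEstimateNetwork:
    def test_null_data_yields_sparse_network(self):
        rng = np.random.default_rng(13)
        reps, ok = 20, 0
        for _ in range(reps):
            values = (rng.random((2000, 14)) < 0.3).astype(int)
            data = sn.BinaryMatrix(values, [f"I{i}" for i in range(14)])
            ok += estimate_network(data).density <= 0.05
        assert ok >= 0.95 * reps

    def test_recovers_planted_structure_at_large_n(
        self, paper_like_network, estimated_20k
    ):
        iu = np.triu_indices(14, k=1)
        true_w = paper_like_network.weights[iu]
        est_w = estimated_20k.weights[iu]
        strong = np.abs(true_w) >= 0.5
        assert np.all(est_w[strong] != 0.0)
        assert np.all(np.sign(est_w[strong]) == np.sign(true_w[strong]))
        either = (true_w != 0) | (est_w != 0)
        corr = np.corrcoef(true_w[either], est_w[either])[0, 1]
        assert corr >= 0.9

    def test_density_grows_with_sample_size(self, paper_like_network, estimated_20k):
        """Small samples need more regularization, hence fewer surviving edges;
        checked as a majority property over replicates."""
        dense = estimated_20k.density
        wins = 0
        reps = 20
        for s in range(reps):
            small = sn.sample_ising(paper_like_network, 300, seed=200 + s)
            wins += estimate_network(small).density <= dense
        assert wins > reps / 2

    def test_estimate_is_symmetric_zero_diagonal(self, estimated_20k):
        W = estimated_20k.weights
        assert np.allclose(W, W.T)
        assert np.all(np.diag(W) == 0.0)

    def test_tiny_sample_does_not_crash(self):
        rng = np.random.default_rng(17)
        data = sn.BinaryMatrix((rng.random((40, 6)) < 0.5).astype(int),
                               list("ABCDEF"))
        net = estimate_network(data)
        assert 0.0 <= net.density <= 1.0

    def test_constant_item_is_isolated_with_warning(self):
        rng = np.random.default_rng(19)
        values = (rng.random((500, 4)) < 0.5).astype(int)
        values[:, 2] = 0  # never endorsed
        data = sn.BinaryMatrix(values, list("ABCD"))
        from symptomnet.errors import DegenerateNodeWarning

        with pytest.warns(DegenerateNodeWarning):
            net = estimate_network(data)
        assert np.all(net.weights[2] == 0.0)
        assert np.all(net.weights[:, 2] == 0.0)

    def test_single_item_rejected(self):
        data = sn.BinaryMatrix(np.array([[0], [1]]), ["A"])
        with pytest.raises(InvalidSpecError):
            estimate_network(data)

    def test_deterministic_given_data(self, data7):
        a = estimate_network(data7)
        b = estimate_network(data7)
        assert np.array_equal(a.weights, b.weights)

    def test_linear_spacing_option_runs(self, data7):
        net = estimate_network(data7, RegularizationConfig(spacing="linear"))
        assert net.n_items == 7


class TestRegularizationConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_lambda": 1},
            {"gamma": 1.5},
            {"lambda_min_ratio": 0.0},
            {"combine_rule": "XOR"},
            {"spacing": "cubic"},
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(InvalidSpecError):
            RegularizationConfig(**kwargs)
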