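"""Ising enumeration/sampling and latent-Gaussian ordinal generation."""

import numpy as np
import pytest

import symptomnet as sn
from symptomnet.errors import (
    EnumerationRefusedError,
    InvalidNetworkError,
    InvalidSpecError,
)
from symptomnet.synthetic import GibbsConfig, enumerate_states

from conftest import CODES7, subnetwork


def two_node_net(w: float) -> sn.PlantedNetwork:
    return sn.PlantedNetwork(["A", "B"], [[0.0, w], [w, 0.0]], [0.0, 0.0])


class TestEnumeration:
    def test_single_free_node_is_a_fair_coin(self):
        net = sn.PlantedNetwork(["A"], [[0.0]], [0.0])
        _, probs = sn.enumerate_ising_distribution(net)
        assert probs == pytest.approx([0.5, 0.5])

    def test_two_nodes_log2_coupling(self):
        # unnormalized masses exp(0), exp(0), exp(0), exp(ln 2) = 1,1,1,2
        _, probs = sn.enumerate_ising_distribution(two_node_net(np.log(2.0)))
        assert probs == pytest.approx([0.2, 0.2, 0.2, 0.4])

    def test_zero_coupling_factorizes(self):
        _, probs = sn.enumerate_ising_distribution(two_node_net(0.0))
        assert probs == pytest.approx([0.25] * 4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_probabilities_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        p = int(rng.integers(2, 8))
        W = rng.normal(0, 1, (p, p))
        W = np.triu(W, 1)
        W = W + W.T
        net = sn.PlantedNetwork([f"I{i}" for i in range(p)], W, rng.normal(0, 1, p))
        _, probs = sn.enumerate_ising_distribution(net)
        assert probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert (probs > 0).all()

    def test_large_p_refused(self):
        p = 17
        net = sn.PlantedNetwork([f"I{i}" for i in range(p)], np.zeros((p, p)),
                                np.zeros(p))
        with pytest.raises(EnumerationRefusedError):
            sn.enumerate_ising_distribution(net)

    def test_asymmetric_weights_rejected(self):
        with pytest.raises(InvalidNetworkError):
            sn.PlantedNetwork(["A", "B"], [[0.0, 1.0], [0.5, 0.0]], [0.0, 0.0])


class TestIsingSampler:
    def test_fair_coin_marginals(self):
        p, n = 4, 10_000
        net = sn.PlantedNetwork([f"I{i}" for i in range(p)], np.zeros((p, p)),
                                np.zeros(p))
        data = sn.sample_ising(net, n, seed=1)
        se = np.sqrt(0.25 / n)
        assert np.all(np.abs(data.values.mean(axis=0) - 0.5) < 3 * se)

    def test_saturated_thresholds_give_all_zeros(self):
        # P(endorse) = logistic(-14) ~ 8e-7 per cell: all-zero with
        # overwhelming probability (and deterministically for this seed)
        p = 5
        net = sn.PlantedNetwork([f"I{i}" for i in range(p)], np.zeros((p, p)),
                                np.full(p, -14.0))
        data = sn.sample_ising(net, 2000, seed=2)
        assert data.values.sum() == 0

    def test_exact_sampler_matches_enumeration(self):
        net = two_node_net(np.log(2.0))
        n = 50_000
        data = sn.sample_ising(net, n, seed=3)
        states = data.values @ np.array([2, 1])  # (00,01,10,11) -> 0..3
        freqs = np.bincount(states, minlength=4) / n
        expected = np.array([0.2, 0.2, 0.2, 0.4])
        se = np.sqrt(expected * (1 - expected) / n)
        assert np.all(np.abs(freqs - expected) < 3 * se)

    def test_gibbs_matches_enumeration(self, network7):
        """The Gibbs path (forced on an enumerable case) reproduces the exact
        marginals and pairwise joint frequencies."""
        n = 100_000
        states, probs = sn.enumerate_ising_distribution(network7)
        true_marg = probs @ states
        true_pair = states.T @ (probs[:, None] * states)
        data = sn.sample_ising(
            network7, n, seed=4, method="gibbs", gibbs=GibbsConfig(burn_in=300)
        )
        emp_marg = data.values.mean(axis=0)
        se = np.sqrt(true_marg * (1 - true_marg) / n)
        assert np.all(np.abs(emp_marg - true_marg) < 4 * se)
        V = data.values.astype(float)
        emp_pair = V.T @ V / n
        iu = np.triu_indices(7, k=1)
        se_pair = np.sqrt(true_pair[iu] * (1 - true_pair[iu]) / n)
        assert np.all(np.abs(emp_pair[iu] - true_pair[iu]) < 4 * se_pair)

    @pytest.mark.parametrize("method", ["exact", "gibbs"])
    def test_reproducible_given_seed(self, network7, method):
        kwargs = {"gibbs": GibbsConfig(burn_in=20)} if method == "gibbs" else {}
        a = sn.sample_ising(network7, 200, seed=9, method=method, **kwargs)
        b = sn.sample_ising(network7, 200, seed=9, method=method, **kwargs)
        assert np.array_equal(a.values, b.values)

    def test_n_must_be_positive(self, network7):
        with pytest.raises(InvalidSpecError):
            sn.sample_ising(network7, 0, seed=1)


class TestLikertSampler:
    def test_independent_items_match_normal_cell_masses(self):
        from scipy.stats import norm

        cuts = np.array([-1.5, -0.5, 0.5, 1.5])
        spec = sn.LatentGaussianSpec(["A", "B"], np.eye(2),
                                     np.tile(cuts, (2, 1)))
        n = 50_000
        lik = sn.sample_likert(spec, n, seed=5)
        edges = np.concatenate([[-np.inf], cuts, [np.inf]])
        expected = np.diff(norm.cdf(edges))
        for j in range(2):
            freqs = np.bincount(lik.values[:, j], minlength=6)[1:] / n
            se = np.sqrt(expected * (1 - expected) / n)
            assert np.all(np.abs(freqs - expected) < 3 * se)

    def test_unreachable_cutpoints_floor_all_responses(self):
        spec = sn.LatentGaussianSpec(["A"], np.eye(1), [[6.0, 7.0, 8.0, 9.0]])
        lik = sn.sample_likert(spec, 500, seed=6)
        assert (lik.values == 1).all()

    def test_reproducible_given_seed(self, ordinal_spec):
        a = sn.sample_likert(ordinal_spec, 100, seed=7)
        b = sn.sample_likert(ordinal_spec, 100, seed=7)
        assert np.array_equal(a.values, b.values)

    def test_indefinite_correlation_rejected(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(InvalidSpecError):
            sn.LatentGaussianSpec(["A", "B", "C"], bad,
                                  np.tile([-1.0, 0.0, 1.0, 2.0], (3, 1)))


class TestPaperLikeFixture:
    def test_hub_edge_ordering(self, paper_like_network):
        net = paper_like_network
        assert net.edge("WL", "HL") > net.edge("WL", "GU")
        assert net.edge("WL", "HL") > net.edge("WL", "SB") > 0

    def test_planted_contrast_direction(self, paper_like_network):
        from symptomnet.inference import ContrastSpec, contrast

        sum_rlh, sum_rpa, delta = contrast(paper_like_network, ContrastSpec())
        assert sum_rlh > sum_rpa
        assert delta > 1.5

    def test_weight_matrix_invariants(self, paper_like_network):
        W = paper_like_network.weights
        assert np.allclose(W, W.T)
        assert np.all(np.diag(W) == 0.0)
        assert len(paper_like_network.item_codes) == 14

    def test_endorsement_frequencies_span_realistic_range(self, paper_like_network):
        states, probs = sn.enumerate_ising_distribution(paper_like_network)
        marginals = probs @ states
        assert marginals.min() > 0.03
        assert marginals.max() < 0.6

    def test_json_roundtrip(self, paper_like_network, tmp_path):
        path = tmp_path / "net.json"
        paper_like_network.to_json(path)
        back = sn.IsingNetwork.from_json(path)
        assert back.item_codes == paper_like_network.item_codes
        assert np.allclose(back.weights, paper_like_network.weights)
        assert np.allclose(back.thresholds, paper_like_network.thresholds)


def test_enumerate_states_orders_first_item_as_high_bit():
    states = enumerate_states(2)
    assert states.tolist() == [[0, 0], [0, 1], [1, 0], [1, 1]]
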