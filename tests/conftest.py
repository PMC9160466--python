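"""Shared fixtures: planted networks and sampled datasets, reused across
modules so the expensive draws and fits happen once per session."""

import numpy as np
import pytest

import symptomnet as sn
from symptomnet.elasso import estimate_network


def subnetwork(net: sn.IsingNetwork, codes: list[str]) -> sn.IsingNetwork:
    """Restrict a planted network to a subset of items (used to build small,
    enumerable test cases that keep the planted contrast structure)."""
    idx = [net.item_codes.index(c) for c in codes]
    return sn.IsingNetwork(codes, net.weights[np.ix_(idx, idx)], net.thresholds[idx])


CODES7 = ["WL", "HL", "SB", "GU", "LS", "LE", "NI"]


@pytest.fixture(scope="session")
def paper_like_network() -> sn.IsingNetwork:
    return sn.make_paper_like_network()


@pytest.fixture(scope="session")
def network7(paper_like_network) -> sn.IsingNetwork:
    """Seven-item planted network: probe + both contrast clusters."""
    return subnetwork(paper_like_network, CODES7)


@pytest.fixture(scope="session")
def data7(network7) -> sn.BinaryMatrix:
    return sn.sample_ising(network7, 2000, seed=71)


@pytest.fixture(scope="session")
def fixture_data_20k(paper_like_network) -> sn.BinaryMatrix:
    return sn.sample_ising(paper_like_network, 20_000, seed=101)


@pytest.fixture(scope="session")
def estimated_20k(fixture_data_20k) -> sn.IsingNetwork:
    return estimate_network(fixture_data_20k)


@pytest.fixture(scope="session")
def ordinal_spec() -> sn.LatentGaussianSpec:
    return sn.make_paper_like_latent_spec()
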