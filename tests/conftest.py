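import numpy as np
import pytest

from netprop_sig.netio import GeneNetwork
from netprop_sig.synth import make_pathway_collection, make_sbm_network, make_signature


@pytest.fixture
def two_node():
    return GeneNetwork.from_edges([("A", "B")])


@pytest.fixture
def triangle():
    return GeneNetwork.from_edges([("A", "B"), ("B", "C"), ("A", "C")])


@pytest.fixture
def std_scenario():
    """Factory for the standard planted-module fixture: SBM 500 genes /
    5 modules, p_in 0.2, p_out 0.01, 60% of the phenotype module observed,
    20 background noise genes."""

    def _make(seed: int):
        network, truth = make_sbm_network(500, 5, 0.2, 0.01, seed=seed)
        signature, truth = make_signature(
            truth, network, observe_frac=0.6, n_background=20, seed=seed + 1
        )
        collection = make_pathway_collection(truth, n_random=20, seed=seed + 2)
        return {
            "network": network,
            "truth": truth,
            "signature": signature,
            "collection": collection,
        }

    return _make


def random_gnp_network(rng: np.random.Generator, max_nodes: int = 60) -> GeneNetwork:
    """Seeded Erdos-Renyi gene network for property tests (may be disconnected)."""
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.02, 0.4))
    names = [f"N{i:04d}" for i in range(n)]
    upper = rng.random((n, n)) < p
    edges = [(names[i], names[j]) for i in range(n) for j in range(i + 1, n) if upper[i, j]]
    return GeneNetwork.from_edges(edges, isolated=names)
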