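import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netprop_sig.diffuse import (
    DiffusionKernel,
    LaplacianMatrix,
    diffuse,
    heat_kernel,
    laplacian,
    scale_scores,
    top_n,
)
from netprop_sig.errors import OrderMismatchError
from netprop_sig.netio import GeneNetwork
from netprop_sig.sig import RelevanceVector

from conftest import random_gnp_network


def taylor_expm(m: np.ndarray, terms: int = 60) -> np.ndarray:
    """Independent truncated-Taylor-series oracle for exp(m) on tiny matrices."""
    out = np.eye(m.shape[0])
    term = np.eye(m.shape[0])
    for k in range(1, terms):
        term = term @ m / k
        out = out + term
    return out


def seed_vector(network: GeneNetwork, weights: dict) -> RelevanceVector:
    scores = np.array([weights.get(n, 0.0) for n in network.nodes])
    return RelevanceVector(scores, network.nodes, len(weights), ())


def test_laplacian_of_single_edge(two_node):
    lap = laplacian(two_node)
    assert np.array_equal(lap.matrix, [[1, -1], [-1, 1]])


def test_laplacian_of_triangle(triangle):
    lap = laplacian(triangle)
    assert np.array_equal(np.diag(lap.matrix), [2, 2, 2])
    off = lap.matrix[~np.eye(3, dtype=bool)]
    assert np.all(off == -1)
    assert np.allclose(lap.matrix.sum(axis=1), 0)


def test_laplacian_isolated_node_row_is_zero():
    net = GeneNetwork.from_edges([("A", "B")], isolated=["Z"])
    lap = laplacian(net)
    z = lap.nodes.index("Z")
    assert np.all(lap.matrix[z] == 0) and np.all(lap.matrix[:, z] == 0)


def test_alpha_zero_gives_exact_identity(triangle):
    w = heat_kernel(laplacian(triangle), alpha=0.0).matrix
    assert np.array_equal(w, np.eye(3))


def test_asymmetric_laplacian_is_rejected():
    bad = LaplacianMatrix(np.array([[1.0, -1.0], [0.0, 1.0]]), ("A", "B"))
    with pytest.raises(ValueError, match="undirected"):
        heat_kernel(bad)


def test_negative_alpha_is_rejected(two_node):
    with pytest.raises(ValueError):
        heat_kernel(laplacian(two_node), alpha=-1)


def test_kernel_matches_taylor_series_oracle(two_node, triangle):
    for net, alpha in [(two_node, 0.1), (triangle, 0.7)]:
        lap = laplacian(net)
        w = heat_kernel(lap, alpha).matrix
        assert np.allclose(w, taylor_expm(-alpha * lap.matrix), atol=1e-12)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), alpha=st.floats(0.01, 2.0))
def test_kernel_is_doubly_stochastic_on_random_graphs(seed, alpha):
    """W = exp(-alpha L) is symmetric, nonnegative, with unit row sums, for
    arbitrary (possibly disconnected) undirected graphs."""
    net = random_gnp_network(np.random.default_rng(seed), max_nodes=60)
    w = heat_kernel(laplacian(net), alpha).matrix
    assert np.allclose(w, w.T, atol=1e-10)
    assert w.min() >= -1e-10 and w.max() <= 1 + 1e-10
    assert np.allclose(w.sum(axis=1), 1.0, atol=1e-10)


def test_no_leakage_between_components():
    net = GeneNetwork.from_edges([("A", "B"), ("C", "D"), ("D", "E")], isolated=["Z"])
    w = heat_kernel(laplacian(net), alpha=0.5)
    res = diffuse(w, seed_vector(net, {"A": 1.0, "B": 2.0}))
    scores = dict(zip(res.frame["gene"], res.frame["score"]))
    # support on {A,B} stays exactly on that component
    assert scores["C"] == 0.0 and scores["D"] == 0.0 and scores["E"] == 0.0
    assert scores["Z"] == 0.0
    assert scores["A"] + scores["B"] == pytest.approx(3.0, abs=1e-12)


def test_diffusion_of_zero_vector_is_zero(triangle):
    w = heat_kernel(laplacian(triangle))
    res = diffuse(w, seed_vector(triangle, {}))
    assert np.array_equal(res.frame["score"], np.zeros(3))


def test_two_node_closed_form_diffusion(two_node):
    w = heat_kernel(laplacian(two_node), alpha=0.1)
    res = diffuse(w, seed_vector(two_node, {"A": 1.0}))
    expected = {"A": (1 + math.exp(-0.2)) / 2, "B": (1 - math.exp(-0.2)) / 2}
    scores = dict(zip(res.frame["gene"], res.frame["score"]))
    for g, v in expected.items():
        assert scores[g] == pytest.approx(v, abs=1e-12)


def test_mass_conservation_on_random_graph():
    net = random_gnp_network(np.random.default_rng(99), max_nodes=50)
    rng = np.random.default_rng(1)
    s = RelevanceVector(rng.lognormal(size=net.n_nodes), net.nodes, net.n_nodes, ())
    res = diffuse(heat_kernel(laplacian(net), 0.1), s)
    assert res.frame["score"].sum() == pytest.approx(s.scores.sum(), abs=1e-8)
    assert (res.frame["score"] >= 0).all()  # nonnegative seed -> nonnegative P
    assert sorted(res.frame["rank"]) == list(range(1, net.n_nodes + 1))


def test_rank_ties_break_lexicographically(two_node):
    w = DiffusionKernel(np.eye(2), 0.0, two_node.nodes)
    res = diffuse(w, seed_vector(two_node, {"A": 1.0, "B": 1.0}))
    tab = res.frame.set_index("gene")
    assert tab.loc["A", "rank"] == 1 and tab.loc["B", "rank"] == 2


def test_node_order_mismatch_is_hard_error(two_node):
    w = heat_kernel(laplacian(two_node))
    wrong = RelevanceVector(np.array([1.0, 0.0]), ("B", "A"), 1, ())
    with pytest.raises(OrderMismatchError):
        diffuse(w, wrong)


def test_scaling_standardises_and_preserves_ranks():
    net = random_gnp_network(np.random.default_rng(7), max_nodes=40)
    s = RelevanceVector(
        np.random.default_rng(2).lognormal(size=net.n_nodes), net.nodes, net.n_nodes, ()
    )
    res = diffuse(heat_kernel(laplacian(net), 0.1), s)
    scaled = scale_scores(res)
    z = scaled.frame["scaled_score"].to_numpy()
    assert z.mean() == pytest.approx(0, abs=1e-10)
    assert z.std(ddof=0) == pytest.approx(1, abs=1e-10)
    assert scaled.frame["rank"].equals(res.frame["rank"])
    mm = scale_scores(res, method="minmax").frame["scaled_score"]
    assert mm.min() == 0 and mm.max() == 1


def test_scaling_constant_scores_warn_to_zero(triangle, caplog):
    res = diffuse(heat_kernel(laplacian(triangle)), seed_vector(triangle, {}))
    with caplog.at_level("WARNING"):
        scaled = scale_scores(res)
    assert (scaled.frame["scaled_score"] == 0).all()
    assert "zero variance" in caplog.text


def test_top_n_bounds_and_ordering(triangle):
    res = diffuse(heat_kernel(laplacian(triangle)), seed_vector(triangle, {"B": 2.0}))
    full = top_n(res, 3)
    assert list(full["rank"]) == [1, 2, 3]
    assert full.iloc[0]["gene"] == "B"
    assert bool(full.iloc[0]["in_signature"])
    with pytest.raises(ValueError):
        top_n(res, 4)
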