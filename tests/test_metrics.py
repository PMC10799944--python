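import numpy as np
import pytest
from hypothesis import given, strategies as st

import bruteforce as bf
from covnet import (
    MetricCurve,
    auc_over_densities,
    betweenness,
    build_ensemble,
    characteristic_path_length,
    clustering_coefficient,
    degree,
    density_grid,
    ensemble_metric_curves,
    global_efficiency,
    local_efficiency,
    nodal_efficiency,
    normalized_global_metrics,
    random_reference,
)
from covnet.build import AssociationMatrix


def complete_graph(n):
    return (1 - np.eye(n)).astype(np.uint8)


def star_graph(n):
    adj = np.zeros((n, n), np.uint8)
    adj[0, 1:] = adj[1:, 0] = 1
    return adj


def ring_lattice(n, k):
    adj = np.zeros((n, n), np.uint8)
    for i in range(n):
        for off in range(1, k // 2 + 1):
            j = (i + off) % n
            adj[i, j] = adj[j, i] = 1
    return adj


def path_graph(n):
    adj = np.zeros((n, n), np.uint8)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1
    return adj


def cycle_graph(n):
    adj = path_graph(n)
    adj[0, n - 1] = adj[n - 1, 0] = 1
    return adj


# ------------------------------------------------------- analytic values


def test_complete_graph_metrics_are_exact():
    k5 = complete_graph(5)
    nodes, mean = clustering_coefficient(k5)
    assert np.all(nodes == 1.0) and mean == 1.0
    assert characteristic_path_length(k5) == 1.0
    assert global_efficiency(k5) == 1.0
    eloc, eloc_mean = local_efficiency(k5)
    assert np.all(eloc == 1.0) and eloc_mean == 1.0
    assert np.all(betweenness(k5) == 0.0)


def test_star_graph_metrics_are_exact():
    s5 = star_graph(5)
    nodes, _ = clustering_coefficient(s5)
    assert np.all(nodes == 0.0)  # no triangles anywhere
    eloc, _ = local_efficiency(s5)
    assert np.all(eloc == 0.0)
    b = betweenness(s5)
    assert b[0] == 6.0  # (n-1)(n-2)/2 through the hub
    assert np.all(b[1:] == 0.0)


def test_ring_lattice_clustering_is_one_half():
    nodes, mean = clustering_coefficient(ring_lattice(20, 4))
    assert np.allclose(nodes, 0.5)
    assert mean == pytest.approx(0.5, abs=1e-15)


def test_four_cycle_betweenness_is_half_per_node():
    assert np.allclose(betweenness(cycle_graph(4)), 0.5)


def test_path_graph_enumerated_distances():
    p3 = path_graph(3)
    assert characteristic_path_length(p3) == pytest.approx(4.0 / 3.0)
    assert global_efficiency(p3) == pytest.approx((1 + 1 + 0.5) / 3.0)
    assert betweenness(p3)[1] == 1.0


def test_disconnected_graph_uses_largest_component_with_warning():
    two_k3 = np.zeros((6, 6), np.uint8)
    two_k3[:3, :3] = complete_graph(3)
    two_k3[3:, 3:] = complete_graph(3)
    with pytest.warns(UserWarning, match="disconnected"):
        assert characteristic_path_length(two_k3) == 1.0
    eff = nodal_efficiency(two_k3)
    assert np.allclose(eff, 2.0 / 5.0)  # two neighbours of five possible


def test_isolated_node_has_zero_nodal_efficiency():
    adj = np.zeros((4, 4), np.uint8)
    adj[0, 1] = adj[1, 0] = 1
    eff = nodal_efficiency(adj)
    assert eff[2] == 0.0 and eff[3] == 0.0


def test_pendant_triangle_local_efficiency_matches_bruteforce():
    adj = np.zeros((4, 4), np.uint8)
    adj[0, 1] = adj[1, 0] = 1
    adj[0, 2] = adj[2, 0] = 1
    adj[1, 2] = adj[2, 1] = 1
    adj[2, 3] = adj[3, 2] = 1  # pendant on one triangle vertex
    eloc, _ = local_efficiency(adj)
    assert np.allclose(eloc, bf.local_efficiency(adj), atol=1e-15)


def test_empty_graph_path_length_is_fatal():
    with pytest.raises(ValueError, match="no edges"):
        characteristic_path_length(np.zeros((4, 4), np.uint8))


# ------------------------------------------------- cross-checks / oracles


def test_metrics_agree_with_networkx_on_random_graphs():
    nx = pytest.importorskip("networkx")
    rng = np.random.default_rng(0)
    for _ in range(10):
        n = int(rng.integers(5, 12))
        adj = bf.random_graph(rng, n, float(rng.uniform(0.2, 0.8)))
        g = nx.from_numpy_array(adj)
        nodes, _ = clustering_coefficient(adj)
        expected_c = np.array([nx.clustering(g, i) for i in range(n)])
        assert np.allclose(nodes, expected_c, atol=1e-12)
        expected_b = np.array(
            list(nx.betweenness_centrality(g, normalized=False).values())
        )
        assert np.allclose(betweenness(adj), expected_b, atol=1e-9)
        expected_eff = np.array(
            [
                sum(1.0 / d for t, d in nx.single_source_shortest_path_length(g, i).items() if t != i)
                / (n - 1)
                for i in range(n)
            ]
        )
        assert np.allclose(nodal_efficiency(adj), expected_eff, atol=1e-12)


@given(st.integers(4, 10), st.floats(0.2, 0.9))
def test_handshake_and_efficiency_path_inequality(n, p):
    rng = np.random.default_rng(n + int(p * 100))
    adj = bf.random_graph(rng, n, p)
    assert degree(adj).sum() == 2 * (adj.sum() // 2)
    if adj.sum() and np.isfinite(bf.distances(adj)).all():
        L = characteristic_path_length(adj)
        # Jensen: mean(1/d) >= 1/mean(d) on the connected graph
        assert global_efficiency(adj) >= 1.0 / L - 1e-12


def test_global_efficiency_monotone_on_nested_ensembles():
    rng = np.random.default_rng(7)
    v = rng.standard_normal((30, 30))
    v = np.tanh((v + v.T) / 2)
    np.fill_diagonal(v, 0)
    ens = build_ensemble(AssociationMatrix(values=v), densities=density_grid())
    eff = [global_efficiency(g) for g in ens]
    assert np.all(np.diff(eff) >= -1e-12)


# ------------------------------------------------------ random reference


def test_rewiring_preserves_degree_sequence_exactly():
    rng = np.random.default_rng(1)
    adj = bf.random_graph(rng, 40, 0.2)
    ref = random_reference(adj, n_swaps_per_edge=10, seed=3)
    assert np.array_equal(degree(ref.adjacency), degree(adj))
    assert ref.adjacency.sum() == adj.sum()
    assert np.all(np.diag(ref.adjacency) == 0)


def test_complete_graph_admits_no_swap_and_warns():
    k5 = complete_graph(5)
    with pytest.warns(UserWarning, match="no legal"):
        ref = random_reference(k5, seed=0)
    assert np.array_equal(ref.adjacency, k5)


def test_rewiring_is_seed_deterministic():
    rng = np.random.default_rng(2)
    adj = bf.random_graph(rng, 30, 0.3)
    a = random_reference(adj, seed=9).adjacency
    b = random_reference(adj, seed=9).adjacency
    c = random_reference(adj, seed=10).adjacency
    assert np.array_equal(a, b)
    assert not np.array_equal(a, c)


def test_rewiring_destroys_lattice_clustering():
    lattice = ring_lattice(50, 4)
    c0 = clustering_coefficient(lattice)[1]
    drops = sum(
        clustering_coefficient(random_reference(lattice, 10, seed=s).adjacency)[1] < c0
        for s in range(20)
    )
    assert drops >= 19


def test_normalized_metrics_random_graph_sigma_near_one():
    rng = np.random.default_rng(4)
    for seed in range(3):
        adj = bf.random_graph(rng, 68, 0.2)
        gm = normalized_global_metrics(adj, n_null=20, seed=seed)
        assert 0.8 < gm.sigma < 1.2
        assert abs(gm.sigma - 1.0) < 0.15


def test_normalized_metrics_lattice_is_small_world():
    gm = normalized_global_metrics(ring_lattice(68, 8), n_null=20, seed=0)
    assert gm.gamma > 2.0
    assert gm.sigma > 1.5


def test_normalized_metrics_deterministic_with_fixed_seed():
    rng = np.random.default_rng(5)
    adj = bf.random_graph(rng, 40, 0.25)
    a = normalized_global_metrics(adj, n_null=1, seed=7)
    b = normalized_global_metrics(adj, n_null=1, seed=7)
    assert a == b


# ------------------------------------------------------------------- AUC


def test_auc_of_constant_curve_is_rectangle():
    grid = density_grid()
    auc = auc_over_densities(MetricCurve("c", grid, np.ones(35)))
    assert auc.auc == pytest.approx(0.34, abs=1e-15)


def test_auc_of_identity_curve_is_closed_form():
    grid = density_grid()
    auc = auc_over_densities(MetricCurve("id", grid, grid.copy()))
    assert auc.auc == pytest.approx((0.40**2 - 0.06**2) / 2.0, abs=1e-12)


def test_auc_single_trapezoid():
    auc = auc_over_densities(
        MetricCurve("t", np.array([0.1, 0.2]), np.array([0.0, 2.0]))
    )
    assert auc.auc == pytest.approx(0.1, abs=1e-15)


def test_auc_validates_its_grid():
    with pytest.raises(ValueError, match="at least 2"):
        auc_over_densities(MetricCurve("x", np.array([0.1]), np.array([1.0])))
    with pytest.raises(ValueError, match="equal length"):
        MetricCurve("x", np.array([0.1, 0.2]), np.array([1.0]))
    with pytest.raises(ValueError, match="increasing"):
        auc_over_densities(
            MetricCurve("x", np.array([0.2, 0.1]), np.array([1.0, 1.0]))
        )


# ----------------------------------------------------- ensemble curves


def test_ensemble_curves_match_single_graph_metrics():
    rng = np.random.default_rng(8)
    v = rng.standard_normal((24, 24))
    v = np.tanh((v + v.T) / 2)
    np.fill_diagonal(v, 0)
    ens = build_ensemble(AssociationMatrix(values=v))
    curves = ensemble_metric_curves(ens, n_null=0, include_nodal=True)
    nodal = curves["nodal"]
    for t in (0, 17, 34):
        adj = ens.graph(t).adjacency
        assert curves["clustering"].values[t] == pytest.approx(
            clustering_coefficient(adj)[1], abs=1e-12
        )
        assert curves["global_efficiency"].values[t] == pytest.approx(
            global_efficiency(adj), abs=1e-12
        )
        assert curves["local_efficiency"].values[t] == pytest.approx(
            local_efficiency(adj)[1], abs=1e-12
        )
        assert np.allclose(nodal["degree"][t], degree(adj))
        assert np.allclose(nodal["betweenness"][t], betweenness(adj), atol=1e-9)
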