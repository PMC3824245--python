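"""Synapse-set statistics: nearest neighbors, proximity-graph clustering,
branch densities, radial histograms, density maps, and the KS test."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from conftest import make_chain_tree, random_tree
from oracles import brute_ks_statistic, brute_mean_clustering, brute_nn_distances

from synaptomap.morphology import branch_decomposition, positions_from_arclengths
from synaptomap.null_model import redistribute_uniform
from synaptomap.spatial_stats import (
    branch_density_table,
    clustering_curve,
    density_map_2d,
    fraction_with_neighbor_within,
    fraction_within_path_radius,
    ks_two_sample,
    mean_clustering_coefficient,
    nearest_neighbor_distances,
    proximity_graph,
    radial_path_histogram,
)
from synaptomap.synapses import SynapseSet


def cable_synapses(tree, arclengths):
    child_idx, offset = positions_from_arclengths(
        tree, np.asarray(arclengths, dtype=float), "basal"
    )
    return SynapseSet(tree, child_idx, offset)


# ---------------------------------------------------------------------------
# Nearest neighbors
# ---------------------------------------------------------------------------

def test_nn_on_straight_cable(chain_tree):
    syn = cable_synapses(chain_tree, [0, 3, 50])
    nn = nearest_neighbor_distances(chain_tree, syn)
    np.testing.assert_allclose(sorted(nn.distances), [3, 3, 47])


def test_nn_coincident_synapses_warn(chain_tree):
    syn = cable_synapses(chain_tree, [10.0, 10.0, 40.0])
    with pytest.warns(UserWarning, match="coincident"):
        nn = nearest_neighbor_distances(chain_tree, syn)
    assert nn.distances[0] == 0.0 and nn.distances[1] == 0.0


def test_nn_requires_two_synapses(chain_tree):
    with pytest.raises(ValueError):
        nearest_neighbor_distances(chain_tree, cable_synapses(chain_tree, [5.0]))


def test_nn_matches_brute_force_oracle():
    tree = random_tree(11)
    syn = redistribute_uniform(tree, "basal", 15, np.random.default_rng(2))
    nn = nearest_neighbor_distances(tree, syn)
    expected = brute_nn_distances(tree, syn)
    np.testing.assert_allclose(nn.distances, expected, atol=1e-9)


def test_fraction_within_neighbor(chain_tree):
    syn = cable_synapses(chain_tree, [0, 3, 50])
    assert fraction_with_neighbor_within(chain_tree, syn, 5.0) == pytest.approx(2 / 3)
    assert fraction_with_neighbor_within(chain_tree, syn, 1.0) == 0.0
    # consistency with the NN ECDF
    nn = nearest_neighbor_distances(chain_tree, syn)
    assert fraction_with_neighbor_within(chain_tree, syn, 5.0) == nn.ecdf(5.0)


def test_fraction_within_nondecreasing_in_d(ref_tree):
    syn = redistribute_uniform(ref_tree, "basal", 100, np.random.default_rng(5))
    vals = [fraction_with_neighbor_within(ref_tree, syn, d) for d in (1, 3, 5, 10, 30)]
    assert all(a <= b for a, b in zip(vals, vals[1:]))
    assert all(0 <= v <= 1 for v in vals)


# ---------------------------------------------------------------------------
# Proximity graph and clustering coefficient
# ---------------------------------------------------------------------------

def test_proximity_graph_triangle_and_empty(chain_tree):
    tri = proximity_graph(chain_tree, cable_synapses(chain_tree, [0, 2, 4]), 5.0)
    assert tri.sum() == 6 and not tri.diagonal().any()
    empty = proximity_graph(chain_tree, cable_synapses(chain_tree, [0, 30, 60]), 29.0)
    assert not empty.any()


def test_proximity_graph_symmetry_random(ref_tree, rng):
    syn = redistribute_uniform(ref_tree, "basal", 60, rng)
    A = proximity_graph(ref_tree, syn, 10.0)
    assert np.array_equal(A, A.T)
    assert not A.diagonal().any()


def test_clustering_triangle_and_path():
    tri = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=bool)
    assert mean_clustering_coefficient(tri) == 1.0
    path = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=bool)
    # middle node has coefficient 0; endpoints (degree 1) are excluded
    assert mean_clustering_coefficient(path) == 0.0


def test_clustering_undefined_marker():
    lone = np.zeros((3, 3), dtype=bool)
    assert np.isnan(mean_clustering_coefficient(lone))


def test_clustering_matches_triangle_enumeration(rng):
    for _ in range(10):
        n = 12
        A = rng.random((n, n)) < 0.3
        A = np.triu(A, 1)
        A = A | A.T
        got = mean_clustering_coefficient(A)
        expected = brute_mean_clustering(A)
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == pytest.approx(expected)


def test_clustering_curve_limits(chain_tree):
    syn = cable_synapses(chain_tree, [10, 20, 40, 80])
    curve = clustering_curve(chain_tree, syn, np.array([5.0, 100.0]))
    assert np.isnan(curve.mean_coefficient[0])  # below min pairwise distance
    assert curve.mean_coefficient[1] == 1.0  # complete graph at d >= diameter


# ---------------------------------------------------------------------------
# Branch densities
# ---------------------------------------------------------------------------

def test_branch_density_single_cable(chain_tree):
    branches = branch_decomposition(chain_tree, "basal")
    syn = cable_synapses(chain_tree, [5, 15, 25, 35, 45])
    table = branch_density_table(chain_tree, branches, syn)
    assert len(table) == 1
    assert table["density_per_um"].iloc[0] == pytest.approx(5 / 100)


def test_branch_density_empty_set(chain_tree):
    branches = branch_decomposition(chain_tree, "basal")
    empty = SynapseSet(chain_tree, np.empty(0, np.int64), np.empty(0))
    table = branch_density_table(chain_tree, branches, empty)
    assert table["synapse_count"].sum() == 0


def test_branch_density_conserves_counts(ref_tree, rng):
    branches = branch_decomposition(ref_tree, "basal")
    syn = redistribute_uniform(ref_tree, "basal", 328, rng)
    table = branch_density_table(ref_tree, branches, syn)
    assert table["synapse_count"].sum() == 328
    assert table.attrs["n_excluded"] == 0
    assert (table["density_per_um"] >= 0).all()


# ---------------------------------------------------------------------------
# Radial histogram and density maps
# ---------------------------------------------------------------------------

def test_radial_histogram_single_bin(chain_tree):
    syn = cable_synapses(chain_tree, [42.0, 42.0, 42.0])
    hist = radial_path_histogram(chain_tree, syn, 10.0)
    assert hist["count"].sum() == 3
    assert (hist["count"] > 0).sum() == 1
    assert hist["cumulative_fraction"].iloc[-1] == 1.0
    assert fraction_within_path_radius(chain_tree, syn, 1e9) == 1.0


def test_radial_histogram_conserves_counts(ref_tree, rng):
    syn = redistribute_uniform(ref_tree, "basal", 200, rng)
    hist = radial_path_histogram(ref_tree, syn, 25.0)
    assert hist["count"].sum() == 200
    assert np.all(np.diff(hist["cumulative_fraction"]) >= 0)


def test_density_map_central_bin(chain_tree):
    syn = cable_synapses(chain_tree, [0.25])  # essentially at the soma
    m = density_map_2d([(chain_tree, syn)], alignment="soma", bin_um=10, extent=50)
    occupied = np.argwhere(m.density > 0)
    assert len(occupied) == 1
    assert occupied[0][0] == 5  # the bin containing x=0 (edges at -50..50)


def test_density_map_translation_invariance_and_linearity():
    t1 = make_chain_tree()
    t2 = random_tree(3)
    s1 = cable_synapses(t1, [10, 20, 30])
    s2 = redistribute_uniform(t2, "basal", 30, np.random.default_rng(0))
    m1 = density_map_2d([(t1, s1)], bin_um=20, extent=200)
    m2 = density_map_2d([(t2, s2)], bin_um=20, extent=200)
    both = density_map_2d([(t1, s1), (t2, s2)], bin_um=20, extent=200)
    np.testing.assert_allclose(both.density, (m1.density + m2.density) / 2)


def test_density_map_pia_requires_coordinate(chain_tree):
    syn = cable_synapses(chain_tree, [10.0])
    with pytest.raises(ValueError, match="pia"):
        density_map_2d([(chain_tree, syn)], alignment="pia")
    m = density_map_2d([(chain_tree, syn)], alignment="pia", pia_y=[-100.0])
    assert m.density.sum() > 0


# ---------------------------------------------------------------------------
# KS test
# ---------------------------------------------------------------------------

def test_ks_identical_samples():
    x = np.arange(30.0)
    D, p = ks_two_sample(x, x.copy())
    assert D == 0.0 and p == 1.0


def test_ks_disjoint_supports():
    D, _ = ks_two_sample(np.arange(30.0), np.arange(100.0, 130.0))
    assert D == 1.0


def test_ks_rejects_empty():
    with pytest.raises(ValueError):
        ks_two_sample(np.array([]), np.arange(3.0))


@given(st.integers(0, 2**31 - 1))
def test_ks_statistic_matches_exhaustive_sweep(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=rng.integers(25, 60))
    y = rng.normal(loc=rng.random(), size=rng.integers(25, 60))
    D, p = ks_two_sample(x, y)
    assert D == pytest.approx(brute_ks_statistic(x, y), abs=1e-12)
    # cross-check against an independent implementation (asymptotic mode)
    ref = sps.ks_2samp(x, y, method="asymp")
    assert D == pytest.approx(ref.statistic, abs=1e-12)
    assert 0.0 <= p <= 1.0


def test_ks_small_sample_warns():
    with pytest.warns(UserWarning, match="n < 25"):
        ks_two_sample(np.arange(5.0), np.arange(40.0))
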