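"""Synthetic-data generators: arbors, synapse placements, neuropil volumes.
Each generator must be a pure function of (params, seed)."""

import numpy as np
import pytest

from synaptomap.morphology import branch_decomposition, write_swc
from synaptomap.null_model import redistribute_uniform
from synaptomap.spatial_stats import ks_two_sample, nearest_neighbor_distances
from synaptomap.synapses import SynapseSet
from synaptomap.synthetic_data import (
    ClusterPlacementParams,
    TreeGenParams,
    VolumeGenParams,
    generate_labeled_volume,
    generate_tree,
    place_branch_biased,
    place_clustered,
)


# ---------------------------------------------------------------------------
# Arbor generation
# ---------------------------------------------------------------------------

def test_no_bifurcation_gives_single_cable():
    params = TreeGenParams(
        total_length=300.0,
        branch_length_mean=1000.0,
        branch_length_sd=1.0,
        bifurcation_prob=0.0,
        basal_fraction=1.0,
        n_basal_stems=1,
        seed=0,
    )
    tree = generate_tree(params)
    assert len(branch_decomposition(tree, "basal")) == 1
    assert tree.total_length("basal") == pytest.approx(300.0, rel=0.02)


def test_same_seed_identical_swc_bytes(tmp_path):
    for k, out in enumerate(["a.swc", "b.swc"]):
        write_swc(generate_tree(TreeGenParams(seed=42)), tmp_path / out)
    assert (tmp_path / "a.swc").read_bytes() == (tmp_path / "b.swc").read_bytes()


def test_total_length_hits_target_across_seeds():
    target = 2000.0
    totals = [
        generate_tree(TreeGenParams(total_length=target, seed=s)).total_length(
            "dendrites"
        )
        for s in range(20)
    ]
    assert abs(np.mean(totals) - target) < 0.1 * target
    assert all(abs(t - target) < 0.1 * target for t in totals)


def test_zero_step_rejected():
    with pytest.raises(ValueError, match="step"):
        TreeGenParams(step=0.0)


def test_region_mix(ref_tree):
    total = ref_tree.total_length("dendrites")
    basal = ref_tree.total_length("basal")
    assert basal / total == pytest.approx(0.7, abs=0.02)


# ---------------------------------------------------------------------------
# Clustered placement
# ---------------------------------------------------------------------------

def test_clustered_degenerate_sigma_one_parent(ref_tree):
    """With a single parent and vanishing spread all synapses coincide."""
    params = ClusterPlacementParams(
        n=20, parent_intensity=1e-9, sigma=1e-9, seed=3
    )
    syn = place_clustered(ref_tree, "basal", params)
    assert len(syn) == 20
    assert len(np.unique(syn.child_idx)) == 1
    assert np.ptp(syn.offset) < 1e-6


def test_clustered_dense_parent_limit_is_uniform(ref_tree):
    """As the parent intensity grows, the cluster process converges to the
    uniform placement: the pooled NN distributions become KS-indistinguishable."""
    nn_clustered = []
    nn_uniform = []
    for s in range(6):
        dense = ClusterPlacementParams(n=300, parent_intensity=50.0, sigma=2.0, seed=s)
        nn_clustered.append(
            nearest_neighbor_distances(
                ref_tree, place_clustered(ref_tree, "basal", dense)
            ).distances
        )
        nn_uniform.append(
            nearest_neighbor_distances(
                ref_tree,
                redistribute_uniform(ref_tree, "basal", 300, np.random.default_rng(s)),
            ).distances
        )
    D, p = ks_two_sample(np.concatenate(nn_clustered), np.concatenate(nn_uniform))
    assert p > 0.01


def test_clustered_exact_count_and_determinism(ref_tree):
    params = ClusterPlacementParams(n=123, seed=9)
    a = place_clustered(ref_tree, "basal", params)
    b = place_clustered(ref_tree, "basal", params)
    assert len(a) == 123
    np.testing.assert_array_equal(a.offset, b.offset)


def test_clustered_detectable_excess_within_5um(ref_tree):
    """Sparse parents with 2 µm spread produce an excess of close neighbors
    relative to the matched uniform null in nearly every run."""
    null_frac = np.mean(
        [
            np.mean(
                nearest_neighbor_distances(
                    ref_tree,
                    redistribute_uniform(
                        ref_tree, "basal", 300, np.random.default_rng(1000 + r)
                    ),
                ).distances
                <= 5.0
            )
            for r in range(50)
        ]
    )
    wins = 0
    n_runs = 20
    for s in range(n_runs):
        syn = place_clustered(
            ref_tree,
            "basal",
            ClusterPlacementParams(n=300, parent_intensity=0.01, sigma=2.0, seed=s),
        )
        frac = np.mean(nearest_neighbor_distances(ref_tree, syn).distances <= 5.0)
        wins += frac > null_frac
    assert wins >= 0.95 * n_runs


# ---------------------------------------------------------------------------
# Branch-biased placement
# ---------------------------------------------------------------------------

def test_branch_biased_zero_weight_branch_empty(ref_tree, rng):
    branches = branch_decomposition(ref_tree, "basal")
    w = np.ones(len(branches))
    w[0] = 0.0
    syn = place_branch_biased(ref_tree, "basal", w, 500, rng)
    from synaptomap.spatial_stats import branch_density_table

    table = branch_density_table(ref_tree, branches, syn)
    assert table["synapse_count"].iloc[0] == 0
    assert table["synapse_count"].sum() == 500


def test_branch_biased_all_zero_weights_error(ref_tree, rng):
    branches = branch_decomposition(ref_tree, "basal")
    with pytest.raises(ValueError, match="weight"):
        place_branch_biased(ref_tree, "basal", np.zeros(len(branches)), 10, rng)


def test_branch_biased_multinomial_ratio():
    """Two equal-length branches with 3:1 weights receive counts in a 3:1
    ratio within 3 SE at n=4000."""
    from synaptomap.morphology import MorphNode, NeuronTree, StructureType

    nodes = [
        MorphNode(1, StructureType.SOMA, 0, 0, 0, 5.0, -1),
        MorphNode(2, StructureType.BASAL_DENDRITE, 100, 0, 0, 0.5, 1),
        MorphNode(3, StructureType.BASAL_DENDRITE, 0, 100, 0, 0.5, 1),
    ]
    tree = NeuronTree(nodes)
    branches = branch_decomposition(tree, "basal")
    syn = place_branch_biased(
        tree, "basal", np.array([3.0, 1.0]), 4000, np.random.default_rng(1)
    )
    from synaptomap.spatial_stats import branch_density_table

    counts = branch_density_table(tree, branches, syn)["synapse_count"].to_numpy()
    p = 0.75
    se = np.sqrt(4000 * p * (1 - p))
    assert abs(counts[0] - 4000 * p) < 3 * se


def test_branch_biased_equal_weights_matches_uniform(ref_tree):
    """Equal weights reduce to uniform placement (pooled-NN KS check)."""
    branches = branch_decomposition(ref_tree, "basal")
    w = np.ones(len(branches))
    nn_b, nn_u = [], []
    for s in range(5):
        syn = place_branch_biased(ref_tree, "basal", w, 300, np.random.default_rng(s))
        nn_b.append(nearest_neighbor_distances(ref_tree, syn).distances)
        uni = redistribute_uniform(ref_tree, "basal", 300, np.random.default_rng(50 + s))
        nn_u.append(nearest_neighbor_distances(ref_tree, uni).distances)
    D, p = ks_two_sample(np.concatenate(nn_b), np.concatenate(nn_u))
    assert p > 0.01


# ---------------------------------------------------------------------------
# Labeled volumes
# ---------------------------------------------------------------------------

def test_volume_every_spine_has_unique_cloud():
    vol = generate_labeled_volume(
        VolumeGenParams(cloud_density=0.0, association_prob=1.0, n_spines=10, seed=1)
    )
    assert len(vol.spine_ids) == 10
    assert len(vol.cloud_ids) == 10
    assert all(len(v) == 1 for v in vol.truth.values())


def test_volume_determinism():
    a = generate_labeled_volume(VolumeGenParams(seed=8))
    b = generate_labeled_volume(VolumeGenParams(seed=8))
    np.testing.assert_array_equal(a.cloud_labels, b.cloud_labels)
    np.testing.assert_array_equal(a.spine_labels, b.spine_labels)
    assert a.truth == b.truth


def test_volume_poisson_cloud_count_moment():
    """Distractor cloud count over seeds is within 3 SE of density x volume."""
    params = VolumeGenParams(
        n_spines=0, cloud_density=0.5, shape=(20, 32, 32), seed=0
    )
    volume_um3 = np.prod([n * s for n, s in zip(params.shape, params.spacing)])
    lam = params.cloud_density * volume_um3
    n_seeds = 50
    counts = [
        len(
            generate_labeled_volume(
                VolumeGenParams(
                    n_spines=0, cloud_density=0.5, shape=(20, 32, 32), seed=s
                )
            ).cloud_ids
        )
        for s in range(n_seeds)
    ]
    se = np.sqrt(lam / n_seeds)
    assert abs(np.mean(counts) - lam) < 3 * se


def test_volume_packing_failure_names_density():
    with pytest.raises(RuntimeError, match="pack"):
        generate_labeled_volume(
            VolumeGenParams(n_spines=4000, shape=(20, 24, 24), seed=0)
        )
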