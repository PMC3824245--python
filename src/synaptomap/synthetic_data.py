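"""Synthetic data generators emulating the study system.

Three generators make every analysis stage testable without real
reconstructions:

* :func:`generate_tree` — branched L5-pyramidal-like arbors grown by a
  stochastic branching walk (default ~4.7 mm total dendrite, 70% basal),
* :func:`place_clustered` / :func:`place_branch_biased` — synapse placements
  with known structure: a Neyman–Scott-style cluster process parameterized
  along the unrolled arclength, and branch-weighted placement,
* :func:`generate_labeled_volume` — segmented neuropil volumes of spine
  heads and vesicle clouds with a recorded ground-truth association map.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .detection_sim import LabeledVolume
from .morphology import (
    MorphNode,
    NeuronTree,
    StructureType,
    branch_decomposition,
    positions_from_arclengths,
)
from .synapses import SynapseSet

__all__ = [
    "TreeGenParams",
    "ClusterPlacementParams",
    "VolumeGenParams",
    "generate_tree",
    "reference_neuron",
    "place_clustered",
    "place_branch_biased",
    "generate_labeled_volume",
]


# ---------------------------------------------------------------------------
# Arbor generation
# ---------------------------------------------------------------------------

@dataclass
class TreeGenParams:
    """Parameters of the stochastic arbor generator.

    Defaults emulate the study's per-neuron means: 4.7 mm total dendrite,
    with a basal/apical split of 70/30 (the analyses restrict to basal
    dendrites, so only the basal total enters the statistics).
    """

    total_length: float = 4700.0  # µm
    branch_length_mean: float = 60.0  # µm
    branch_length_sd: float = 25.0  # µm
    bifurcation_prob: float = 0.5  # per branch tip
    step: float = 5.0  # µm segment length
    basal_fraction: float = 0.7
    n_basal_stems: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("segment step must be positive")
        if not 0 <= self.bifurcation_prob <= 1:
            raise ValueError("bifurcation_prob must be in [0, 1]")
        if not 0 <= self.basal_fraction <= 1:
            raise ValueError("basal_fraction must be in [0, 1]")
        if min(self.total_length, self.branch_length_mean, self.branch_length_sd) < 0:
            raise ValueError("lengths must be nonnegative")


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([0.0, 1.0, 0.0])


def _grow_region(
    nodes: list[MorphNode],
    rng: np.random.Generator,
    stype: int,
    stems: list[np.ndarray],
    target: float,
    p: TreeGenParams,
) -> None:
    """Grow one region (basal or apical) as a branching random walk until the
    region's summed edge length reaches `target` (overshoot < one step)."""
    soma_id = nodes[0].id
    soma_xyz = np.array([nodes[0].x, nodes[0].y, nodes[0].z])
    grown = 0.0
    # each tip: (parent node id, position, direction)
    tips: list[tuple[int, np.ndarray, np.ndarray]] = [
        (soma_id, soma_xyz.copy(), _unit(d)) for d in stems
    ]
    while grown < target:
        if not tips:  # all tips terminated early: reseed a stem at the soma
            tips.append((soma_id, soma_xyz.copy(), _unit(rng.normal(size=3))))
        parent_id, pos, direction = tips.pop(rng.integers(len(tips)))
        blen = max(p.step, rng.normal(p.branch_length_mean, p.branch_length_sd))
        travelled = 0.0
        while travelled < blen and grown < target:
            direction = _unit(direction + 0.35 * rng.normal(size=3))
            pos = pos + p.step * direction
            nid = len(nodes) + 1
            nodes.append(
                MorphNode(nid, stype, float(pos[0]), float(pos[1]), float(pos[2]),
                          0.5, parent_id)
            )
            parent_id = nid
            travelled += p.step
            grown += p.step
        if grown >= target:
            break
        if rng.random() < p.bifurcation_prob:
            for _ in range(2):
                d = _unit(direction + 0.8 * rng.normal(size=3))
                tips.append((parent_id, pos.copy(), d))
        # else: tip terminates


def generate_tree(params: TreeGenParams) -> NeuronTree:
    """Generate a branched arbor; total dendritic length lands within one
    segment step of the target (well within 10%).  Deterministic per seed."""
    rng = np.random.default_rng(params.seed)
    nodes: list[MorphNode] = [
        MorphNode(1, StructureType.SOMA, 0.0, 0.0, 0.0, 10.0, -1)
    ]
    basal_target = params.total_length * params.basal_fraction
    apical_target = params.total_length - basal_target
    if basal_target > 0:
        angles = 2 * np.pi * np.arange(params.n_basal_stems) / params.n_basal_stems
        stems = [
            np.array([np.cos(a), -0.6, np.sin(a)]) for a in angles
        ]  # downward/lateral fan (y = depth axis, pia at low y)
        _grow_region(nodes, rng, StructureType.BASAL_DENDRITE, stems, basal_target, params)
    if apical_target > 0:
        _grow_region(
            nodes, rng, StructureType.APICAL_DENDRITE,
            [np.array([0.0, 1.0, 0.0])], apical_target, params,
        )
    return NeuronTree(nodes)


def reference_neuron(seed: int = 0) -> NeuronTree:
    """The default synthetic reference neuron used throughout the analyses:
    ~4.7 mm total dendrite at the study's per-neuron scale."""
    return generate_tree(TreeGenParams(seed=seed))


# ---------------------------------------------------------------------------
# Synapse placement
# ---------------------------------------------------------------------------

@dataclass
class ClusterPlacementParams:
    """Neyman–Scott-style cluster process on the unrolled arbor.

    Parents are a Poisson process of intensity ``parent_intensity`` per µm of
    arclength; each synapse picks a parent uniformly and is displaced along
    the arclength by Normal(0, sigma), reflected into [0, L).
    """

    n: int = 328
    parent_intensity: float = 0.01  # parents per µm
    sigma: float = 2.0  # µm
    seed: int = 0

    def __post_init__(self):
        if self.n < 0:
            raise ValueError("n must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.parent_intensity <= 0:
            raise ValueError("parent_intensity must be positive")


def _reflect(s: np.ndarray, L: float) -> np.ndarray:
    t = np.mod(s, 2 * L)
    out = np.where(t < L, t, 2 * L - t)
    return np.minimum(out, np.nextafter(L, 0.0))  # keep strictly below L


def place_clustered(
    tree: NeuronTree, region: str, params: ClusterPlacementParams
) -> SynapseSet:
    """Clustered placement: exactly params.n synapses from the cluster
    process described by `params`, mapped onto the tree."""
    rng = np.random.default_rng(params.seed)
    L = tree.total_length(region)
    n_parents = max(1, rng.poisson(params.parent_intensity * L))
    parents = rng.random(n_parents) * L
    which = rng.integers(n_parents, size=params.n)
    s = _reflect(parents[which] + rng.normal(0.0, params.sigma, params.n), L)
    if params.n == 0:
        return SynapseSet(tree, np.empty(0, np.int64), np.empty(0))
    child_idx, offset = positions_from_arclengths(tree, s, region)
    return SynapseSet(tree, child_idx, offset)


def place_branch_biased(
    tree: NeuronTree,
    region: str,
    branch_weights: np.ndarray,
    n: int,
    rng: np.random.Generator,
) -> SynapseSet:
    """Branch-biased placement: branch chosen with probability proportional
    to weight × length, position uniform within the chosen branch."""
    branches = branch_decomposition(tree, region)
    w = np.asarray(branch_weights, dtype=float)
    if len(w) != len(branches):
        raise ValueError("one weight per branch required")
    if np.any(w < 0) or not np.any(w > 0):
        raise ValueError("weights must be nonnegative with at least one positive")
    lengths = np.array([b.length for b in branches])
    probs = w * lengths
    probs = probs / probs.sum()
    choice = rng.choice(len(branches), size=n, p=probs)
    # uniform position within branch via the branch's arclength interval;
    # branch edges are contiguous in canonical DFS order
    edges, cum = tree.canonical_edges(region)
    rank = np.full(len(tree.nodes), -1, dtype=np.int64)
    rank[edges] = np.arange(len(edges))
    starts = np.empty(len(branches))
    for k, b in enumerate(branches):
        first_edge = tree.node_index(b.node_path[1])
        r = rank[first_edge]
        starts[k] = cum[r] - tree.edge_length[edges[r]]
    s = starts[choice] + rng.random(n) * lengths[choice]
    s = np.minimum(s, np.nextafter(tree.total_length(region), 0.0))
    child_idx, offset = positions_from_arclengths(tree, s, region)
    return SynapseSet(tree, child_idx, offset)


# ---------------------------------------------------------------------------
# Labeled neuropil volumes
# ---------------------------------------------------------------------------

@dataclass
class VolumeGenParams:
    """Synthetic segmented neuropil.

    Spine heads are non-overlapping spheres; each has, with probability
    ``association_prob``, one truly associated vesicle cloud placed touching
    it; distractor clouds are Poisson in space with ``cloud_density`` per
    µm³.  Spacing is (dz, dy, dx) µm and may be anisotropic.
    """

    shape: tuple[int, int, int] = (40, 64, 64)
    spacing: tuple[float, float, float] = (0.2, 0.1, 0.1)
    n_spines: int = 20
    cloud_density: float = 0.3  # clouds per µm³
    association_prob: float = 1.0
    spine_radius: float = 0.25  # µm
    cloud_radius: float = 0.25  # µm
    min_gap: float = 0.3  # µm distractor clearance from spine surfaces
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.association_prob <= 1:
            raise ValueError("association_prob must be in [0, 1]")
        if min(self.spine_radius, self.cloud_radius) <= 0:
            raise ValueError("object radii must be positive")
        if self.cloud_density < 0 or self.n_spines < 0:
            raise ValueError("densities and counts must be nonnegative")


def _sphere_mask(shape, spacing, center_um, radius_um) -> np.ndarray:
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(shape, spacing)], indexing="ij"
    )
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center_um))
    return d2 <= radius_um**2


def generate_labeled_volume(params: VolumeGenParams) -> LabeledVolume:
    """Generate a labeled neuropil volume with known truth map."""
    rng = np.random.default_rng(params.seed)
    shape, spacing = params.shape, params.spacing
    extent = np.array([n * s for n, s in zip(shape, spacing)])
    margin = params.spine_radius + 2 * params.cloud_radius + spacing[0]
    if np.any(extent <= 2 * margin):
        raise ValueError("objects do not fit in the grid")

    spine_labels = np.zeros(shape, dtype=np.int32)
    cloud_labels = np.zeros(shape, dtype=np.int32)
    truth: dict[int, list[int]] = {}

    # non-overlapping spine placement with bounded retries
    centers: list[np.ndarray] = []
    min_sep = 2 * (params.spine_radius + params.cloud_radius) + params.min_gap
    tries = 0
    while len(centers) < params.n_spines:
        tries += 1
        if tries > 200 * max(params.n_spines, 1):
            raise RuntimeError(
                f"could not pack {params.n_spines} spines at density "
                f"{params.n_spines / np.prod(extent):.3g}/um^3"
            )
        c = margin + rng.random(3) * (extent - 2 * margin)
        if all(np.linalg.norm(c - o) >= min_sep for o in centers):
            centers.append(c)

    cloud_id = 0
    for k, c in enumerate(centers, start=1):
        spine_labels[_sphere_mask(shape, spacing, c, params.spine_radius)] = k
        if rng.random() < params.association_prob:
            cloud_id += 1
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            cc = c + direction * (params.spine_radius + params.cloud_radius)
            cloud_labels[_sphere_mask(shape, spacing, cc, params.cloud_radius)] = cloud_id
            truth[k] = [cloud_id]
        else:
            truth[k] = []

    # Poisson distractor clouds, kept clear of spine surfaces
    n_distract = rng.poisson(params.cloud_density * float(np.prod(extent)))
    placed = 0
    tries = 0
    while placed < n_distract and tries < 50 * max(n_distract, 1):
        tries += 1
        cc = rng.random(3) * extent
        if any(
            np.linalg.norm(cc - sc)
            < params.spine_radius + params.cloud_radius + params.min_gap
            for sc in centers
        ):
            continue
        cloud_id += 1
        cloud_labels[_sphere_mask(shape, spacing, cc, params.cloud_radius)] = cloud_id
        placed += 1

    return LabeledVolume(spine_labels, cloud_labels, spacing, truth)
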