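"""Synapse sets: collections of labeled-synapse positions on a neuron tree.

Positions live on tree edges (parent node, child node, µm offset from the
parent endpoint).  A CSV schema is provided for interchange:

    neuron_id, parent_node_id, child_node_id, offset_um

Alternatively columns ``x, y, z`` may be given; those are snapped to the
nearest point of the tree (the snap distance is logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .morphology import NeuronTree, TreePosition, pairwise_path_distance

logger = logging.getLogger(__name__)

__all__ = ["SynapseSet", "read_synapse_csv", "write_synapse_csv"]


@dataclass
class SynapseSet:
    """Positions of labeled synapses on a tree.

    Stored as parallel arrays ``child_idx`` (node index of each position's
    edge child endpoint) and ``offset`` (µm from the parent endpoint).
    """

    tree: NeuronTree
    child_idx: np.ndarray
    offset: np.ndarray

    def __post_init__(self):
        self.child_idx = np.asarray(self.child_idx, dtype=np.int64)
        self.offset = np.asarray(self.offset, dtype=float)
        if self.child_idx.shape != self.offset.shape:
            raise ValueError("child_idx and offset must have equal length")
        if len(self.child_idx):
            if np.any(self.tree.parent_idx[self.child_idx] < 0):
                raise ValueError("synapse placed on the root node (no edge)")
            lens = self.tree.edge_length[self.child_idx]
            if np.any((self.offset < -1e-9) | (self.offset > lens + 1e-9)):
                raise ValueError("synapse offset outside its edge")

    def __len__(self) -> int:
        return len(self.child_idx)

    @classmethod
    def from_positions(cls, tree: NeuronTree, positions) -> "SynapseSet":
        child_idx, offset = tree.position_arrays(list(positions))
        return cls(tree, child_idx, offset)

    @property
    def positions(self) -> list[TreePosition]:
        out = []
        for c, o in zip(self.child_idx, self.offset):
            c = int(c)
            out.append(
                TreePosition(
                    int(self.tree.ids[self.tree.parent_idx[c]]),
                    int(self.tree.ids[c]),
                    float(o),
                )
            )
        return out

    @property
    def xyz(self) -> np.ndarray:
        """Derived 3D coordinates (µm)."""
        return self.tree.positions_xyz(self.child_idx, self.offset)

    def path_distances_from_soma(self) -> np.ndarray:
        return self.tree.root_path_distance(self.child_idx, self.offset)

    def pairwise_path_distances(self) -> np.ndarray:
        return pairwise_path_distance(self.tree, self.child_idx, self.offset)


def read_synapse_csv(path, tree: NeuronTree, neuron_id=None) -> SynapseSet:
    """Load a synapse CSV onto `tree`.

    Rows with edge/offset columns are taken verbatim; if only x,y,z columns
    are present each point is snapped to the nearest tree node's parent edge
    by perpendicular projection, and the snap distance is logged.
    """
    df = pd.read_csv(path)
    if neuron_id is not None and "neuron_id" in df.columns:
        df = df[df["neuron_id"] == neuron_id]
    if {"parent_node_id", "child_node_id", "offset_um"} <= set(df.columns):
        child_idx = np.array(
            [tree.node_index(c) for c in df["child_node_id"]], dtype=np.int64
        )
        exp_parent = tree.parent_idx[child_idx]
        got_parent = np.array(
            [tree.node_index(p) for p in df["parent_node_id"]], dtype=np.int64
        )
        if np.any(exp_parent != got_parent):
            bad = df["child_node_id"].to_numpy()[exp_parent != got_parent][0]
            raise ValueError(f"row for child {bad}: not an edge of the tree")
        return SynapseSet(tree, child_idx, df["offset_um"].to_numpy(float))
    if {"x", "y", "z"} <= set(df.columns):
        return snap_points_to_tree(tree, df[["x", "y", "z"]].to_numpy(float))
    raise ValueError(
        "synapse CSV needs (parent_node_id, child_node_id, offset_um) or (x, y, z)"
    )


def snap_points_to_tree(tree: NeuronTree, pts: np.ndarray) -> SynapseSet:
    """Snap 3D points to the nearest point on any non-root edge."""
    edges = np.flatnonzero(tree.parent_idx >= 0)
    p0 = tree.xyz[tree.parent_idx[edges]]
    v = tree.xyz[edges] - p0
    vv = np.einsum("ij,ij->i", v, v)
    child_idx = np.empty(len(pts), dtype=np.int64)
    offset = np.empty(len(pts), dtype=float)
    worst = 0.0
    for k, pt in enumerate(np.atleast_2d(pts)):
        t = np.clip(np.einsum("ij,ij->i", pt - p0, v) / np.where(vv > 0, vv, 1), 0, 1)
        proj = p0 + t[:, None] * v
        d2 = np.sum((proj - pt) ** 2, axis=1)
        j = int(np.argmin(d2))
        child_idx[k] = edges[j]
        offset[k] = t[j] * np.sqrt(vv[j])
        worst = max(worst, float(np.sqrt(d2[j])))
    logger.info("snapped %d points to tree; max snap distance %.3f um", len(pts), worst)
    return SynapseSet(tree, child_idx, offset)


def write_synapse_csv(synapses: SynapseSet, path, neuron_id: int = 0) -> None:
    tree = synapses.tree
    df = pd.DataFrame(
        {
            "neuron_id": neuron_id,
            "parent_node_id": tree.ids[tree.parent_idx[synapses.child_idx]],
            "child_node_id": tree.ids[synapses.child_idx],
            "offset_um": synapses.offset,
        }
    )
    df.to_csv(path, index=False)
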