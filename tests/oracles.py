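"""Independent brute-force oracles used by the test suite.

These deliberately avoid the code paths they check: shortest paths go
through networkx Dijkstra on an explicitly densified graph, distance
transforms through an all-pairs scan, clustering coefficients through
triangle enumeration, and the KS statistic through an exhaustive ECDF sweep.
"""

import numpy as np
import networkx as nx

from synaptomap.morphology import NeuronTree
from synaptomap.synapses import SynapseSet


def node_graph(tree: NeuronTree) -> nx.Graph:
    G = nx.Graph()
    for k in range(len(tree.nodes)):
        p = tree.parent_idx[k]
        if p >= 0:
            G.add_edge(int(p), int(k), weight=float(tree.edge_length[k]))
    return G


def dijkstra_position_distance(tree: NeuronTree, a, b) -> float:
    """Shortest path between two on-tree positions via a graph densified
    with both positions spliced in as explicit vertices."""
    (ca, oa), (cb, ob) = a, b
    G = node_graph(tree)
    pa, pb = int(tree.parent_idx[ca]), int(tree.parent_idx[cb])
    if ca == cb:
        (o1, n1), (o2, n2) = sorted([(oa, "A"), (ob, "B")])
        G.remove_edge(pa, int(ca))
        G.add_edge(pa, n1, weight=o1)
        G.add_edge(n1, n2, weight=o2 - o1)
        G.add_edge(n2, int(ca), weight=float(tree.edge_length[ca]) - o2)
    else:
        G.remove_edge(pa, int(ca))
        G.add_edge(pa, "A", weight=oa)
        G.add_edge("A", int(ca), weight=float(tree.edge_length[ca]) - oa)
        G.remove_edge(pb, int(cb))
        G.add_edge(pb, "B", weight=ob)
        G.add_edge("B", int(cb), weight=float(tree.edge_length[cb]) - ob)
    return nx.dijkstra_path_length(G, "A", "B")


def brute_nn_distances(tree: NeuronTree, synapses: SynapseSet) -> np.ndarray:
    """O(n^2) nearest-neighbor distances over the Dijkstra oracle."""
    n = len(synapses)
    pos = list(zip(synapses.child_idx, synapses.offset))
    D = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dijkstra_position_distance(tree, pos[i], pos[j])
    return D.min(axis=1)


def brute_distance_transform(mask: np.ndarray, spacing) -> np.ndarray:
    """All-pairs scan: per-voxel min physical distance to any mask voxel."""
    coords = np.argwhere(mask) * np.asarray(spacing)
    grids = np.meshgrid(
        *[np.arange(n) * s for n, s in zip(mask.shape, spacing)], indexing="ij"
    )
    pts = np.stack([g.ravel() for g in grids], axis=1)
    out = np.full(len(pts), np.inf)
    for chunk in np.array_split(np.arange(len(pts)), 16):
        d = np.linalg.norm(pts[chunk, None, :] - coords[None, :, :], axis=2)
        out[chunk] = d.min(axis=1)
    return out.reshape(mask.shape)


def brute_mean_clustering(adj: np.ndarray) -> float:
    """Triangle enumeration, nodes of degree < 2 excluded from the mean."""
    A = np.asarray(adj, dtype=bool)
    n = len(A)
    coeffs = []
    for i in range(n):
        nbrs = np.flatnonzero(A[i])
        if len(nbrs) < 2:
            continue
        links = 0
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                links += A[nbrs[a], nbrs[b]]
        coeffs.append(links / (len(nbrs) * (len(nbrs) - 1) / 2))
    return float(np.mean(coeffs)) if coeffs else float("nan")


def brute_ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Exhaustive sup of |ECDF_x - ECDF_y| over every pooled sample point."""
    best = 0.0
    for t in np.concatenate([x, y]):
        best = max(best, abs(np.mean(x <= t) - np.mean(y <= t)))
    return best


def brute_sholl(tree: NeuronTree, radii, region="dendrites", ds=0.01) -> np.ndarray:
    """Dense arclength sampling: count sign changes of (distance-to-soma - r)
    along each edge sampled every `ds` µm."""
    mask = tree.region_edge_mask(region)
    edges = np.flatnonzero(mask)
    c = tree.soma_center
    counts = np.zeros(len(radii), dtype=int)
    for e in edges:
        p0 = tree.xyz[tree.parent_idx[e]]
        p1 = tree.xyz[e]
        n = max(2, int(np.ceil(tree.edge_length[e] / ds)))
        t = np.linspace(0, 1, n)
        d = np.linalg.norm(p0 + t[:, None] * (p1 - p0) - c, axis=1)
        for k, r in enumerate(radii):
            s = np.sign(d - r)
            counts[k] += int(np.sum(s[:-1] * s[1:] < 0))
    return counts
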