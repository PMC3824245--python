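"""Neuron morphology model built on SWC skeletons.

A reconstructed neuron is a rooted geometric tree whose nodes carry 3D
coordinates (µm) and a structure type (soma, axon, basal or apical dendrite).
The module provides the exact path-length (geodesic) metric along the tree,
the arclength "unrolling" bijection between positions on the arbor and a
single interval [0, L) used by the random-redistribution null, decomposition
of the arbor into branches (segments between branch points / terminals), and
3D Sholl analysis (intersections of dendrites with concentric spheres
centered on the soma).

Conventions
-----------
* SWC dialect: 1-based node ids, parent -1 for the root, type codes
  1 soma / 2 axon / 3 basal dendrite / 4 apical dendrite.
* Soma nodes contribute no analyzed length; axon edges are excluded from all
  dendritic analyses.
* An edge belongs to the region of its *child* node.
* Canonical edge ordering for the arclength map: depth-first from the root,
  children visited in ascending node id.  Any fixed order yields the same
  null distribution; determinism is the requirement.
* Offsets of on-tree positions are measured in µm from the parent endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StructureType",
    "MorphNode",
    "TreePosition",
    "Branch",
    "ShollProfile",
    "NeuronTree",
    "SWCError",
    "read_swc",
    "write_swc",
    "path_distance",
    "pairwise_path_distance",
    "position_from_arclength",
    "arclength_from_position",
    "branch_decomposition",
    "sholl_3d",
]


class StructureType(IntEnum):
    """SWC structure type codes."""

    UNDEFINED = 0
    SOMA = 1
    AXON = 2
    BASAL_DENDRITE = 3
    APICAL_DENDRITE = 4
    OTHER = 5


#: Region name -> structure type codes included in that region.  Soma is
#: always excluded from analyzed length.
REGIONS: dict[str, tuple[int, ...]] = {
    "basal": (StructureType.BASAL_DENDRITE,),
    "apical": (StructureType.APICAL_DENDRITE,),
    "dendrites": (StructureType.BASAL_DENDRITE, StructureType.APICAL_DENDRITE),
    "axon": (StructureType.AXON,),
    "all": (
        StructureType.AXON,
        StructureType.BASAL_DENDRITE,
        StructureType.APICAL_DENDRITE,
        StructureType.OTHER,
        StructureType.UNDEFINED,
    ),
}


class SWCError(ValueError):
    """Structured SWC parse/validation error."""


@dataclass(frozen=True)
class MorphNode:
    id: int
    structure_type: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int  # -1 for root


@dataclass(frozen=True)
class TreePosition:
    """A point on the tree: an edge (parent_id, child_id) plus a µm offset
    measured from the parent endpoint."""

    parent_id: int
    child_id: int
    offset: float

    @property
    def edge(self) -> tuple[int, int]:
        return (self.parent_id, self.child_id)


@dataclass(frozen=True)
class Branch:
    """Maximal unbranched run of edges between branch points / terminals."""

    branch_id: int
    node_path: tuple[int, ...]  # node ids, first = proximal anchor
    length: float
    region: str


@dataclass
class ShollProfile:
    radii: np.ndarray
    intersections: np.ndarray


class _LCAIndex:
    """Euler-tour + sparse-table index for vectorized lowest-common-ancestor
    queries.  The minimum root-path distance on the tour segment between two
    first occurrences is attained exactly at the LCA (edge weights > 0)."""

    def __init__(self, tour_nodes: np.ndarray, tour_dist: np.ndarray, first_occ: np.ndarray):
        self.tour_nodes = tour_nodes
        self.tour_dist = tour_dist
        self.first_occ = first_occ
        m = len(tour_nodes)
        levels = max(1, m.bit_length())
        table = np.empty((levels, m), dtype=np.int64)
        table[0] = np.arange(m)
        for k in range(1, levels):
            half = 1 << (k - 1)
            width = m - (1 << k) + 1
            if width <= 0:
                table = table[:k]
                break
            a = table[k - 1, :width]
            b = table[k - 1, half : half + width]
            table[k, :width] = np.where(tour_dist[a] <= tour_dist[b], a, b)
        self._table = table
        logt = np.zeros(m + 1, dtype=np.int64)
        for i in range(2, m + 1):
            logt[i] = logt[i >> 1] + 1
        self._logt = logt

    def lca(self, u: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Vectorized LCA: node indices for arrays of node indices."""
        fu = self.first_occ[u]
        fv = self.first_occ[v]
        lo = np.minimum(fu, fv)
        hi = np.maximum(fu, fv)
        j = self._logt[hi - lo + 1]
        a = self._table[j, lo]
        b = self._table[j, hi - (1 << j) + 1]
        pick = np.where(self.tour_dist[a] <= self.tour_dist[b], a, b)
        return self.tour_nodes[pick]


class NeuronTree:
    """Rooted geometric tree of SWC nodes with per-edge physical lengths.

    Parameters
    ----------
    nodes:
        Iterable of :class:`MorphNode`.  Exactly one node must be a root
        (``parent_id == -1``); ids must be unique and parents must exist.
    """

    def __init__(self, nodes: Iterable[MorphNode]):
        nodes = list(nodes)
        if not nodes:
            raise SWCError("empty morphology")
        ids = np.array([n.id for n in nodes], dtype=np.int64)
        if len(np.unique(ids)) != len(ids):
            dup = ids[np.argmax(np.bincount(ids - ids.min()) > 1)]
            raise SWCError(f"duplicate node id {int(dup)}")
        self.nodes: list[MorphNode] = nodes
        self.ids = ids
        self._index = {int(i): k for k, i in enumerate(ids)}
        self.xyz = np.array([[n.x, n.y, n.z] for n in nodes], dtype=float)
        self.radius = np.array([n.radius for n in nodes], dtype=float)
        self.types = np.array([n.structure_type for n in nodes], dtype=np.int64)

        roots = [n for n in nodes if n.parent_id == -1]
        if len(roots) != 1:
            raise SWCError(f"expected exactly one root, found {len(roots)}")
        self.root_idx = self._index[roots[0].id]

        parent_idx = np.full(len(nodes), -1, dtype=np.int64)
        for k, n in enumerate(nodes):
            if n.parent_id == -1:
                continue
            if n.parent_id not in self._index:
                raise SWCError(
                    f"node {n.id} references missing parent {n.parent_id}"
                )
            parent_idx[k] = self._index[n.parent_id]
        self.parent_idx = parent_idx

        children: list[list[int]] = [[] for _ in nodes]
        for k, p in enumerate(parent_idx):
            if p >= 0:
                children[p].append(k)
        # canonical order: ascending child id
        self.children = [sorted(c, key=lambda k: self.ids[k]) for c in children]

        # edge length for each non-root node's parent edge
        diffs = self.xyz - self.xyz[np.maximum(parent_idx, 0)]
        self.edge_length = np.linalg.norm(diffs, axis=1)
        self.edge_length[self.root_idx] = 0.0
        nonroot = np.arange(len(nodes)) != self.root_idx
        if np.any(self.edge_length[nonroot] <= 0):
            bad = self.ids[nonroot][self.edge_length[nonroot] <= 0][0]
            raise SWCError(f"zero-length edge at node {int(bad)}")

        self._finish_traversal()
        self._canonical_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._branch_cache: dict[str, list[Branch]] = {}

    # -- construction internals ------------------------------------------

    def _finish_traversal(self) -> None:
        n = len(self.nodes)
        order = np.empty(n, dtype=np.int64)
        dist_root = np.zeros(n, dtype=float)
        tour_nodes: list[int] = []
        tour_dist: list[float] = []
        first_occ = np.full(n, -1, dtype=np.int64)
        visited = np.zeros(n, dtype=bool)

        # iterative DFS, canonical child order; record Euler tour
        stack: list[tuple[int, int]] = [(self.root_idx, 0)]
        pos = 0
        while stack:
            node, ci = stack[-1]
            if ci == 0:
                if visited[node]:
                    raise SWCError(f"cycle detected at node {int(self.ids[node])}")
                visited[node] = True
                order[pos] = node
                pos += 1
                if first_occ[node] < 0:
                    first_occ[node] = len(tour_nodes)
                tour_nodes.append(node)
                tour_dist.append(dist_root[node])
            kids = self.children[node]
            if ci < len(kids):
                stack[-1] = (node, ci + 1)
                child = kids[ci]
                dist_root[child] = dist_root[node] + self.edge_length[child]
                stack.append((child, 0))
            else:
                stack.pop()
                if stack:
                    parent = stack[-1][0]
                    tour_nodes.append(parent)
                    tour_dist.append(dist_root[parent])
        if pos != n:
            missing = self.ids[~visited]
            raise SWCError(
                f"disconnected morphology: {len(missing)} unreachable node(s), "
                f"first id {int(missing[0])}"
            )
        self.dfs_order = order
        self.dist_root = dist_root
        self._lca = _LCAIndex(
            np.asarray(tour_nodes, dtype=np.int64),
            np.asarray(tour_dist, dtype=float),
            first_occ,
        )

    # -- basic properties -------------------------------------------------

    @property
    def soma_center(self) -> np.ndarray:
        """Coordinate of the root soma node (µm)."""
        return self.xyz[self.root_idx]

    def node_index(self, node_id: int) -> int:
        return self._index[int(node_id)]

    def region_edge_mask(self, region: str) -> np.ndarray:
        """Boolean per-node mask: True where the node's parent edge belongs
        to `region` (child-node typing; soma edges always excluded)."""
        codes = REGIONS[region]
        mask = np.isin(self.types, codes) & (self.parent_idx >= 0)
        mask &= self.types != StructureType.SOMA
        return mask

    def canonical_edges(self, region: str) -> tuple[np.ndarray, np.ndarray]:
        """Region edges in canonical DFS order.

        Returns ``(child_idx, cum_length)`` where ``cum_length[k]`` is the
        arclength at the *end* of edge k; ``cum_length[-1]`` is the region's
        total length L.
        """
        if region not in self._canonical_cache:
            mask = self.region_edge_mask(region)
            edges = self.dfs_order[mask[self.dfs_order]]
            cum = np.cumsum(self.edge_length[edges])
            self._canonical_cache[region] = (edges, cum)
        return self._canonical_cache[region]

    def total_length(self, region: str = "dendrites") -> float:
        """Summed edge length (µm) of the region."""
        _, cum = self.canonical_edges(region)
        return float(cum[-1]) if len(cum) else 0.0

    # -- position helpers --------------------------------------------------

    def position(self, parent_id: int, child_id: int, offset: float) -> TreePosition:
        ci = self.node_index(child_id)
        if self.parent_idx[ci] != self.node_index(parent_id):
            raise ValueError(f"({parent_id}, {child_id}) is not an edge of this tree")
        if not 0.0 <= offset <= self.edge_length[ci] + 1e-9:
            raise ValueError(
                f"offset {offset} outside edge of length {self.edge_length[ci]}"
            )
        return TreePosition(parent_id, child_id, float(offset))

    def position_arrays(
        self, positions: Sequence[TreePosition]
    ) -> tuple[np.ndarray, np.ndarray]:
        """(child node indices, offsets) arrays for a list of positions."""
        child_idx = np.array(
            [self.node_index(p.child_id) for p in positions], dtype=np.int64
        )
        offset = np.array([p.offset for p in positions], dtype=float)
        return child_idx, offset

    def positions_xyz(self, child_idx: np.ndarray, offset: np.ndarray) -> np.ndarray:
        """3D coordinates (µm) of positions by linear interpolation along
        their edges."""
        p = self.parent_idx[child_idx]
        frac = np.where(
            self.edge_length[child_idx] > 0, offset / self.edge_length[child_idx], 0.0
        )
        return self.xyz[p] + frac[:, None] * (self.xyz[child_idx] - self.xyz[p])

    def root_path_distance(self, child_idx: np.ndarray, offset: np.ndarray) -> np.ndarray:
        """Path distance (µm) from the soma center (root) to each position."""
        return self.dist_root[child_idx] - self.edge_length[child_idx] + offset


# ---------------------------------------------------------------------------
# SWC I/O
# ---------------------------------------------------------------------------

def read_swc(path) -> NeuronTree:
    """Parse a whitespace-delimited SWC file into a :class:`NeuronTree`.

    Two-pass: rows are collected first, so a parent listed after its child is
    accepted.  Raises :class:`SWCError` naming the offending line / node on
    duplicate ids, dangling parents or cycles.
    """
    nodes: list[MorphNode] = []
    seen: set[int] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCError(f"line {lineno}: expected 7 fields, got {len(parts)}")
            try:
                nid = int(parts[0])
                stype = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                pid = int(parts[6])
            except ValueError as exc:
                raise SWCError(f"line {lineno}: {exc}") from None
            if nid in seen:
                raise SWCError(f"line {lineno}: duplicate node id {nid}")
            seen.add(nid)
            nodes.append(MorphNode(nid, stype, x, y, z, r, pid))
    for n in nodes:
        if n.parent_id != -1 and n.parent_id not in seen:
            raise SWCError(f"node {n.id} references missing parent {n.parent_id}")
    return NeuronTree(nodes)


def write_swc(tree: NeuronTree, path) -> None:
    """Write SWC with numeric fields at 6 significant digits (round-trip
    faithful at that precision)."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for n in tree.nodes:
            fh.write(
                f"{n.id} {n.structure_type} {n.x:.6g} {n.y:.6g} {n.z:.6g} "
                f"{n.radius:.6g} {n.parent_id}\n"
            )


# ---------------------------------------------------------------------------
# Path-length metric
# ---------------------------------------------------------------------------

def pairwise_path_distance(
    tree: NeuronTree, child_idx: np.ndarray, offset: np.ndarray
) -> np.ndarray:
    """Full symmetric matrix of geodesic (along-tree) distances, in µm,
    between positions given as (child node index, offset-from-parent).

    Uses root-path distances and vectorized LCA queries:
    ``d(a,b) = s(a) + s(b) - 2 s(meet)`` with corrections when both points
    share an edge or one lies on the other's root path.
    """
    child_idx = np.asarray(child_idx, dtype=np.int64)
    offset = np.asarray(offset, dtype=float)
    m = len(child_idx)
    sr = tree.root_path_distance(child_idx, offset)
    D = np.zeros((m, m), dtype=float)
    if m < 2:
        return D
    iu, ju = np.triu_indices(m, k=1)
    ci, cj = child_idx[iu], child_idx[ju]
    lca = tree._lca.lca(ci, cj)
    d = sr[iu] + sr[ju] - 2.0 * tree.dist_root[lca]
    same = ci == cj
    anc_i = (lca == ci) & ~same  # position i's edge lies on j's root path
    anc_j = (lca == cj) & ~same
    diff = sr[iu] - sr[ju]
    d[same] = np.abs(diff[same])
    d[anc_i] = -diff[anc_i]
    d[anc_j] = diff[anc_j]
    D[iu, ju] = d
    D[ju, iu] = d
    return D


def path_distance(tree: NeuronTree, a: TreePosition, b: TreePosition) -> float:
    """Geodesic distance along the tree between two on-tree positions (µm)."""
    child_idx, offset = tree.position_arrays([a, b])
    return float(pairwise_path_distance(tree, child_idx, offset)[0, 1])


# ---------------------------------------------------------------------------
# Arclength bijection ("unrolling")
# ---------------------------------------------------------------------------

def positions_from_arclengths(
    tree: NeuronTree, s: np.ndarray, region: str = "basal"
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized inverse of the unrolling map: arclengths s in [0, L) ->
    (child node index, offset) arrays under the canonical edge order."""
    edges, cum = tree.canonical_edges(region)
    if len(edges) == 0:
        raise ValueError(f"region {region!r} has no edges")
    s = np.asarray(s, dtype=float)
    L = cum[-1]
    if np.any((s < 0) | (s >= L)):
        bad = s[(s < 0) | (s >= L)][0]
        raise ValueError(f"arclength {bad} outside [0, {L})")
    k = np.searchsorted(cum, s, side="right")
    start = cum[k] - tree.edge_length[edges[k]]
    return edges[k], s - start


def position_from_arclength(
    tree: NeuronTree, s: float, region: str = "basal"
) -> TreePosition:
    """Map an arclength s in [0, L) on the unrolled region back onto the
    tree (canonical depth-first edge order, children by ascending id)."""
    child_idx, offset = positions_from_arclengths(tree, np.array([s]), region)
    c = int(child_idx[0])
    return TreePosition(
        int(tree.ids[tree.parent_idx[c]]), int(tree.ids[c]), float(offset[0])
    )


def arclengths_from_positions(
    tree: NeuronTree, child_idx: np.ndarray, offset: np.ndarray, region: str = "basal"
) -> np.ndarray:
    """Vectorized forward unrolling map: positions -> arclengths in [0, L)."""
    edges, cum = tree.canonical_edges(region)
    rank = np.full(len(tree.nodes), -1, dtype=np.int64)
    rank[edges] = np.arange(len(edges))
    r = rank[np.asarray(child_idx, dtype=np.int64)]
    if np.any(r < 0):
        raise ValueError(f"position outside region {region!r}")
    start = cum[r] - tree.edge_length[edges[r]]
    return start + np.asarray(offset, dtype=float)


def arclength_from_position(
    tree: NeuronTree, pos: TreePosition, region: str = "basal"
) -> float:
    child_idx, offset = tree.position_arrays([pos])
    return float(arclengths_from_positions(tree, child_idx, offset, region)[0])


# ---------------------------------------------------------------------------
# Branch decomposition
# ---------------------------------------------------------------------------

def branch_decomposition(tree: NeuronTree, region: str = "basal") -> list[Branch]:
    """Split the region's edges into branches: maximal unbranched runs between
    branch points and terminals.  Branch lengths partition total_length(region).
    """
    if region in tree._branch_cache:
        return tree._branch_cache[region]
    mask = tree.region_edge_mask(region)
    # children within region, canonical order
    region_children = [
        [c for c in tree.children[k] if mask[c]] for k in range(len(tree.nodes))
    ]
    # branch starts: region edges whose parent is a branch point w.r.t. the
    # region subgraph, or whose parent has no region parent-edge (region root)
    branches: list[Branch] = []
    for start in tree.dfs_order:
        if not mask[start]:
            continue
        p = tree.parent_idx[start]
        parent_is_anchor = (not mask[p]) or len(region_children[p]) > 1
        if not parent_is_anchor:
            continue
        path = [p, start]
        length = tree.edge_length[start]
        node = start
        while len(region_children[node]) == 1:
            node = region_children[node][0]
            path.append(node)
            length += tree.edge_length[node]
        branches.append(
            Branch(
                branch_id=len(branches),
                node_path=tuple(int(tree.ids[k]) for k in path),
                length=float(length),
                region=region,
            )
        )
    tree._branch_cache[region] = branches
    return branches


def branch_of_edges(tree: NeuronTree, region: str = "basal") -> np.ndarray:
    """Per-node array mapping each region edge (child node index) to its
    branch_id; -1 outside the region."""
    branches = branch_decomposition(tree, region)
    out = np.full(len(tree.nodes), -1, dtype=np.int64)
    for b in branches:
        for nid in b.node_path[1:]:
            out[tree.node_index(nid)] = b.branch_id
    return out


# ---------------------------------------------------------------------------
# Sholl analysis
# ---------------------------------------------------------------------------

def sholl_3d(
    tree: NeuronTree, radii: np.ndarray, region: str = "dendrites"
) -> ShollProfile:
    """3D Sholl analysis: per radius, the number of crossings of dendritic
    segments with the sphere of that radius centered at the soma center.

    Each straight segment can cross a given sphere at most twice; both
    crossings are counted.  Crossings are counted on the half-open parameter
    interval (0, 1] of each edge so a node lying exactly on a sphere is not
    double-counted between its two adjacent edges.
    """
    radii = np.asarray(radii, dtype=float)
    if len(radii) and (np.any(np.diff(radii) <= 0) or radii[0] <= 0):
        raise ValueError("radii must be strictly increasing and positive")
    mask = tree.region_edge_mask(region)
    edges = np.flatnonzero(mask)
    c = tree.soma_center
    p0 = tree.xyz[tree.parent_idx[edges]] - c
    p1 = tree.xyz[edges] - c
    v = p1 - p0
    vv = np.einsum("ij,ij->i", v, v)
    # squared distance along the edge: q(t) = |p0 + t v|^2, minimized at t*
    tstar = np.clip(-np.einsum("ij,ij->i", p0, v) / np.where(vv > 0, vv, 1.0), 0.0, 1.0)
    q0 = np.einsum("ij,ij->i", p0, p0)
    q1 = np.einsum("ij,ij->i", p1, p1)
    qs = q0 + 2 * tstar * np.einsum("ij,ij->i", p0, v) + tstar**2 * vv

    # q(t) = squared distance is decreasing on [0, t*], increasing on [t*, 1].
    # Count roots of q(t) = r^2 in the half-open interval (0, 1]:
    #   descending piece holds a root in (0, t*] iff q0 > r^2 >= qs;
    #   ascending piece holds a root in (t*, 1] iff qs < r^2 <= q1.
    # Exact boundary hits thereby attach to the proximal edge only, and an
    # interior tangency (qs == r^2) counts once.
    counts = np.zeros(len(radii), dtype=np.int64)
    for k, r in enumerate(radii):
        r2 = r * r
        desc = (q0 > r2) & (qs <= r2)
        asc = (qs < r2) & (q1 >= r2)
        counts[k] = int(np.sum(desc) + np.sum(asc))
    return ShollProfile(radii=radii, intersections=counts)
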