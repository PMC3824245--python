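"""Descriptive and comparative statistics of synapse sets on dendritic trees.

All distances are path distances along the tree (geodesics), not Euclidean
distances — including the "neighbor within d µm" rule — unless a function's
``metric="euclidean"`` option says otherwise.  The statistics mirror the
standard toolkit for analyzing labeled-synapse maps on reconstructed arbors:

* per-branch synapse counts and densities,
* nearest-neighbor path-distance distributions and their ECDFs,
* proximity graphs (synapses connected when within a threshold d) and the
  mean local clustering coefficient as a function of d,
* radial (path-distance-from-soma) histograms,
* soma- or pia-aligned 2D mean density maps across neurons,
* a two-sample Kolmogorov–Smirnov test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import kolmogorov

from .morphology import Branch, NeuronTree, branch_of_edges
from .synapses import SynapseSet

__all__ = [
    "NNDistribution",
    "ClusteringCurve",
    "DensityMap2D",
    "nearest_neighbor_distances",
    "fraction_with_neighbor_within",
    "proximity_graph",
    "mean_clustering_coefficient",
    "clustering_curve",
    "branch_density_table",
    "radial_path_histogram",
    "density_map_2d",
    "ks_two_sample",
    "UNDEFINED",
]

#: Marker returned where a mean clustering coefficient is undefined
#: (no node of degree >= 2 in the proximity graph).
UNDEFINED = float("nan")


@dataclass
class NNDistribution:
    """Nearest-neighbor path distances, one per synapse."""

    distances: np.ndarray

    def ecdf(self, d) -> np.ndarray:
        """Empirical CDF evaluated at d (scalar or array)."""
        x = np.sort(self.distances)
        return np.searchsorted(x, np.asarray(d, dtype=float), side="right") / len(x)


@dataclass
class ClusteringCurve:
    thresholds: np.ndarray
    mean_coefficient: np.ndarray  # NaN where undefined


@dataclass
class DensityMap2D:
    x_edges: np.ndarray
    y_edges: np.ndarray
    density: np.ndarray  # synapses / µm², averaged over neurons
    alignment: str


# ---------------------------------------------------------------------------
# Nearest neighbors
# ---------------------------------------------------------------------------

def _pairwise(tree: NeuronTree, synapses: SynapseSet, metric: str) -> np.ndarray:
    if metric == "path":
        return synapses.pairwise_path_distances()
    if metric == "euclidean":
        xyz = synapses.xyz
        diff = xyz[:, None, :] - xyz[None, :, :]
        return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))
    raise ValueError(f"unknown metric {metric!r}")


def nearest_neighbor_distances(
    tree: NeuronTree, synapses: SynapseSet, metric: str = "path"
) -> NNDistribution:
    """For each synapse, the minimum distance to any other synapse.

    Computed from the full pairwise path-distance matrix.  Coincident
    synapses (distance 0) are legal — annotation may place two contacts on
    one spine — and produce a warning.
    """
    n = len(synapses)
    if n < 2:
        raise ValueError("nearest-neighbor distances need at least 2 synapses")
    D = _pairwise(tree, synapses, metric)
    np.fill_diagonal(D, np.inf)
    nn = D.min(axis=1)
    if np.any(nn == 0):
        warnings.warn(
            f"{int(np.sum(nn == 0))} synapses are coincident with a neighbor",
            stacklevel=2,
        )
    return NNDistribution(distances=nn)


def fraction_with_neighbor_within(
    tree: NeuronTree, synapses: SynapseSet, d: float, metric: str = "path"
) -> float:
    """Share of synapses with at least one other synapse within path
    distance d.  Equals the NN ECDF at d."""
    if d <= 0:
        raise ValueError("d must be positive")
    nn = nearest_neighbor_distances(tree, synapses, metric)
    return float(np.mean(nn.distances <= d))


# ---------------------------------------------------------------------------
# Proximity graph and clustering coefficient
# ---------------------------------------------------------------------------

def proximity_graph(
    tree: NeuronTree, synapses: SynapseSet, d: float, metric: str = "path"
) -> np.ndarray:
    """Boolean adjacency matrix: synapses i != j connected iff their path
    distance is <= d.  Symmetric, zero diagonal."""
    if d <= 0:
        raise ValueError("d must be positive")
    D = _pairwise(tree, synapses, metric)
    A = D <= d
    np.fill_diagonal(A, False)
    return A


def mean_clustering_coefficient(adjacency: np.ndarray) -> float:
    """Mean local clustering coefficient of an undirected graph.

    For each node with degree >= 2, the fraction of its neighbor pairs that
    are themselves connected (triangles through the node over deg·(deg−1)/2);
    nodes of degree < 2 (ratio undefined) are excluded from the average.
    Returns NaN (``UNDEFINED``) when no node has degree >= 2.
    """
    A = np.asarray(adjacency, dtype=bool)
    deg = A.sum(axis=1)
    eligible = deg >= 2
    if not np.any(eligible):
        return UNDEFINED
    Af = A.astype(np.float64)
    triangles = ((Af @ Af) * Af).sum(axis=1) / 2.0
    possible = deg * (deg - 1) / 2.0
    coeffs = triangles[eligible] / possible[eligible]
    return float(np.mean(coeffs))


def clustering_curve(
    tree: NeuronTree,
    synapses: SynapseSet,
    d_grid: np.ndarray,
    metric: str = "path",
) -> ClusteringCurve:
    """Mean clustering coefficient of the proximity graph at each threshold.

    At d >= the diameter of the synapse set the graph is complete and the
    coefficient is exactly 1.
    """
    d_grid = np.asarray(d_grid, dtype=float)
    if np.any(np.diff(d_grid) <= 0):
        raise ValueError("d_grid must be strictly increasing")
    D = _pairwise(tree, synapses, metric)
    out = np.empty(len(d_grid))
    for k, d in enumerate(d_grid):
        A = D <= d
        np.fill_diagonal(A, False)
        out[k] = mean_clustering_coefficient(A)
    return ClusteringCurve(thresholds=d_grid, mean_coefficient=out)


# ---------------------------------------------------------------------------
# Branch densities
# ---------------------------------------------------------------------------

def branch_density_table(
    tree: NeuronTree,
    branches: list[Branch],
    synapses: SynapseSet,
) -> pd.DataFrame:
    """Per-branch synapse counts and linear densities (synapses/µm).

    Each synapse is assigned to the single branch containing its edge;
    synapses on edges outside the branches' region are excluded (count
    reported in the frame's ``attrs["n_excluded"]``).
    """
    if not branches:
        raise ValueError("no branches supplied")
    region = branches[0].region
    edge_branch = branch_of_edges(tree, region)
    b = edge_branch[synapses.child_idx] if len(synapses) else np.empty(0, np.int64)
    excluded = int(np.sum(b < 0))
    counts = np.bincount(b[b >= 0], minlength=len(branches))
    lengths = np.array([br.length for br in branches])
    df = pd.DataFrame(
        {
            "branch_id": [br.branch_id for br in branches],
            "length_um": lengths,
            "synapse_count": counts,
            "density_per_um": counts / lengths,
        }
    )
    df.attrs["n_excluded"] = excluded
    return df


# ---------------------------------------------------------------------------
# Radial distribution and density maps
# ---------------------------------------------------------------------------

def radial_path_histogram(
    tree: NeuronTree, synapses: SynapseSet, bin_width: float
) -> pd.DataFrame:
    """Histogram of synapse counts over path distance from the soma center.

    Returns a frame with bin edges, counts, and the cumulative fraction of
    synapses within each bin's upper edge (so the fraction of synapses
    within any radius r is readable off the table, or use
    :func:`fraction_within_path_radius`).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    r = synapses.path_distances_from_soma()
    n_bins = max(1, int(np.ceil((r.max() if len(r) else bin_width) / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(r, bins=edges)
    cum = np.cumsum(counts) / max(len(r), 1)
    return pd.DataFrame(
        {
            "bin_lo_um": edges[:-1],
            "bin_hi_um": edges[1:],
            "count": counts,
            "cumulative_fraction": cum,
        }
    )


def fraction_within_path_radius(
    tree: NeuronTree, synapses: SynapseSet, r: float
) -> float:
    """Fraction of synapses within path distance r of the soma center."""
    d = synapses.path_distances_from_soma()
    return float(np.mean(d <= r)) if len(d) else 0.0


def density_map_2d(
    neurons: list[tuple[NeuronTree, SynapseSet]],
    alignment: str = "soma",
    bin_um: float = 10.0,
    extent: float = 400.0,
    pia_y: list[float] | None = None,
) -> DensityMap2D:
    """Mean 2D synapse density map across neurons.

    Synapse positions are projected onto the x–y plane and translated so
    that, per neuron, either the soma center (``alignment="soma"``) or the
    pia (``alignment="pia"``: x to the soma, y to the supplied per-neuron pia
    y-coordinate) sits at the origin.  Counts are binned on a common grid of
    ``bin_um`` µm square bins spanning ±extent, converted to synapses/µm²,
    and averaged across neurons.
    """
    if alignment not in ("soma", "pia"):
        raise ValueError(f"unknown alignment {alignment!r}")
    if alignment == "pia" and (pia_y is None or len(pia_y) != len(neurons)):
        raise ValueError("pia alignment requires one pia y-coordinate per neuron")
    edges = np.arange(-extent, extent + bin_um, bin_um)
    acc = np.zeros((len(edges) - 1, len(edges) - 1))
    for k, (tree, syn) in enumerate(neurons):
        xy = syn.xyz[:, :2].copy()
        soma = tree.soma_center
        xy[:, 0] -= soma[0]
        xy[:, 1] -= soma[1] if alignment == "soma" else pia_y[k]
        H, _, _ = np.histogram2d(xy[:, 0], xy[:, 1], bins=[edges, edges])
        acc += H / bin_um**2
    return DensityMap2D(
        x_edges=edges, y_edges=edges, density=acc / len(neurons), alignment=alignment
    )


# ---------------------------------------------------------------------------
# Kolmogorov–Smirnov test
# ---------------------------------------------------------------------------

def ks_two_sample(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov test.

    D is the exact supremum of |ECDF_x − ECDF_y| over the pooled sample; the
    p-value is from the asymptotic Kolmogorov distribution with effective
    sample size n_x·n_y/(n_x+n_y).  A warning is emitted when either sample
    is small (< 25), where the asymptotic p is approximate.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValueError("both samples must be nonempty")
    if min(nx, ny) < 25:
        warnings.warn("asymptotic KS p-value with n < 25 is approximate", stacklevel=2)
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / nx
    cdf_y = np.searchsorted(y, pooled, side="right") / ny
    D = float(np.max(np.abs(cdf_x - cdf_y)))
    en = nx * ny / (nx + ny)
    p = float(kolmogorov(np.sqrt(en) * D))
    return D, min(max(p, 0.0), 1.0)
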