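"""Monte Carlo null model: uniform redistribution of synapses on the arbor.

The null hypothesis is that synapses land uniformly at random over the
selected dendritic region.  It is simulated by "unrolling" the region onto a
line of length L = total path length, drawing n i.i.d. Uniform[0, L)
arclengths, and mapping them back onto the tree — so the per-branch null
count is Binomial(n, branch_length / L).

Ensembles of R replicates (default 1000) give per-branch 95% count
envelopes, null distributions of arbitrary statistics, and
observed-vs-null comparisons (fraction of branches outside the envelope,
KS tests of nearest-neighbor distances, clustering-coefficient curves).

Randomness is fully reproducible: replicate r of an ensemble with master
seed m uses the substream SeedSequence(m, spawn_key=(r,)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .morphology import Branch, NeuronTree, branch_of_edges, positions_from_arclengths
from .synapses import SynapseSet

__all__ = [
    "NullEnsemble",
    "redistribute_uniform",
    "simulate_ensemble",
    "branch_envelope",
    "fraction_outside_envelope",
    "null_statistic_distribution",
]


def _rng_for(master_seed: int, replicate: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(replicate),))
    )


def redistribute_uniform(
    tree: NeuronTree, region: str, n: int, rng: np.random.Generator
) -> SynapseSet:
    """One null draw: n synapses placed uniformly along the unrolled region
    and mapped back onto the tree."""
    if n < 0:
        raise ValueError("n must be >= 0")
    L = tree.total_length(region)
    if L <= 0:
        raise ValueError(f"region {region!r} has zero total length")
    s = rng.random(n) * L
    child_idx, offset = (
        positions_from_arclengths(tree, s, region)
        if n
        else (np.empty(0, np.int64), np.empty(0))
    )
    return SynapseSet(tree, child_idx, offset)


@dataclass
class NullEnsemble:
    """R uniform-redistribution replicates with reproducible substreams."""

    tree: NeuronTree
    region: str
    n_synapses: int
    master_seed: int
    replicates: list[SynapseSet]

    @property
    def R(self) -> int:
        return len(self.replicates)

    def replicate_seed(self, r: int) -> tuple[int, ...]:
        """Identifier of replicate r's substream."""
        return (self.master_seed, r)

    def branch_counts(self, branches: Sequence[Branch]) -> np.ndarray:
        """(R, n_branches) matrix of per-replicate synapse counts."""
        edge_branch = branch_of_edges(self.tree, self.region)
        out = np.empty((self.R, len(branches)), dtype=np.int64)
        for r, rep in enumerate(self.replicates):
            b = edge_branch[rep.child_idx]
            out[r] = np.bincount(b[b >= 0], minlength=len(branches))
        return out


def simulate_ensemble(
    tree: NeuronTree, region: str, n: int, R: int, master_seed: int
) -> NullEnsemble:
    """Simulate R independent uniform-null replicates of n synapses."""
    if R < 1:
        raise ValueError("R must be >= 1")
    reps = [
        redistribute_uniform(tree, region, n, _rng_for(master_seed, r))
        for r in range(R)
    ]
    return NullEnsemble(tree, region, n, int(master_seed), reps)


def branch_envelope(
    ensemble: NullEnsemble,
    branches: Sequence[Branch],
    level: float = 0.95,
    method: str = "empirical",
) -> pd.DataFrame:
    """Per-branch count envelope at confidence `level`.

    ``method="empirical"`` (default): nearest-rank quantiles at
    (1−level)/2 and (1+level)/2 of the replicate counts.
    ``method="binomial"``: exact Binomial(n, length/L) quantiles —
    equivalent in expectation, provided as a cross-check.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    lengths = np.array([b.length for b in branches])
    alpha = (1 - level) / 2
    if method == "empirical":
        counts = np.sort(ensemble.branch_counts(branches), axis=0)
        R = ensemble.R
        lo_rank = max(int(np.ceil(alpha * R)), 1) - 1  # nearest-rank, 1-indexed
        hi_rank = min(int(np.ceil((1 - alpha) * R)), R) - 1
        lower = counts[lo_rank]
        upper = counts[hi_rank]
    elif method == "binomial":
        L = ensemble.tree.total_length(ensemble.region)
        p = lengths / L
        lower = binom.ppf(alpha, ensemble.n_synapses, p).astype(np.int64)
        upper = binom.ppf(1 - alpha, ensemble.n_synapses, p).astype(np.int64)
    else:
        raise ValueError(f"unknown method {method!r}")
    return pd.DataFrame(
        {
            "branch_id": [b.branch_id for b in branches],
            "length_um": lengths,
            "lower_count": lower,
            "upper_count": upper,
        }
    )


def fraction_outside_envelope(
    observed: pd.DataFrame, envelope: pd.DataFrame
) -> float:
    """Share of branches whose observed synapse count falls outside
    [lower_count, upper_count] of the null envelope."""
    if not np.array_equal(
        observed["branch_id"].to_numpy(), envelope["branch_id"].to_numpy()
    ):
        raise ValueError("observed table and envelope cover different branches")
    c = observed["synapse_count"].to_numpy()
    outside = (c < envelope["lower_count"].to_numpy()) | (
        c > envelope["upper_count"].to_numpy()
    )
    return float(np.mean(outside))


def null_statistic_distribution(
    ensemble: NullEnsemble,
    statistic: Callable[[NeuronTree, SynapseSet], object],
) -> list:
    """Evaluate a pure statistic of (tree, synapse set) on every replicate.

    Returns the list of R values.  Array-valued statistics (e.g. per-synapse
    nearest-neighbor distances) can be pooled across replicates with
    :func:`pooled`.
    """
    return [statistic(ensemble.tree, rep) for rep in ensemble.replicates]


def pooled(values: list) -> np.ndarray:
    """Concatenate array-valued replicate statistics into one pooled sample."""
    return np.concatenate([np.atleast_1d(np.asarray(v, dtype=float)) for v in values])
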