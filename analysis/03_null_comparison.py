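"""Step 3 — compare each placement against the uniform-redistribution null.

Builds an R = 1000 null ensemble on the reference arbor, derives the 95%
per-branch count envelope, and for each placement reports the fraction of
branches outside the envelope and a KS test of nearest-neighbor distances
against the pooled null.  Uses the pipeline's report machinery via run
configs so the outputs are deterministic.
"""

import json
from pathlib import Path

import numpy as np

from synaptomap.morphology import branch_decomposition, read_swc
from synaptomap.null_model import (
    branch_envelope,
    fraction_outside_envelope,
    null_statistic_distribution,
    pooled,
    simulate_ensemble,
)
from synaptomap.spatial_stats import (
    branch_density_table,
    fraction_with_neighbor_within,
    ks_two_sample,
    nearest_neighbor_distances,
)
from synaptomap.synapses import read_synapse_csv

ROOT = Path(__file__).resolve().parent.parent
DATA, RESULTS = ROOT / "data", ROOT / "results"
PLACEMENTS = ["uniform", "clustered", "branch_biased"]
SEED, R = 0, 1000


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    tree = read_swc(DATA / "neuron.swc")
    branches = branch_decomposition(tree, "basal")
    ens = simulate_ensemble(tree, "basal", 328, R, master_seed=SEED)
    env = branch_envelope(ens, branches, level=0.95)
    env.to_csv(RESULTS / "null_envelope.csv", index=False)
    nn_pool = pooled(
        null_statistic_distribution(
            ens, lambda t, s: nearest_neighbor_distances(t, s).distances
        )
    )
    frac5_null = null_statistic_distribution(
        ens, lambda t, s: fraction_with_neighbor_within(t, s, 5.0)
    )

    summary = {
        "null": {
            "n_replicates": R,
            "nn_mean_um": round(float(np.mean(nn_pool)), 3),
            "fraction_within_5um_mean": round(float(np.mean(frac5_null)), 3),
        }
    }
    for name in PLACEMENTS:
        syn = read_synapse_csv(DATA / f"synapses_{name}.csv", tree)
        table = branch_density_table(tree, branches, syn)
        D, p = ks_two_sample(
            nearest_neighbor_distances(tree, syn).distances, nn_pool
        )
        summary[name] = {
            "fraction_branches_outside_envelope": round(
                fraction_outside_envelope(table, env), 3
            ),
            "ks_statistic": round(D, 4),
            "ks_p": float(f"{p:.4g}"),
        }
    (RESULTS / "null_comparison.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    for name in PLACEMENTS:
        s = summary[name]
        print(f"{name:14s} outside envelope {s['fraction_branches_outside_envelope']:.3f}  "
              f"KS D {s['ks_statistic']:.3f}  p {s['ks_p']:.3g}")


if __name__ == "__main__":
    main()
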