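"""Step 1 — generate the synthetic data used by the downstream analyses.

Writes to ``data/``: the reference arbor (SWC), three synapse placements
(uniform, clustered, branch-biased) as CSVs, and a labeled neuropil volume
with ground truth for the detection simulation.
"""

import json
from pathlib import Path

import numpy as np

from synaptomap.morphology import branch_decomposition, write_swc
from synaptomap.null_model import redistribute_uniform
from synaptomap.synapses import write_synapse_csv
from synaptomap.synthetic_data import (
    ClusterPlacementParams,
    VolumeGenParams,
    generate_labeled_volume,
    place_branch_biased,
    place_clustered,
    reference_neuron,
)

SEED = 0
DATA = Path(__file__).resolve().parent.parent / "data"


def main() -> None:
    DATA.mkdir(exist_ok=True)
    tree = reference_neuron(seed=SEED)
    write_swc(tree, DATA / "neuron.swc")

    uniform = redistribute_uniform(tree, "basal", 328, np.random.default_rng(SEED))
    write_synapse_csv(uniform, DATA / "synapses_uniform.csv")

    clustered = place_clustered(
        tree,
        "basal",
        ClusterPlacementParams(n=328, parent_intensity=0.01, sigma=2.0, seed=SEED),
    )
    write_synapse_csv(clustered, DATA / "synapses_clustered.csv")

    branches = branch_decomposition(tree, "basal")
    weights = np.where(np.arange(len(branches)) % 2 == 0, 4.0, 1.0)
    biased = place_branch_biased(
        tree, "basal", weights, 328, np.random.default_rng(SEED + 1)
    )
    write_synapse_csv(biased, DATA / "synapses_branch_biased.csv")

    vol = generate_labeled_volume(VolumeGenParams(seed=SEED))
    vol.save(DATA / "volume.tiff", DATA / "volume.json")

    manifest = {
        "seed": SEED,
        "basal_length_um": round(tree.total_length("basal"), 3),
        "n_branches": len(branches),
        "n_synapses": 328,
    }
    (DATA / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    print(f"wrote synthetic data to {DATA}")


if __name__ == "__main__":
    main()
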