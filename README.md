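# synaptomap

Spatial statistics of labeled synapses on dendritic arbors, with a
Monte Carlo uniform-redistribution null model and a simulation of
distance-based synapse-detection errors in volumetric light microscopy.

## The scientific problem

Large-scale correlative microscopy (e.g. array tomography combined with
genetically labeled presynaptic terminals) can map hundreds of synapses onto
a single reconstructed neuron. Two questions follow:

1. **Are the synapses arranged non-uniformly on the dendritic tree?**
   Apparent clusters arise by chance even under uniform placement, so every
   observed statistic must be compared against a null model in which the
   same number of synapses is redistributed uniformly along the arbor's
   total dendritic length. This package measures synapse arrangements with
   nearest-neighbor (NN) distances *along the dendrite* (the geodesic path
   metric, not straight-line distance), a proximity-graph clustering
   coefficient, per-branch densities against Monte Carlo envelopes, radial
   path-distance histograms, and 3D Sholl profiles.
2. **How often does distance-based synapse pairing go wrong?** When a
   labeled presynaptic structure is paired to the nearest postsynaptic spine
   within a distance `d`, any additional nearby structure can be paired
   falsely. If `n` structures lie within `d` of a spine and exactly one is
   the true partner, the false-positive probability is `(n − 1)/n`. The
   detection simulator evaluates this on labeled 3D volumes with known
   ground truth, as a function of the pairing distance (a proxy for imaging
   resolution).

All data are synthetic and generated programmatically: random dendritic
arbors (SWC), synapse placements (uniform, Neyman-Scott clustered,
branch-biased), and labeled neuropil volumes with ground-truth pairings.

## Worked example

```bash
python analysis/01_simulate_data.py        # arbor, placements, volume -> data/
python analysis/02_synapse_distribution.py # descriptive statistics -> results/
python analysis/03_null_comparison.py      # null ensemble + envelopes
python analysis/04_detection_accuracy.py   # FP-rate-vs-resolution curve
```

On the default seed this prints (values are exact reruns, everything is
deterministic given the seed):

```
uniform        NN mean   4.95 um  within 5 um 0.634
clustered      NN mean   0.52 um  within 5 um 0.994
branch_biased  NN mean   4.42 um  within 5 um 0.726

uniform        outside envelope 0.000  KS D 0.055  p 0.276
clustered      outside envelope 0.692  KS D 0.698  p 3.65e-139
branch_biased  outside envelope 0.288  KS D 0.131  p 2.44e-05

d = 0.20 um: mean FP rate 0.000 (20 spines)
d = 0.50 um: mean FP rate 0.217 (20 spines)
d = 1.00 um: mean FP rate 0.730 (20 spines)
```

The uniform placement is statistically indistinguishable from its own null;
the clustered placement is detected overwhelmingly by both the NN-distance
KS test and the branch envelope; and the false-positive rate of
distance-based pairing rises from 0 at high resolution to ~73% at a 1 µm
pairing distance.

The same computations are available through the CLI:

```bash
synaptomap simulate --out-dir data --seed 0 --placement clustered
synaptomap stats --swc data/neuron.swc --synapses data/synapses.csv --out results/
synaptomap null --swc data/neuron.swc --synapses data/synapses.csv \
    --replicates 1000 --out results/envelope.csv
synaptomap compare --config run.yaml   # full deterministic report bundle
synaptomap detect-sim --volume-tiff data/volume.tiff \
    --volume-json data/volume.json --out results/fp_curve.csv
```

## Layout

- `src/synaptomap/` — the library: `morphology` (SWC, path metric,
  arclength bijection, branches, Sholl), `spatial_stats`, `null_model`,
  `detection_sim`, `synthetic_data`, `pipeline`, `cli`.
- `analysis/` — numbered scripts reproducing the full analysis narrative.
- `scripts/acceptance.py` — one-shot recomputation of headline quantities.
- `tests/` — per-module suites with independent brute-force oracles
  (`tests/oracles.py`) plus the acceptance suite.
- `docs/methods.md` — model definitions, parameter rationale, and numerical
  choices.
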