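# Methods

This note defines the models and conventions implemented in `synaptomap`,
and records the rationale for every parameter default and numerical choice.
All distances are micrometers (µm) unless stated otherwise.

## Morphology model

A neuron is a rooted tree read from SWC. Each node carries an integer
structure type (1 soma, 2 axon, 3 basal dendrite, 4 apical dendrite). An
edge belongs to a *region* according to the type of its **child** node;
the named regions are `basal`, `apical`, `dendrites` (basal ∪ apical),
`axon`, and `all` (everything but soma-internal edges). Soma edges are
excluded from all dendritic analyses.

**Path metric.** The distance between two points on the tree is the length
of the unique path between them along the edges (geodesic distance), not
the Euclidean straight-line distance. Pairwise distances are computed via
an Euler-tour + sparse-table lowest-common-ancestor index; positions on the
same edge and ancestor–descendant positions are handled exactly. The
implementation is verified against Dijkstra shortest paths on graphs with
the query positions spliced in as explicit vertices.

**Arclength bijection ("unrolling").** The edges of a region, taken in a
canonical depth-first order (children visited in ascending node id), define
a bijection between the interval `[0, L)` (L = total region length) and
points on the arbor. This is the basis of the uniform null: drawing
`s ~ Uniform[0, L)` and mapping it back yields a uniformly distributed
point on the arbor, exactly and without rejection.

**Branch decomposition.** A branch is a maximal unbranched path between
"anchors": region roots (e.g. a stem leaving the soma), branch points
(nodes with ≥ 2 in-region children), and tips. For a binary tree with `k`
bifurcations and one stem this yields `2k + 1` branches; branch lengths sum
exactly to the region total.

**Sholl analysis.** For each radius `r` centered on the soma, the number of
crossings of the sphere of radius `r` by the arbor is counted per edge by
locating the monotone pieces of the squared-distance function along the
edge, with a half-open `(0, 1]` convention so that a node lying exactly on
the sphere is counted once. Radii are caller-supplied (the analysis scripts
use 25 µm steps); verified against dense 0.01 µm sampling.

## Spatial statistics

**Nearest-neighbor (NN) distances.** For each synapse, the path distance to
its nearest other synapse in the same set. Computed from the full pairwise
path-distance matrix — neighbors are sought across the whole region, not
just the same branch. Coincident synapses (distance 0) are legal but
trigger a warning. Requires ≥ 2 synapses.

**Fraction with a neighbor within d.** `P(NN ≤ d)`, i.e. the NN ECDF at
`d`; the analysis default `d = 5 µm` targets the scale of local clusters.

**Clustering coefficient.** Synapses are vertices of a proximity graph with
an edge whenever the path distance is ≤ `d`. The mean local clustering
coefficient averages `triangles / (deg·(deg−1)/2)` over vertices with
degree ≥ 2; if no vertex qualifies the value is NaN (undefined), not 0.
This convention keeps the `d → 0` and `d → diameter` limits exact (NaN and
1.0 respectively).

**Branch density table.** Synapse count and count/length for every branch
of the region; synapses on edges outside the region are excluded and
counted in `attrs["n_excluded"]`.

**Radial path histogram.** Histogram of path distance from the soma surface
(along the arbor) in fixed-width bins (default 25 µm), with the cumulative
fraction per bin.

**2D density maps.** Synapse positions are projected to the x–y plane,
aligned either to the soma (origin at the soma center) or to the pia (a
caller-supplied y-coordinate per neuron), binned in 10 µm bins over a
±400 µm extent, expressed as counts/bin-area and averaged over neurons.

**Two-sample KS test.** The statistic is the exact supremum of the ECDF
difference over the pooled sample; the p-value uses the asymptotic
Kolmogorov distribution with effective size `n·m/(n+m)` (cross-checked
against an independent implementation). A warning is emitted if either
sample has `n < 25`, where the asymptotic p-value is unreliable.

*Caveat (important):* NN distances within one point pattern are **not
independent** — mutual nearest neighbors contribute duplicated values, so
the effective sample is roughly `2n/3`. Applying an iid two-sample test to
such samples is anticonservative: under a true uniform null the measured
rejection rate at nominal α = 0.05 is ≈ 0.16–0.21 (reference arbor,
n = 328). The package implements the conventional test faithfully and
documents the inflation; the envelope-based branch test does not suffer
from this problem and is the calibrated alternative.

## Uniform-redistribution null model

For an observed set of `n` synapses on a region of total length `L`, a null
replicate redistributes `n` points uniformly on `[0, L)` via the arclength
bijection. An ensemble of `R = 1000` replicates (the analysis default;
enough to resolve 95% envelopes with ~±1 count of Monte Carlo noise) is
generated reproducibly: replicate `r` uses the independent substream
`np.random.SeedSequence(master_seed, spawn_key=(r,))`, so any subset of
replicates can be regenerated without the others.

**Branch envelopes.** For each branch, the `level = 0.95` central envelope
of null counts, by nearest-rank empirical quantiles (rank `⌈αR⌉` and
`⌈(1−α)R⌉`); a closed-form Binomial(n, ℓ/L) quantile method is available
as a cross-check (`method="binomial"`). The observed fraction of branches
outside the envelope is the headline branch-level statistic; under the
null it is ≤ 0.05 by construction (discreteness makes it conservative;
measured ≈ 0.03).

## Detection simulation

**Labeled volumes.** Two `int32` label volumes over the same anisotropic
voxel grid — postsynaptic spine heads and presynaptic vesicle clouds — plus
a ground-truth map from each spine id to its true partner cloud ids (empty
list = no partner). Serialized as a stacked TIFF plus a JSON sidecar.

**Distances.** Physical distances between structures use the anisotropic
Euclidean distance transform (`scipy.ndimage.distance_transform_edt` with
voxel `sampling`), verified against an `O(N²)` brute force. For each spine,
the per-cloud minimum distance is read off the EDT of that spine's mask.

**False-positive model.** If `n ≥ 1` clouds lie within the pairing distance
`d` of a spine and exactly one is the true partner, picking one yields a
false positive with probability `p = (n − 1)/n`. `fp_rate_curve` averages
`p` over all spines with `n ≥ 1` (spines with no cloud within `d` are
excluded and reported), as a function of `d` — larger `d` stands in for
poorer effective resolution.

**Synthetic image rendering.** A three-channel volumetric image:
red = presynaptic label, green = postsynaptic label, blue = presynaptic
label with an intensity gradient toward the associated spine. Because the
generator does not model bouton cytosol separately from vesicle clouds, the
red channel is rendered from the cloud support. Rendering applies (i)
random *sparsification* — only a fraction of structures (default 0.1) is
retained, mimicking sparse labeling where ~90% of structures lack the
label, (ii) Gaussian blur with a physical `psf_sigma` (µm, converted per
axis), and (iii) block-mean downsampling to a target pixel size (ceiling
blocks at the boundary). Channels are clipped to `[0, 1]` without
re-normalization so that blur conserves total intensity (testable).

## Synthetic data generators

**Arbor generator.** Dendrites grow from the soma in fixed steps (default
5 µm, small enough that segment chords approximate smooth curvature) with
direction jitter; segment lengths are Normal(60, 25) µm truncated positive,
and each completed segment bifurcates with probability 0.5, matching
reported mean segment counts and lengths of layer-5 basal trees. Growth
stops when the target total length (default 4.7 mm, a typical total
dendritic length for such cells) is reached. The default split is 70%
basal (5 stems) / 30% apical — the basal/apical ratio is a package choice;
all shipped analyses use the basal region only. `reference_neuron(seed)`
returns the default-parameter arbor.

**Synapse placements.** `n = 328` synapses by default (a typical per-neuron
count for a labeled long-range projection).
*Uniform:* the null generator itself.
*Clustered:* a Neyman–Scott process on the arclength interval — Poisson
parents (default intensity 0.01/µm, i.e. sparse parents ~100 µm apart)
with Normal(0, σ = 2 µm) offsets, reflected into `[0, L)`; exactly `n`
offspring are kept.
*Branch-biased:* branch weights (relative density multipliers) define
per-branch probabilities ∝ weight × length; within a branch, placement is
uniform.

**Labeled volume generator.** Default grid 40×64×64 voxels at
(0.2, 0.1, 0.1) µm spacing (axial coarser than lateral, as in optical
sectioning). Spine heads are non-overlapping spheres (radius 0.25 µm, a
typical spine-head radius); each gets a true partner cloud touching it
(association probability default 1.0), and distractor clouds are placed as
a Poisson process (default 0.3/µm³, neuropil-like crowding) at least
`min_gap = 0.3 µm` clear of spines. Packing failures raise an error that
names the requested density rather than looping forever.

## Determinism

Every stochastic routine takes an explicit seed or `numpy` Generator.
Report bundles (`pipeline.run_analysis`, the CLI `compare` command) are a
pure function of (input files, config, master seed): reruns are
byte-identical, floats are rounded to 6 decimals in JSON, CSV column order
is fixed, and input files are fingerprinted with SHA-256 in the summary.

## Known limitations

- The KS-on-NN-distances calibration issue described above: use the branch
  envelope when a calibrated test is required.
- The p-value of the KS test is asymptotic; exact small-sample p-values are
  out of scope (a warning is raised below n = 25).
- The arbor generator produces statistically plausible trees, not
  reconstructions of any real cell; tapering, spine necks, and boutons are
  not modeled.
- 2D density maps average over neurons on a fixed grid; no smoothing or
  registration beyond soma/pia alignment is applied.
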