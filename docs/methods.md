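# Methods

This note documents the statistical model behind `bamscope`, the
assumptions baked into each stage, the parameters that matter, and what
the synthetic-data generator does and does not emulate.

## The measurement model

A screening run images each larva's brain for 10 min before and 15 min
after compound perfusion, at two z-planes. The recorded fluorescence of a
calcium reporter is a proxy for neuronal firing; the analysis reduces it
to *calcium-transient counts* per region of interest (ROI).

**ROI meshing.** Each plane is tiled into square ROIs of 15.21 µm²
(`mesh_rois`). The ROI area must map to an integer pixel block given the
sensor's pixel area; otherwise the nearest valid area is suggested rather
than silently resampling. ROI traces are plain block means per frame.

**Transient detection.** Each epoch's trace is baselined by its own mean
F₀ (a rolling-percentile baseline is deliberately not the default: epochs
are short and drift is removed by filtering), converted to ΔF/F, and
high-pass filtered at 0.2 Hz with a zero-phase second-order Butterworth
filter (forward–backward, so no phase distortion of event onsets).
Events are upward crossings of the threshold mean + 2 SD of the ΔF/F
curve, with a 1 s refractory period separating distinct events. Threshold
counting is deliberately simple — no deconvolution or spike inference —
and is exact for well-separated, high-SNR transients; on noisy traces it
is a noisy but unbiased-rate estimator, which is why everything
downstream works with replicate statistics rather than single counts.

**Registration.** Count maps are aligned to a common brain template by a
similarity transform (rotation ± 20°, final step 0.5°; translation;
isotropic scale estimated from foreground areas) found by coarse-to-fine
grid search. The objective combines template-mask overlap with left–right
mirror correlation about the template midline, reflecting the bilateral
symmetry of the larval brain; the brain midline is the registration
landmark. Foreground is separated from background by Otsu's threshold.
Eye-region ROIs are removed after alignment. If no candidate improves on
the identity, the identity is returned with a warning rather than a
spurious transform.

**BAM.** The brain activity map is the per-ROI
change in transient counts, post minus pre, summed over z-planes:
`a_ij = Σ_k (c¹_ijk − c⁰_ijk)`. Because the pre epoch is 10 min and the
post epoch 15 min, raw counts are not directly comparable; counts are
first rate-normalised to a common 10-min reference (scaled and rounded to
the nearest integer) before differencing. This is configurable
(`normalize_rates=False` recovers the raw difference) and is logged as a
protocol decision: with equal epochs the two definitions coincide
exactly. BAM entries are therefore signed integers.

**T-score BAM.** Per ROI, the one-sample T statistic across the n = 5
biological replicates: `t_ij = ā_ij / (s_ij/√n)`, with the sample SD
(ddof = 1). T-scores make replicate-inconsistent changes small regardless
of their raw magnitude.

*Variance floor.* With only 5 integer-valued replicates, the sample SD is
occasionally near zero by chance (χ²₄ sampling plus rounding), which
would turn single ROIs into |t| spikes of 10³–10⁴ that dominate every
Euclidean distance and the PCA basis. A count difference carries
irreducible Poisson counting noise — Var(a) ≈ c⁰ + c¹, so SD ≳ 1.4
whenever any transients occur — and sample SDs below that scale are
underestimates. The denominator SD is therefore floored at
`sd_floor = 1.5` counts (applied as max(s, floor) to every ROI), capping
|t| at ~1.5·√n·|ā|, on the same scale as genuine T values. The floor is
configurable; `sd_floor=0` gives the raw statistic. Consequence: exact
scale invariance of t under rescaling of all replicates holds wherever
the SD exceeds the floor (true of any positive floor).

## Pheno-Prints

PCA is fitted once, on the template-masked, flattened T-score maps of the
training library, with mean-centring only — T-scores are already unitless
and share a scale, so per-ROI standardisation would only amplify empty
regions. The top 20 components define the basis; every map (training and
test alike) is projected onto it to give its Pheno-Print. Raw
coefficients are used (no scaling by explained variance) so Euclidean
distances in Pheno-Print space equal distances between denoised maps.
The decomposition is an exact SVD (deterministic at this scale), with the
sign of each loading fixed so its largest-magnitude entry is positive,
making fingerprints reproducible across platforms. A library with fewer
maps than components, or zero variance, is rejected with a clear error.

## Consensus clustering and choosing k

Each of `n_iterations` (default 1000) rounds subsamples 80 % of the
drugs without replacement (a with-replacement mode exists), clusters them
by average-linkage hierarchical clustering on Euclidean Pheno-Print
distance, and cuts the tree at every candidate k (default 2–15). The
consensus matrix entry M_k[i,j] is the fraction of co-sampled iterations
in which i and j co-clustered; pairs never co-sampled get 0 with a
warning. Distance and linkage are configurable; average linkage and
Euclidean distance are the defaults.

k is selected by the consensus-CDF criterion: compute the area under the
empirical CDF of the off-diagonal consensus entries (exact integral of
the step ECDF over [0, 1], left endpoints — mass at consensus 1
contributes no area) and take the smallest k whose relative AUC gain to
k+1 falls below 1 %. If no k qualifies, the largest candidate is returned
with a warning. The granularity of this rule is ~(cluster size)/(number
of drug pairs): clusters must contain enough drugs that splitting one
moves less than 1 % of pairs, which holds comfortably at the default
library scale (~18 drugs per cluster of 179).

Final labels come from cutting an average-linkage tree on the distance
1 − M_k. Per-cluster representative patterns are elementwise means of
in-cluster T-score maps.

**Coherence tests.** For each drug, a one-tailed Mann–Whitney rank test
compares its consensus scores with in-cluster vs out-of-cluster drugs
(in > out), with Benjamini–Hochberg adjustment across drugs. The groups
are unavoidably of unequal size, which a paired signed-rank test cannot
accommodate; a paired Wilcoxon variant is available when groups are
equalised by subsampling (`equalize_groups=True`). A second variant runs
the same comparison on Pheno-Print distances (in < out). Drugs in
singleton clusters get a missing p-value and a log message.

## ATC association and signature subgroups

For every (cluster, category) pair: p = P(X ≥ k) with
X ~ Hypergeometric(N, K, n), where N is the training population, K the
category size, n the cluster size, k the overlap. Categories are ATC
level-2 codes. Drugs holding several codes count once toward each
category they hold (configurable to primary-code-only); the association
grid is small (10 × 7), so significance is nominal at α = 0.05 with a
BH-adjusted column emitted alongside for reference. A significant overlap
defines the signature subgroup; its Pheno-Print centroid (componentwise
mean) anchors candidate ranking. Note the discrete tail makes the test
conservative: the attainable type-I rate is at or below the nominal α,
which the test suite checks against the exact attainable level rather
than α itself.

## Functional prediction

A random forest (100 trees, √p features per split, bootstrap per tree,
fixed seed, out-of-bag accuracy reported) is trained on training
Pheno-Prints and consensus labels, then assigns each test compound by
majority vote. Vote ties break toward the lowest cluster label and are
logged. Compounds landing in ATC-associated clusters receive a
therapeutic-potential score r = Pearson correlation across the 20 PC
coefficients between the compound's Pheno-Print and the signature
centroid, and are ranked within the cluster (missing scores — e.g. a
zero-variance fingerprint — rank last). Compounds in non-associated
clusters are assigned but unscored.

## The synthetic-data generator

The generator emulates the *statistical structure* of the screen, not its
optics:

- **Cluster effect templates** are smooth, signed, left–right
  mirror-symmetric maps built from 3–5 contiguous blocks (full-width
  anterior/posterior bands and lateralised mirrored patch pairs),
  mimicking region-patterned drug effects (e.g. forebrain excitation with
  broad suppression elsewhere). Templates are rejection-sampled to
  pairwise Pearson correlation < 0.5, and normalised so the mean |value|
  over the affected region is 1 — making `effect_amplitude` exactly the
  mean absolute transient-count change where the drug acts.
- **Libraries**: each drug's personal effect map is
  template × `effect_amplitude` (default 8 counts) plus a per-ROI
  drug-specific offset (SD 0.25 × amplitude); each replicate adds
  acquisition noise (SD 0.5 × amplitude) and is rounded to integers.
  Defaults: 179 training drugs in 10 clusters, 121 test compounds drawn
  from the same clusters, 5 replicates each, 50 signal-free DMSO
  replicates. Amplitude and noise defaults are calibration constants of
  the scenario: they are chosen so that the planted structure is
  recoverable at study scale (k = 10 selected, ARI 1.0, top-20 PCs ≈ 70 %
  of variance), and they stay fixed across all tests.
- **ATC links**: each cluster is linked to one of 7 level-2 categories;
  a training drug receives its cluster's category with probability
  `atc_purity` (default 0.6), otherwise a uniformly random other
  category. Purity 1/n_categories makes labels independent of clusters
  (the null used in calibration tests).
- **Movies** (`simulate_movie`): per-ROI inhomogeneous Poisson events
  (baseline rate pre; baseline + template rate post, clipped at 0 with a
  log message), convolved with a 0.1 s-rise / 1 s-decay kernel, plus a
  < 0.05 Hz sinusoidal illumination drift and white noise; planted event
  times are returned as ground truth. Movies are rendered per-ROI, not
  per-neuron: single-cell morphology, motion artifacts and anatomically
  realistic atlases are out of scope.

Because all replicate variation is Gaussian-on-integer rather than
biological, passing tests demonstrate that the *pipeline* recovers
planted structure under the stated noise model — not that real BAM data
have this structure. Heavy-tailed replicate T statistics, however, are a
genuine feature shared with real few-replicate data, which is why the
variance floor matters beyond simulation.

## Determinism and problem sizes

Every source of randomness flows through explicit integer seeds; the
pipeline derives per-stage seeds from one master seed by hashing the
stage name, so stages are individually reproducible and two runs with the
same configuration are bit-identical. The test suite runs the full
default-scale scenario once (179 drugs, 250 consensus resamples — the
plateau decision is unchanged between 250 and 1000 resamples, which the
calibration checks exploit) and smaller scenarios (24×16 grids, 36–100
drugs) for unit-level properties; `scripts/acceptance.py` uses the full
1000 resamples.

## Known limitations

- Registration is 2-D similarity only; 3-D atlas registration and motion
  correction are out of scope.
- Transient counting is threshold-based; overlapping events within a
  refractory period merge, and near-threshold noise can add or drop
  events on low-SNR traces.
- The <1 % plateau rule needs clusters of ≳ (1 % of pairs) drugs; on very
  small libraries it over-segments deterministically.
- The hypergeometric test treats drugs as exchangeable; correlated ATC
  codes (multi-label drugs) make K values non-independent across
  categories.
- Single-dose, single-time-point screens only; no dose–response
  modelling.
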