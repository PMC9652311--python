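# Methods

This note documents the models and procedures `coalt` implements, the
parameters that matter, what the synthetic-data generator does and does not
emulate, and the numerical choices made where the design was genuinely open.

## Co-alteration matrix and hubs

The input is a parcels × disorders table of Cohen's d values on a fixed
bilateral parcellation (68 Desikan-Killiany-sized parcels by default). The
co-alteration matrix correlates parcel *profiles across disorders*:
`R(i,j) = corr(d_i, d_j)` over the ≥3 disorder values. Two consequences
worth keeping in mind:

* only disorder-to-disorder *variation* creates structure — a pattern loaded
  equally by every disorder contributes nothing to R;
* with six disorders each correlation rests on six observations, so R is
  heavy-tailed; this mirrors the real analysis setting, not a limitation of
  the implementation.

Missing values are excluded pairwise; a constant parcel profile yields NA
with a warning. A weighted Pearson option (weights ∝ total n per disorder)
supports sample-size-corrected sensitivity analyses; it is off by default.

**Thresholding.** `threshold_matrix(scope="global")` ranks the upper-triangle
entries by signed value and keeps the top `ceil((1−sparsity)·n_edges)`,
zeroing symmetrically; ties break by (value, then lower label index), so the
operation is deterministic and idempotent. "Strong connections" therefore
means strongly *positive* covariance: large negative correlations are
dropped, not kept. Hub degree is the per-parcel sum of retained edge weights
(`weighted_sum`, default) or the retained-edge count (`binary_count`); the
default matches the covariance-network convention of summing supra-threshold
connections. Hub mapping thresholds globally; the gradient stage thresholds
row-wise (below) — the two conventions are deliberately distinct and both
exposed.

**Hit map.** Each disorder map is z-scored across parcels (sample s.d.) and
summed. `part="reductions"` zeroes positive d values before z-scoring;
`part="increases"` is the mirror image. z-scoring is the minimal reading of
"normalized" that puts disorders with different effect-size scales on an
equal footing.

## Spin tests

Significance of every map–map correlation comes from spherical rotation
nulls. Each spin draws one uniform random rotation (scipy's `Rotation.random`),
applies it to left-hemisphere centroids and the x-mirrored rotation to
right-hemisphere centroids, and reassigns each parcel the value of its
nearest original centroid within the same hemisphere (great-circle distance;
duplicates allowed, no bijection enforced — the standard parcel-level
convention). p-values use the add-one rule `p = (1+k)/(1+n)`, two-sided on
|r| by default; subcortical values are never spun (the null always rotates
the cortical map side).

Defaults: 1000 spins (p-floor ≈ 0.001); use ≥10000 when bounds near 1e-4
must be resolved.

Parcel-level spins with duplication are known to be mildly anticonservative
at coarse parcellations; at the package's study conditions the measured
type-I error at α = 0.05 is ≈ 0.046–0.06 (see the acceptance suite), within
the band expected for this method family. Two geometric facts shaped the
generator (next section) and are worth stating because they apply to real
data too: a rotation is a closed isometry only of a full sphere, and any map
component that is invariant under within-hemisphere rotation — notably a
hemisphere-mean offset — is a component the spin null can never explore.

## Synthetic data

The generator emulates the *statistical shape* of the real study inputs:

* **Atlas.** Each hemisphere's centroids are a Fibonacci lattice covering a
  full unit sphere (the registration-sphere geometry spin tests are defined
  on); the right hemisphere mirrors the left (x → −x). Cytoarchitectonic
  classes are latitude bands, five per hemisphere. The construction is
  deterministic.
* **Effect maps.** Two fixed latent spatial patterns (the anterior–posterior
  and inferior–superior coordinate harmonics, z-scored) times a per-disorder
  loading matrix, plus spatially autocorrelated noise. The default loadings
  give the first three disorders (SCZ/BD/OCD-like) strong weights on latent
  1 and the rest weights on latent 2, planting the shared-block structure the
  clustering and embedding stages should recover. Sample sizes default to the
  published ENIGMA cohort sizes.
* **Noise.** White noise smoothed with a von-Mises-like kernel
  `exp((cos Δ − 1)/ℓ²)` on great-circle distance, independently per
  hemisphere, then standardized within hemisphere. Per-hemisphere
  standardization removes the rotation-invariant hemisphere-contrast
  component (see above); standardized effect maps carry no meaningful
  hemisphere offset anyway. The angular scale ℓ defaults to 0.3 rad,
  chosen in pre-registered calibration runs as a scale at which maps are
  clearly autocorrelated at the parcel level (Moran ≈ 0.18 on a
  nearest-neighbour kernel) while the spin null remains honest (marginal
  type-I ≈ 0.046 at α = 0.05 over 2500 fresh-ensemble replicates).
* **Connectome.** A smooth distance-kernel baseline scaled so row sums track
  the hub target, with each planted epicenter's row/column replaced by a
  positively rescaled copy of the hub map plus noise (`conn_noise_sd`,
  default 0.1). 14 subcortical seed profiles are built the same way, two of
  them planted. With zero noise and a single planted seed the epicenter
  correlation is exactly 1 by construction.
* **Annotations.** 24 term maps with Gaussian response profiles whose peaks
  march monotonically along the target gradient's rank; an expression table
  whose first `n_signal_genes` (default 20 of 500) genes correlate with the
  gradient at ≈ `signal_r` (default 0.8), the rest being autocorrelated
  noise; brain-expressed flags cover all signal genes plus half the rest.

What the generator does **not** emulate: subject-level thickness, site and
scanner effects, parcel-size heterogeneity, distance-dependent connectivity
artefacts, realistic gene–gene coexpression modules, or any asymmetry
between hemispheres. Passing tests therefore demonstrate that the pipeline
recovers planted structure of the assumed form under honest spatial nulls —
not that the biological conclusions drawn from any particular real dataset
are correct.

The two-block preset (`two_block_config`) replaces latent 1 by a binary
anterior/posterior split and gives all disorders sign-alternating loadings
on it (recall that only cross-disorder loading variation creates
covariance); the principal gradient of the resulting co-alteration matrix
must separate the two parcel blocks.

## Gradients

The co-alteration matrix is row-thresholded (each row keeps its top 20%),
mapped through the normalized-angle kernel
`1 − arccos(cosine(row_i, row_j))/π`, and decomposed by diffusion map
embedding: density-normalize `W' = D^{−α} W D^{−α}` with α = 0.5, form the
Markov operator, and eigendecompose via the symmetric conjugate
`D'^{−1/2} W' D'^{−1/2}` (dense `scipy.linalg.eigh`; n = 68 needs no
iterative solver). The trivial stationary component is dropped; under the
diffusion-time-zero rule each component is scaled by λ/(1−λ) (plain
eigenvectors available via `scale_by_lambda=False`). Variance explained is
λᵢ/Σλ over the retained nontrivial eigenvalues (the denominator convention
is documented here because "retained vs full spectrum" is a genuine choice;
fractions are reported over the `n_components` kept, default 10, with
negative tail eigenvalues clipped at zero).

Component sign is arbitrary in any eigendecomposition; `coalt` fixes it
deterministically — against an anchor map when provided (the pipeline uses
the anterior–posterior centroid coordinate), otherwise by making the
largest-magnitude loading positive — and records the convention. Eigenvalue
gaps below 1e-10 are flagged as degenerate in the result and manifest.

`bin_gradient` uses rank-based quantile bins (ties to the lower bin), so
binning is invariant to monotone transforms; with 68 parcels and 20 bins the
bin sizes are 3–4. Leave-one-disorder-out stability recomputes the matrix
and embedding per exclusion and reports |r| against the full-sample G1/G2
after sign alignment.

## Decoding

* **Cytoarchitecture:** descriptive per-class distributions (n, mean, sd,
  median, range) of a gradient over the five von Economo-Koskinas classes;
  no inferential statistic is attached.
* **Terms:** bin-wise mean z per term; center of gravity
  `cog(t) = Σ_b b·max(z̄(b,t),0) / Σ_b max(z̄(b,t),0)` over the 20 bins,
  using the positive part as weights so centers stay inside [1, n_bins];
  terms with no positive association get NA. The ROI–term statistic is the
  mean parcel z within the bin (the simplest faithful reading; a one-sample
  z variant would be a drop-in replacement). The 2-D variant reports each
  term's (cog along G1, cog along G2).
* **Genes:** per-gene Pearson r with the gradient; spatial specificity from
  spin surrogates of the *gradient* (two-sided, add-one), candidate set at
  `p_spatial < 0.01`; set statistic = mean |r| over the set. Gene
  specificity: (i) the null-coexpressed model samples `n_null_sets` random
  sets matching the candidate set's decile histogram of mean absolute
  coexpression — the construction is checked per run and a warning is
  raised when the candidate set sits so deep in the coexpression tail that
  decile matching cannot track its level; (ii) the null-brain model samples
  uniformly from brain-expressed genes. Both set p-values are one-sided
  (greater), add-one. Two-sided spatial p at the 0.01 cut matches the
  convention used for all other spin tests in the package.

## Disorder embedding

Within-disorder covariance is `S(i,j) = −|d_i − d_j|` (inverting difference
scores by negation; any monotone inversion is rank-equivalent, and the
coupling correlations are affine-invariant, so the choice is immaterial and
documented). Coupling maps correlate row i of S with row i of the
transdiagnostic matrix, excluding entry i. Cross-disorder similarity is the
disorder × disorder correlation of effect maps, clustered agglomeratively
(average linkage on 1 − r; complete linkage available) and cut at k = 2;
cluster labels are renumbered by smallest member index so runs are
reproducible. Disorder positions report the hub-map correlation (+ spin p),
G1/G2 correlations (+ spin p), and epicenter overlap in percent with the
number of significant transdiagnostic epicenters as denominator (Jaccard
available); when either epicenter set is empty the overlap is 0 and a flag
says which set was empty.

## Numerical conventions and degenerate inputs

* Correlations are pairwise-complete; fewer than 10 complete pairs is an
  error, constant vectors give NA.
* All tie-breaks (edge ranking, epicenter ranking, bin assignment, cluster
  labels) are deterministic and documented at the operation.
* Every random stage takes an explicit seed; identical (config, seed) gives
  bitwise-identical output.
* Tables are tab-separated with canonical FreeSurfer-style parcel labels
  (`lh_*`/`rh_*`); the ENIGMA/HCP `L_*`/`R_*` dialect is normalized on load.
  Maps with more than 10% missing parcels abort.

## Problem sizes

The test and acceptance suites run entirely on synthetic data at the study's
native scale (68 parcels, 6 disorders, 14 subcortical seeds, 24 terms,
500 genes, 1000 spins). Monte-Carlo recovery and calibration checks use
10–100 generator seeds and 500 null map pairs; these sizes give binomial
standard errors small enough for the stated acceptance bands while keeping
a full run in well under a minute on one CPU.

## Known limitations

* Spin nulls at 34 parcels per hemisphere are only approximately calibrated
  (measured type-I ≈ 0.05–0.06 at α = 0.05); bijective or variogram-matched
  surrogates are out of scope.
* The co-alteration matrix with six disorders is statistically coarse by
  construction; gradients beyond G2 are not meaningful at this sample size.
* The coexpression-matched gene null matches decile histograms, not the
  full coexpression spectrum; candidate sets in the extreme tail are
  flagged rather than matched exactly.
* Variance-explained fractions depend on the number of retained components;
  comparisons across analyses must hold `n_components` fixed.
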