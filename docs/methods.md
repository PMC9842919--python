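# Methods

## The model

The package studies the dependence of DTI scalar indices on intracranial
volume (ICV), sex, and age with a single-equation linear model per response
(a tract's mean FA or volume, or a voxel on the white-matter skeleton):

    y_i = b0 + b_ICV (ICV_i − ICV̄) + b_age (age_i − agē) + b_sex F_i + e_i

with `F_i = 1` for women (so `b_sex` is the women − men contrast throughout)
and `e_i ~ N(0, s²)`. Continuous covariates are mean-centered; centering
changes only the intercept, and the test suite asserts the invariance of
slopes, t, p, and partial η² numerically. Interaction terms (ICV×sex,
ICV×age, ICV×sex×age) can be screened first: the full model is fitted, the
interaction p-values are BH-corrected as one family, and interactions that
do not survive are dropped.

The synthetic cohort generator is exactly this model run forward, which
makes the estimator/generator pair self-checking: on noiseless data OLS
returns the generating coefficients to numerical precision, and at realistic
noise the estimates land within sampling error of them.

### Default parameters

| parameter | default | unit | origin |
|---|---|---|---|
| ICV, men | 1667.9 ± 120.2 | ml | population summary for 50–66 y cohort |
| ICV, women | 1455.9 ± 115.8 | ml | same |
| age | uniform on [50, 66] | years | narrow early-aging band; exact shape unspecified, uniform chosen |
| `beta_icv` | 4.7 × 10⁻⁵ | FA/ml | voxelwise FA–ICV slope, read as per-mm³ and converted to per-ml (≈ 0.03 FA across the cohort ICV range) |
| `beta_age` | −3.0 × 10⁻⁴ | FA/yr | corpus-callosum tract-level age slope, used as the representative magnitude for all tracts |
| `sex_offset` | +0.004 | FA | order of the reported CC FA sex difference (0.361 vs 0.359) |
| `noise_sd` | 0.011 | FA | typical within-group tract FA SD |
| tract baselines | per-tract, 0.31–0.39 | FA | men's tract means |

The ICV/age slope scales in the source voxelwise analyses are not stated
with units, so both are free parameters of `CohortSpec`; the defaults above
are the declared reading, not an assertion of intent.

## Diffusion metrics

The tensor is fitted per voxel by log-linear least squares on
`log S = log S0 − b gᵀ D g` (no weighting, no outlier rejection), requiring
≥ 6 non-collinear b > 0 directions and ≥ 1 b = 0 volume. Eigenvalues are
sorted descending and the indices use the standard formulas; `MD = (AD +
2·RD)/3` holds identically and is asserted voxelwise. Degenerate all-zero
tensors get FA = 0 rather than NaN so background voxels cannot poison
skeleton statistics; FA is clipped to [0, 1] because noisy fits can produce
negative eigenvalues.

The skeleton machinery is deliberately registration-free: the skeleton is
either supplied as a mask or built from a mean-FA map by a discrete ridge
test (voxel ≥ 0.2 FA and a local maximum along the direction of strongest
downward curvature of the smoothed FA surface). Projection then carries the
maximum FA found within ±5 voxels along that perpendicular direction onto
each skeleton voxel, which reproduces the projection contract of
skeleton-based voxelwise analyses without template registration. Projected
maps are idempotent under re-projection.

Head motion is summarized by the scan-to-scan RMS displacement of points on
a sphere of radius R (default 80 mm, a standard head approximation — the
source framework leaves R open): with `M = T1 T0⁻¹ − I`,
`rms = sqrt(R²/5 · tr(AᵀA) + tᵀt)`. The per-subject `rms_mean` averages
over the diffusion-weighted volumes only, following the reading that b = 0
volumes are excluded.

## Bundle clustering

Streamlines are resampled to 25 equal-arc-length points. The pairwise
distance is the corresponding-point mean Euclidean distance minimized over
the two point orderings — flip-invariant, symmetric, cheap on fixed-length
curves. (Mean-closest-point distances are a known alternative; the
corresponding-point form is fixed here and declared, not inferred.)

Clustering is Ward agglomeration on the precomputed distance matrix,
treating distances as Euclidean: the Lance–Williams recurrence on squared
distances. This is the standard accommodation when items are not vectors.
Exact merge ties break toward the lexicographically lowest cluster pair, so
the merge sequence is fully deterministic; the implementation is verified
merge-for-merge against a naive O(n³) agglomerator that recomputes the
within-cluster sum-of-squares increase directly from point clouds, and
against scipy's Ward linkage on Euclidean data.

Population-scale runs cluster random subsets: the pooled streamlines are
partitioned into subsets (population-scale 10,000; desk-scale tests use a few
hundred), each subset is cut at k clusters, and each subset's labels are
matched to a global reference (the first subset of the first repetition) by
Hungarian assignment on flip-aligned mean streamlines per cluster. The whole
step repeats with fresh random partitions (population-scale 100, desk-scale 10);
a streamline's consensus label is its modal label and its stability the
agreement fraction. Tract extraction keeps streamlines in a tract's label
set with stability ≥ 0.5 by default — majority agreement as the natural
pruning cut where no threshold is prescribed.

In the end-to-end pipeline, tract label sets are derived automatically by
majority ground-truth composition of each consensus cluster. This is a
stand-in for the manual cluster-to-tract curation a human would perform on
real data, and is only valid because the phantom's ground truth is known.

## Tract metrics

A tract ROI marks every voxel visited by at least one streamline sample,
with segments supersampled at 0.25 × the smallest voxel dimension and a
half-open voxel-box convention (`index = floor(voxel_coord + 0.5)`), so
boundary membership is unambiguous. Tract volume is voxel count × voxel
volume — deliberately the literal definition, which reflects voxels reached
by tracking rather than the anatomical pathway volume. Tract FA is the
arithmetic mean over the ROI; an empty ROI is an error and the subject/tract
is excluded case-wise. Note the sampling definition: a segment grazing a
voxel corner between two samples can miss that voxel; at the default step
this affects a few percent of surface voxels (the tests compare against a
0.01 mm dense pass).

## Statistics

**Matching.** ICV-matched man/woman pairs (|ΔICV| < 10 ml) are found by
rectangular assignment: compatible pairs cost their |ΔICV|, incompatible
pairs a penalty exceeding any feasible total, so the solution maximizes the
pair count first and then minimizes the total ICV discrepancy. A greedy
nearest-available sweep was considered and rejected: it is not
cardinality-optimal (small counterexamples exist), which the assignment
formulation guarantees — the tests verify cardinality against brute-force
bipartite matching on hundreds of random instances. One caveat: with group
ICV distributions ~212 ml apart, any cardinality-maximal matching must
stretch pairs at the edges of the overlap region, all in the same direction,
leaving a residual matched-group difference of ~1–2 ml (pooled |t| ≈
0.1–0.2 at realistic group sizes) rather than exactly zero.

**Permutation inference.** Freedman–Lane: the reduced model (without the
term under test) is fitted, its residuals are row-permuted, and the
full-model t for the term is recomputed per unit. Family-wise correction
uses the null distribution of the maximum statistic over units, either the
raw |t| (`maxstat`) or TFCE-enhanced |t|; both are two-sided via the
absolute map. Corrected p = (1 + #{perm ≥ observed})/(n_perm + 1), so the
attainable floor is 1/(n_perm + 1). The implementation exploits two
identities for speed: adding back the nuisance fit changes neither the
term's coefficient nor the residual sum of squares (so only residuals need
permuting), and the total sum of squares is permutation-invariant. The
family-wise error rate under pure noise is calibrated by simulation in the
acceptance suite (within [0.02, 0.08] at α = 0.05).

**TFCE.** `sum_h extent(h)^E · h^H · dh` with the standard H = 2, E = 0.5,
dh = max/100 (skeletonized data conventionally use different exponents —
all three are arguments). Connected components come from an explicit
neighborhood adjacency, so the same code serves 3D grids and arbitrary
graphs. Enhancement is monotone in the input and reduces to the closed-form
`sum h² dh` for an isolated unit.

**Multiplicity.** BH step-up within predefined families (ICV effects, sex
effects, age effects treated separately), implemented via statsmodels and
verified against the literal step-up definition exhaustively on short
p-vectors.

**Effect sizes.** Cohen's d = (women − men)/pooled SD, computed from raw
groups or printed (n, mean, SD) summaries and *not* covariate-adjusted
(declared choice; the adjusted variant is ambiguous in the source). Partial
η² per single-df term is t²/(t² + df_resid), identical to the Type-III SS
ratio, which the tests confirm by refitting reduced models.

## Synthetic data: what it does and does not emulate

Phantom bundles are smooth random perturbations of eight schematic
centerlines (arches, verticals, arcs placed far apart); offsets are bounded
by the dispersion radius via the Bezier convex-hull property, and point
order is randomly flipped so flip-invariance is always exercised. DWI signal
follows the single-tensor model `S = S0 exp(−b gᵀ D g)` on a 40-direction,
b = 1000 s/mm², 5 × b = 0 scheme with Rician (magnitude) noise.

What passing tests therefore show: the estimators recover what the forward
models generate, the clustering recovers well-separated bundles, and the
inference procedures are calibrated under their own assumptions. What they
do not show: robustness to anatomically realistic geometry (crossing,
kissing, fanning fibers), registration error, motion/eddy artifacts,
non-Gaussian covariate structure, or the real cohort's effect sizes. No
claims about the real population transfer from these tests.

## Problem sizes and numerical choices

Desk-scale defaults (8 bundles × 100–200 streamlines × 3 clustering
subjects, subset size 500, 10 repetitions, 500–2000 permutations, cohorts
of 60–2000) exercise every code path in seconds to a couple of minutes;
population-scale values (10,000-streamline subsets, 100 repetitions, 5000
permutations, k = 250) are plain configuration. All randomness flows
through explicit integer seeds; the pipeline derives stage seeds from one
master seed via a counter-based `SeedSequence` fan-out so stages can be
rerun independently and full runs are byte-identical. All ties — Ward
merges, assignment, modal labels — break toward the lowest index.

Known limitations: the ridge-based skeleton is a simplification and is not
meant to match template-registered skeletons voxel-for-voxel; hemispheric
structure is handled as separate responses rather than with mixed models
(the interaction screen is OLS-based and approximate); tract volume depends
on the tracking threshold by construction; and the sample-based rasterizer
can miss corner-grazed voxels at the default supersampling step.
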