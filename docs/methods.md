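# Methods

`hemiconn` implements the analysis chain for comparing the topological
organization of the two hemispheric white-matter networks of the human
brain: node template construction, deterministic tensor tractography,
FA-weighted network assembly, weighted graph-efficiency metrics with a
lateralization index, and a covariate-adjusted group-statistics battery.
Because clinical diffusion-MRI cohorts cannot be redistributed, the
package ships a first-class synthetic layer — tensor phantoms with known
fibre geometry and simulated cohorts with planted, exactly known
asymmetry effects — on which every stage is validated end to end.

## Node template: symmetric random parcellation

A cortical mask is made exactly mirror-symmetric about the midsagittal
plane (world `x = 0`) by combining it with its x-flip.  The combine rule
defaults to **union** (a voxel is kept if present on either side), which
preserves cortical coverage; **intersection** is available because the
binarization threshold of an "averaged" mask is a free choice with no
canonical value.

One hemisphere is then tiled into `n_rois` (default 512) connected,
near-equal-size ROIs by seeded region growing: seed voxels are drawn
uniformly without replacement; at each iteration the currently smallest
ROI accretes one unassigned 6-connected voxel, ties broken by lowest
linear voxel index.  Growing smallest-first keeps the size ratio
max/min ≲ 2 on compact masks (a construction target, not an assertion —
highly irregular masks can do worse).  Voxels unreachable from any seed
are attached to the nearest ROI by world-space centroid distance so the
tiling is always total; in pathological fragmented masks this can break
ROI connectedness, and masks with more connected components than ROIs are
rejected outright.

The right-hemisphere labels are flipped through the midplane to produce
the bilateral template; left label = right label + `n_rois`.  Mirror
flipping, rather than independent parcellation per hemisphere, is what
guarantees the one-to-one homologous node correspondence that the
asymmetry index requires.

Conventions: voxel indices are 0-based; world coordinates are mm through
a diagonal affine; hemisphere membership is the sign of world x, with
`x = 0` voxels belonging to neither hemisphere.

## Tractography: deterministic FACT-style tracking

Streamlines propagate from every seed voxel bidirectionally along the
non-interpolated principal eigenvector of the voxel containing the
current point, with a fixed step of half the smallest voxel dimension.
The eigenvector sign at each step is the one minimizing turning.
Propagation stops when the next point would enter a voxel with
FA < `fa_stop` (default 0.2) or leave the grid/brain mask, when the turn
between consecutive segments exceeds `angle_stop` degrees (default 45),
or at `max_len` = 300 mm (a cycle guard with no biological meaning).
Seeding is whole-brain: one seed per voxel at or above the FA threshold;
a seed below threshold yields a recorded zero-length streamline.  There
is no randomness anywhere in the tracker.

This is a documented reference implementation of the FACT family, not a
bit-level clone of any particular tool; the step length and interpolation
details of published pipelines vary and are rarely printed.

## Exact mirror symmetry (the built-in null experiment)

The pipeline is engineered so that a bilaterally symmetric input produces
*bitwise identical* left and right networks, making every asymmetry index
exactly zero rather than zero up to rounding:

* phantom grids use an odd x-dimension with a world-centred affine, so
  the midplane runs through the centre voxel column and grid x-flips are
  exact world mirrors;
* nearest-voxel lookup rounds the centre-relative x offset half away
  from zero, which commutes exactly with mirroring (IEEE negation is
  exact);
* FA is computed from tensor invariants (trace and Frobenius norm), which
  are bitwise insensitive to the sign flips of Dxy/Dxz under mirroring;
* principal eigenvectors are computed after canonicalizing the tensor's
  x-orientation, so mirrored tensors give exactly mirrored directions;
* per-edge FA samples are pooled with exactly rounded order-independent
  summation (`math.fsum`), so edge weights do not depend on streamline
  enumeration order.

The acceptance suite pushes a symmetric phantom through
track → build-net → metrics and asserts AI == 0.0 identically.

## Networks and metrics

An edge connects two ROIs of one hemisphere when a streamline's two
terminal points fall in them (nearest-voxel lookup); cross-hemisphere
pairs, self-loops and unlabelled endpoints are dropped and logged.  The
edge weight is the mean FA over **all points of all connecting
streamlines** (pooled estimator); the mean-of-per-fibre-means variant is
exposed as `weight_mode="per-fiber"`.  `edge_min_fibers` defaults to 1;
the strict "more than one fibre" reading (≥ 2) is available by flag —
the phrase is genuinely ambiguous and both are defensible.

Edge weights `w ∈ (0, 1]` convert to lengths as `1/w` (the convention of
the standard connectome toolboxes); `-log w` is available, and the rule
used is recorded in the `PathLengthMatrix`.  This conversion is the
single most consequential choice the metrics make, which is why it is
explicit and logged rather than implicit.  Shortest paths come from
Dijkstra over all sources; disconnected pairs contribute 0 to every
efficiency sum (the standard Latora–Marchiori contract):

* `E_glob = (1/(N(N−1))) Σ_{i≠j} 1/L_ij`
* `E_nodal(i) = (1/(N−1)) Σ_{j≠i} 1/L_ij` (mean over i equals `E_glob`,
  used as a numerical cross-check at 1e-12)
* `E_loc = (1/N) Σ_i E_glob(G_i)`, `G_i` the neighbour subgraph of i with
  original weights, i excluded; nodes with fewer than two neighbours
  contribute 0.

The asymmetry index of a paired measure is `AI = (M_R − M_L)/(M_R + M_L)`:
positive values mean rightward lateralization.  When both measures are
zero the AI is undefined and returned as NaN with a warning; downstream
statistics drop such cases per test (complete-case analysis, counts
logged).

## Statistical battery

All models are ordinary least squares, two-sided, with sex coded
female = 0 / male = 1 and covariates mean-centred within the analysis
sample.

1. **Within-group hemisphere test.**  The repeated-measures GLM with
   hemisphere as a two-level within factor and age, sex, hemispheric-ICV
   difference, TR and TE as covariates is implemented as the exactly
   equivalent paired-difference regression: `d = right − left` on centred
   covariates, testing the intercept (t² equals the within-factor F; the
   suite verifies this against an independent residual-sum-of-squares
   route, and the t/p values against a frozen independent `lm` oracle).
   Positive t = rightward.
2. **Interaction screen.**  Each AI measure is first screened for a
   sex × group interaction (F-test of the interaction block over the main
   effects model with age, sex, whole-brain ICV, hemispheric-ICV
   difference, TR, TE); a significant screen flags the comparison for
   sex stratification (sex is dropped from the stratified covariates).
3. **Group effect and post hocs.**  Three-level group F-test,
   covariate-adjusted; pairwise AD−NC, AD−MCI, MCI−NC contrasts fit per
   pair with the same covariates, Bonferroni-corrected with m = 3
   (p × 3, capped at 1).
4. **Nodal multiplicity.**  Within-group nodal tests are
   Benjamini–Hochberg corrected at q = 0.05 with m = number of nodes,
   per group.  Between-group nodal effects are reported at uncorrected
   p < 0.05 with the BH decision additionally computed and stored —
   published workflows mix these conventions, so both are emitted with
   provenance.
5. **AI–memory associations.**  Each memory score (verbal-learning
   TOTAL / TOT6 / RECOG) is regressed on each AI measure plus the
   covariates; negative t means stronger rightward asymmetry tracks
   poorer memory.  Nodal associations are restricted to the nodes with
   significant group differences and BH-corrected across nodes per score.

The battery orchestrates these stages, restricting nodal group tests to
nodes significantly asymmetric in at least one group, and serializes
every result with its statistic, df, raw and adjusted p, and adjustment
method.  Degenerate inputs (a perfectly symmetric cohort with constant
zero AI) complete with the association family skipped and noted.

## Synthetic data

**Phantoms.**  Bundles are tubes around polylines; inside, tensors are
cylindrically symmetric (λ1 > λ2 = λ3) with the principal axis along the
local bundle direction and eigenvalues solved in closed form from the
target FA at fixed mean diffusivity 0.7 (arbitrary units) — an invertible
construction, so the phantom's FA map is known exactly.  The background
is a low-FA (default 0.05) field oriented along +z (mirror-neutral).
Overlapping bundles with conflicting directions or FA are rejected by
name.  Optional i.i.d. Gaussian noise on tensor components models
estimation noise; it is off in all mirror-symmetry experiments.

**Cohorts.**  Each subject draws one base symmetric weighted network
(edges Bernoulli(`density` = 0.15), weights N(0.45, 0.10) clipped to
(0, 1]); the left hemisphere is the base, the right adds the group's
`global_asym_delta` (defaults NC 0, MCI 0.004, AD 0.012) plus a
per-subject N(0, 0.010) lateralization jitter, and `nodal_asym_delta` on
edges incident to a designated node subset.  The jitter is what gives
subjects a realistic between-subject AI spread (≈ 0.01 in AI units);
without it the group tests would have degenerate power and null
calibration would be meaningless.  Weights are re-clipped after shifting
and the clipping rate is reported in the truth record.  Group sizes
default to 48/95/25 (NC/MCI/AD), ages to group means 75.0/74.9/77.4
(SD 6.0/7.4/8.4) years, and sex to group-specific male fractions
(21/48, 57/95, 19/25 — the AD group deliberately male-skewed so the
interaction screen has a realistic imbalance to face).  Intracranial
volume is N(1.45e6, 1.4e5) mm³ split nearly evenly between hemispheres;
TR ≈ N(12900, 500) ms and TE ≈ N(68, 3) ms emulate mild site variation.
Memory scores follow `score = β0 + β_AI·trueAI + β_age(age−75) + β_sex·male + ε`
with negative `β_AI` (−400/−120/−110 points per AI unit for
TOTAL/TOT6/RECOG, noise SD 9.0/3.3/3.5), anchored at normal-control
levels, where `trueAI = s/(2·μ_w + s)` is the subject's planted global
asymmetry.  One root seed spawns an independent RNG stream per subject
(`SeedSequence.spawn`), so cohorts reproduce element-wise.

The planted deltas are free parameters chosen by Monte-Carlo calibration
for test power (≥ 200 replicates before freezing), not estimates of any
clinical effect size: no published effect sizes exist for these AI
differences.  At the defaults, the AD-vs-NC detection power at
n = 200/group and the negative-coefficient sign-recovery rate at the
default cohort sizes both measured 1.0.

**What the simulator does not model:** raw diffusion-weighted signals,
gradient tables and scanner noise, registration error, spatially
structured (non-exchangeable) edge effects, missing data, and any true
nonlinear AI–score relationship.  Passing tests therefore demonstrate the
correctness and calibration of the pipeline's computations, not clinical
validity on real scans.

## Problem sizes and numerics

The test and acceptance workloads use scaled-down problem sizes chosen as
the package's own defaults for routine validation: 64-node hemispheres
for cohort-level simulations (the template default remains 512; all graph
code is exercised at 512 in the FDR family and the parcellation test),
50-replicate power runs at n = 200/group, 100-replicate sign-recovery
runs, and 2000-replicate null calibrations at n = 60.  Monte-Carlo
tolerances: type-I rates are asserted within [0.04, 0.06] at α = 0.05
(±2 binomial SE at 2000 replicates); empirical FDR within 2 MC SE of
q = 0.05.

Numerical choices worth knowing: Dijkstra via sparse graphs (a zero
weight means "no edge", so weights must be strictly positive, enforced by
a 1e-6 clip floor in the simulator); efficiency identities checked at
1e-12; OLS through the pseudoinverse with explicit constant/collinearity
screening that names the offending covariate; BH implemented by the
standard step-up with the critical index reported.
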