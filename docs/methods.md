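# Methods

## Generative model

The unit of analysis is the run-wise activation pattern `b_ir` (condition
`i`, run `r`, voxel vector of length P). The generator draws

    b_ir = c + s_i + g_r + e_ir

with all components independent across voxels and zero-mean Gaussian:
`c` the common pattern (voxel-wise variance `v_common`), `s_i` the
condition-specific pattern (`v_specific`), `g_r` a run-common effect
(`v_run`, drawn once per run and shared by all trials of that run), and
`e_ir` trial noise (`v_trial`).

The specific patterns are linear combinations of `d ∈ {1,2,3}` basis voxel
maps, and the coordinate geometry controls how the four conditions are
arranged in that subspace:

- **random** — coordinates i.i.d. N(0, v_specific/d); patterns are
  uncorrelated across conditions with expected voxel variance
  `v_specific`. The basis maps are Gaussian, so realized per-condition
  variances fluctuate around the parameter (with only 4 conditions and up
  to 3 basis maps this fluctuation is substantial; moment checks therefore
  average over replicate draws).
- **evenly_spaced** — coordinates at the vertices of a centered regular
  simplex (requires d = K−1). Here the basis is orthonormalized and
  rescaled to unit voxel variance so that the simplex is exact: all
  pairwise pattern distances are strictly equal and each pattern's
  realized mean-square is exactly `v_specific`.
- **scaled_1d** — all conditions are scalar multiples of a single Gaussian
  map (d = 1), emulating conditions that differ only in the intensity of
  one pattern.

BOLD runs place each trial's pattern (common + specific + run effect + a
fresh trial-noise draw) under a 13.5 s boxcar convolved with the canonical
double-gamma HRF, sampled on a 0.05 s grid and read out at the volume
times; white scanner noise (`noise_sd`) is added per volume and voxel.
The schedule mirrors the scanning design: 8 runs of 110 volumes at
TR = 2.72 s, 16 trials (4 per condition) plus 4 rest phases of 13.5 s in
random order per run. The design's own timing inconsistency (trial grid in
multiples of 13.5 s against TR 2.72 s) is reproduced, not resolved; FIR
bins are defined in TR units, so the 9 bins cover 24.48 s.

## GLM

One regressor per condition per run plus a per-run intercept. Data and
design are high-pass filtered identically by residualizing against a
discrete-cosine basis containing the constant and all frequencies below
1/128 Hz (drift removal only; no autocorrelation model — estimation here
is used for point estimates, not time-series inference). Per-voxel
coefficients come from ordinary least squares; the robust option computes
each volume's cross-voxel mean squared residual, standardizes it, converts
it to a Tukey bisquare weight (c = 4.685, weights shared across voxels)
and reweights for two iterations — a simple, testable realization of
down-weighting artifact volumes. The FIR variant estimates one amplitude
per condition per run per post-onset TR bin (9 bins); temporal components
are the left singular vectors of the bin × (observation·voxel) matrix
after per-bin mean removal, ordered by singular value.

## Classifier

Regularized LDA with equal priors. The pooled within-class covariance uses
residuals from training-fold class means with denominator
(observations − classes), and is regularized by adding
`reg_fraction = 0.01` of its mean diagonal element to the diagonal. Test
patterns go to the class with minimal Mahalanobis distance; exact ties
(measure-zero, but possible on degenerate inputs) deterministically go to
the lowest class index. Cross-validation is leave-one-run-out, and the
binomial z-transform uses the total number of cross-validated
classifications (32 for 4 conditions × 8 runs), which makes z = 1.64
correspond to the 37.5% within-subject accuracy threshold (the threshold
helper truncates to one decimal place). The behavioral classifier averages
movement time, mean peak force and error rate per condition and run,
z-standardizes each feature across all condition-runs, drops constant
features with a warning, and feeds the rest to the same LDA.

## Searchlight, ROI and group inference

Cortical geometry is abstracted to units with coordinates and per-unit
areas (a flat sheet by default; any coordinate set, e.g. mesh-derived,
plugs in). A searchlight selects each center's p = 160 nearest units
(distance ties broken by index) and assigns the neighborhood's
cross-validated accuracy to the center. ROI accuracy uses the
random-subspace scheme: repeated draws of 160 units without replacement,
accuracy averaged over draws. Suprathreshold area sums unit areas above an
accuracy threshold.

Group maps are tested with one-sample t statistics per unit (paired
contrasts are passed as difference maps). The cluster-forming threshold is
the **one-sided** critical t at p = 0.002: with 16 subjects this gives
t(15) > 3.395, matching the reported threshold (a two-sided reading would
give 3.73 and does not). Clusters are connected components of
suprathreshold units (adjacency radius 1.5 units, i.e. 8-connectivity on a
unit grid), measured by total area; family-wise p-values come from the
sign-flip permutation null of the maximum cluster area, with the standard
(1 + exceedances)/(n_perm + 1) estimator, replacing parametric
Gaussian-field cluster correction.

## Dimensionality analysis

Per cross-validation fold, the pattern components are the right singular
vectors of the grand-mean-centered training class means, ordered by
singular value (singular value = between-class signal along that
component, the natural reading of "most informative"). Training and test
patterns are projected onto the top d components and the same regularized
LDA runs in the subspace. For 4 classes the centered class means have rank
at most 3, so d ranges over 1–3.

Accuracy-matched simulations bisect on the specific-pattern variance
(trial noise fixed at 1, common and run components omitted — they do not
affect the classifier) until the mean simulated accuracy at a chosen
matching dimensionality equals the observed accuracy within 0.005, then
report the full d = 1..3 curve under the requested geometry. The matching
dimensionality is a parameter (`match_dim`), since matching on the one- or
three-dimensional classifier are both defensible conventions. Simulation
seeds are fixed per replicate so that accuracy is a monotone deterministic
function of the signal scale, keeping the bisection well behaved (40
iterations maximum; targets at or below chance return a flat chance curve
with a warning).

## Variance decomposition

A method-of-moments estimator on raw voxel cross-products. With
m(i,r; j,r′) the mean over voxels of `b_ir · b_jr′`, averaging over the
four cells (same/different condition × same/different run) gives four
linear equations in (v_common, v_specific, v_run, v_trial), solved
exactly; negative solutions are clipped to zero with a warning and the
unclipped values retained. Raw products are used deliberately: removing
the mean pattern would absorb the common component, which is itself a
quantity of interest. This moment estimator is a concrete, testable
stand-in for likelihood-based pattern-component estimation; it estimates
the *realized* second moments of the drawn patterns, so recovery of
generating parameters is assessed on replicate averages. Two known biases
are documented rather than hidden: for the evenly-spaced geometry the
negative coordinate correlations of the simplex inflate the specific
estimate by a factor 4/3 and depress the common estimate by v_specific/3;
and GLM estimation noise adds to the trial-noise component of estimated
(rather than directly simulated) patterns.

## Default parameters

| parameter | default | why |
| --- | --- | --- |
| TR, volumes/run, trial length | 2.72 s, 110, 13.5 s | the scanning design being emulated |
| runs × conditions × trials | 8 × 4 × 4 | same |
| press / interference threshold | 2.5 N / 2.2 N (≥ / strict <) | the task's keypress rule; ties at 2.2 N block |
| force-trace sampling | 200 Hz | resolves press onsets to 5 ms |
| high-pass cutoff | 1/128 Hz | standard drift removal for this TR |
| LDA regularization | 1% of mean diagonal | standard shrinkage for 160-voxel neighborhoods |
| searchlight size | p = 160 units | the neighborhood size the analysis is built around |
| ROI scheme | top 800 units, 160-unit draws | random-subspace averaging; 5000 draws for production, fewer in the demo pipeline |
| demo signal levels | trained: evenly spaced, v_specific 0.003, v_common 0.30; untrained: random, 0.002 / 0.40; v_run = v_trial = 0.1; scanner noise SD 1 | places cohort accuracies in the observed 32–55% band with trained > untrained, and keeps common:specific pattern variance ≥ 100:1 |
| behavioral generator | MT 1209/1341 ± 297 ms, ±300 ms per-sequence spread, 12% errors, 4.4/4.0 N forces | reproduces the reported in-scanner performance table, including ~55–60% behavioral decodability |
| cohort size | N = 16 | the random-effects design size (tests and the demo use smaller cohorts) |

Movement time is defined onset-of-first-press to onset-of-fifth-press:
onset-based timing is invariant to release dynamics, and the alternative
(onset-to-release) is not better constrained. A degenerate regression with
all-zero post-test differences reports t = 0, p = 1 rather than NaN.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analyses assume —
Gaussian spatially-random components, exchangeable runs, linear
HRF-convolved responses, homoscedastic scanner noise. It does not emulate
spatially smooth noise, physiological confounds, motion, susceptibility
distortion, cortical folding, or inter-subject anatomical variability.
Passing tests therefore validate the estimators and their calibration
under the model's assumptions (null accuracy at 25%, correct family-wise
error control, unbiased component recovery, correct geometry signatures),
not robustness to real-data artifacts. Real-data I/O (4-D NIfTI plus
BIDS-style events tables) is supported so the same code paths run on
preprocessed volumes, but preprocessing itself (realignment, distortion
correction, surface reconstruction) is out of scope.

## Problem sizes

The test suite and the calibration script use desk-scale sizes chosen as
a deliberate trade-off between Monte-Carlo error and turnaround: 200 null
datasets for accuracy calibration, 2000 sequence pools for the
transition-overlap average, 100–200 replicates for moment-recovery and
family-wise-error checks, 8×8 to 14×14 sheets for map-level tests, and
cohorts of 2–6 subjects for pipeline tests. All Monte-Carlo assertions use
tolerances derived from the corresponding standard errors.
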