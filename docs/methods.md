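# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and — importantly — the statistical behaviour of TR-level
cross-validation on run-blocked designs, including one intrinsic
miscalibration that the test suite reports honestly instead of hiding.

## The decoding model

Within one subject, every acquired volume (TR) is a sample and every voxel
inside a chosen mask is a feature.  Features are percent signal change
(PSC), z-scored per voxel over the included timeseries; the classifier is a
support vector machine with a radial-basis-function kernel, `C = 100` and
`gamma = 1/P` (`P` = feature count), trained to separate the two memory
conditions.  Model evaluation uses randomized k-fold cross-validation
(default 10 folds; folds are random TR subsets whose sizes differ by at most
one).  Reported accuracy is the *median* fold accuracy; sensitivity and
specificity are pooled over the held-out predictions of all folds
(well-defined even when a small fold contains few positive rows — a per-fold
median of ratios with tiny denominators is not).

Feature-weight maps.  An RBF SVM has no primal weight vector in voxel
space; the reported per-voxel weight is the linear pre-image of the dual
solution, `w_j = Σ_i α_i y_i x_ij` over support vectors, and the final map
is each voxel's median weight across folds.  This is the standard reported
quantity for kernel SVMs in neuroimaging, but it is *not* the gradient of
the decision function: it is essentially a (support-vector-weighted)
difference of class means.  Two consequences follow and are verified in the
test suite: it localizes mean-coded condition signal very well (localization
ROC-AUC ≈ 0.96 on the default synthetic subject), and it is nearly blind to
purely variance-coded signal (a symmetric spread of one class along a
direction cancels in the sum).

The leakage caveat of the classical recipe is kept deliberately: z-scoring
uses statistics of the full included timeseries, and folds are random TR
subsets that ignore temporal autocorrelation.  A leakage-safe per-training-
fold z-scoring mode (`zscore="none"` + downstream scaling) is available.

## The synthetic study

`SimConfig` defaults encode the emulated design: two conditions × five
repetitions of 90 TRs at TR = 2 s (3-minute narrated recall runs; the 30-s
rests preceding each run are excluded from classification in the original
design and are not simulated), on a 3-mm isotropic grid.  The anatomy is a
concentric-shell phantom — CSF core (r < 9 mm), WM shell (9–20 mm), GM
shell (20–33 mm) on a centred 24³ grid, 4 408 GM voxels — small enough that
the full pipeline runs in seconds, while real-size grids pass through the
same interfaces.

Each run contains:

- voxel noise: stationary AR(1) in time (`ar1_coef = 0.35`, a realistic
  lag-1 autocorrelation at TR = 2 s) and spatially correlated
  (`noise_fwhm_mm = 6`), marginal SD `noise_sd = 1`.  Spatial correlation is
  essential realism: spatially *white* voxel noise maximizes the
  run-geometry pathologies described below.  The per-voxel renormalization
  after spatial smoothing uses SDs pooled across **all** runs — a per-run
  renormalization would imprint a run fingerprint;
- polynomial drift (random degree-1–2 Legendre coefficients,
  `drift_amplitude = 2` noise-SD);
- compartment signals: one slow common timecourse added to all WM voxels
  and another to all CSF voxels, so the WM/CSF mean regressors have real
  work to do;
- rigid-body motion: six weakly mean-reverting random walks
  (`motion_step_sd = 0.02` mm/° per TR; decay 0.995 keeps excursions
  bounded without distorting step statistics);
- optionally, a motion-coupled artifact: standardized framewise
  displacement times a smooth, anatomically fixed random gain map
  (`motion_artifact`, default 0 — motion artifact is spatially
  heterogeneous in real data; a spatially uniform artifact would be
  perfectly absorbed by the WM/CSF mean regressors).

The trauma condition adds a signed, spatially smoothed activation pattern on
a support of `n_signal_voxels` GM voxels, rescaled so its RMS amplitude over
the support is `effect_size` noise-SD units.  The default support (1 100
voxels, ~25 % of the phantom's GM) models the central empirical finding the
package exists to probe: recall engages a *brain-wide distributed* state.
The size is also a kernel-visibility constraint — with `gamma = 1/P` the
RBF kernel's exponent sees a signal only through `‖Δμ‖²/P`, so a handful of
strong voxels is invisible among thousands of features no matter how large
their univariate effect.  With `nonstationarity = q`, a fraction `q` of the
support moves to fresh GM locations between successive repetitions
(modelling the drifting network configuration under repeated recall); an
optional two-state engagement envelope (`envelope_amplitude`, default off)
modulates the signal within runs.

Cohorts draw covariates from the emulated clinical sample (severity
~ N(62.3, 13.5) clipped to the instrument's 17–85 range, age
~ N(33.8, 10.8), comorbid depression 44 %, substance use 25 %) and couple
the signal amplitude inside a designated mid-GM-shell sphere to
standardized severity (`severity_coupling`), giving group-level analyses a
recoverable planted effect.

What the generator does **not** emulate: hemodynamic impulse responses
(signals switch instantaneously), physiological quasi-periodic noise,
susceptibility dropout, scanner drift nonlinearities, and between-subject
anatomical variability (all subjects share one phantom).  Passing tests
therefore demonstrate correctness of the machinery and the qualitative
phenomena (distributed decodability, diminishing-returns reproducibility,
motion-control gap), not quantitative transfer to any particular scanner.

## Preprocessing

Stage order (single entry point, so methodological permutations differ only
in the smoothing flag): nuisance regression → optional smoothing →
detrending → PSC.

- **Nuisance regression** uses the 24 Volterra motion terms
  `[R, R², R_{t-1}, R²_{t-1}]` (lagged rows zero-padded at t = 0), the WM
  and CSF mean timecourses, and polynomial drift columns of degree ≤ 2
  fitted *jointly*.  Joint estimation is not a style choice: regressing
  stochastic smooth regressors against data that still contain drift
  transfers run-specific regressor timecourses into every voxel (the fitted
  slopes pick up the drift–regressor correlation), which a later detrend
  cannot undo and which a powerful classifier then reads as a run
  signature.  Exact-duplicate and all-zero columns are dropped at assembly;
  rank deficiency after the drop is an error.  Rotations stay in native
  degrees (no lever-arm conversion).
- **Smoothing to a target FWHM** iterates estimate-and-add: measure current
  smoothness, apply the incremental Gaussian `√(target² − current²)`
  (Gaussian widths add in quadrature), re-measure; stop within
  `tolerance_mm` (default 0.5 mm) or after `max_iterations`.  Smoothing is
  kernel-renormalized inside the brain mask, so per-volume means are
  preserved and nothing bleeds across the mask edge.
- **Smoothness estimation** works on temporally differenced data (which
  suppresses task structure), models the one-voxel-lag spatial correlation
  ρ of the differences as Gaussian, inverts `FWHM = v·√(2 ln 2 / (−ln ρ))`
  per axis, floors estimates at the voxel size (the grid resolves nothing
  below its own sampling), and combines axes geometrically.  A spatially
  constant image returns the `inf` sentinel.
- **Detrending** removes a least-squares polynomial (default order 2) per
  voxel; order 0 is exact mean-centring; the operation is idempotent.
- **PSC** maps each voxel to `100·(x_t − m)/m`.  Voxels whose baseline
  magnitude falls below 1 % of the global in-mask mean are zeroed and
  counted (avoids dividing by near-zero).

**Session-anchored baselines.**  Nuisance regression and detrending
necessarily zero each voxel's within-run mean.  If PSC then also used the
run's own mean, every voxel's mean would be exactly zero in every run, the
two conditions would have *identical* class means by construction, and no
sustained condition response could reach the classifier or the weight maps —
only within-run dynamics would remain.  In the real acquisition the rest
epoch preceding each run anchors the baseline; the pipeline reproduces that
anchoring at the session level: the PSC baseline is the voxel's mean over
**all** of the subject's runs, and each run's mean deviation from it
(smoothed alongside the data in the smoothed arm) is re-added after the
mean-removing stages.  This single composition choice is what makes
sustained condition signal, weight-map localization, cross-run
reproducibility structure and group-level coupling analyses all work; its
cost is analysed next.

## Null behaviour of run-confounded TR-level CV

In this design, condition labels are blocked by run: every TR of a run
shares the run's label.  The test suite demonstrates (and the acceptance
check honestly fails on) a structural fact: **with run-blocked labels,
TR-level cross-validated accuracy under a true null is not 0.5**, for two
opposing reasons:

1. *Anti-learning.*  Per-run operations (mean/trend removal, the ~29-column
   nuisance projection) couple the rows of a run: each row is pushed away
   from its run-mates in feature space by a systematic O(q/T) amount.  In
   high dimensions distances concentrate, so an RBF SVM with C = 100 reads
   this tiny repulsion reliably; a test row is then attributed to the
   *other* class (its own class contains its own run).  On spatially white
   noise this drives null accuracy to ≈ 0 — the "below-chance
   classification" phenomenon reported in the MVPA literature.
2. *Run fingerprints.*  Anything shared by the rows of one run — temporal
   autocorrelation between neighbouring TRs, and above all the run-mean
   noise (σ/√T per voxel) retained by session anchoring — lets the
   classifier identify the run, and hence its label.  Under the default
   configuration this pro-leakage channel dominates: measured null accuracy
   over 50 seeded small-grid subjects is ≈ 0.92.

No configuration consistent with the stage contracts lands at 0.5: designs
that zero the run means anti-learn (accuracy ≈ 0.0–0.08), designs that keep
sustained responses fingerprint (≈ 0.9+); intermediate parameter choices
merely move along the knife edge.  The correct calibrated null for this
machinery is the **TR-level label permutation**, which breaks the run–label
alignment; the suite verifies it sits at 0.500 ± binomial noise.  Practical
implication, worth stating plainly: absolute accuracy values from
run-confounded TR-level CV should never be compared against 0.5 — only
against a permutation distribution, or between conditions sharing the same
run structure (as the smoothing/run-count/mask comparisons and the motion
control do).

A related consequence: with session anchoring, a one-run-per-condition
model (k = 1) is trivially perfect — at k = 1 class and run coincide, so
any run-level structure separates the classes.  Rising accuracy-vs-run-count
curves therefore do not reproduce here; the monotonicity check operates at
the default effect size where the curve is flat at ceiling, while the
*reproducibility* curve (below) carries the interesting run-count
structure.

## Reproducibility and group statistics

Weight maps from models trained with k = 1…5 repetitions per condition are
compared by spatial Pearson correlation, Fisher r-to-z transformed
(`z = arctanh r`; |r| = 1 is reported as ±18.7, the `arctanh(1 − 1e−16)`
order sentinel, keeping tables numeric).  Each model's summary is the
median of its similarities with all other models; models are compared
across subjects with a paired signed-rank test (paired t optional).  With
non-stationary patterns the median-similarity curve peaks at intermediate k
(measured peak at k = 3–4 with `nonstationarity = 0.5`): few-run models
overfit their repetitions' patterns, many-run models average incompatible
ones — the diminishing-returns trade-off the run-count recommendation rests
on.

Group-level inference on weight maps:

- voxelwise one-sample t tests (two-sided; zero-variance voxels get the
  sentinel p = 1 and are counted);
- voxelwise robust regression of weights on severity controlling for age
  and the binary comorbidity covariates (entered as 0/1).  The estimator is
  Huber's M-estimator (tuning 1.345, IRLS with MAD-about-zero scale,
  relative tolerance 1e−8, ≤ 50 iterations), implemented as a vectorized
  IRLS sharing one design across all voxels — a per-voxel loop through a
  generic implementation is orders of magnitude slower at map scale — and
  cross-checked against the reference single-response implementation to
  1e−4 in the test suite.  p-values use a t reference distribution on
  n − p degrees of freedom (slightly more conservative than normal-theory
  p-values).  At the emulated sample size n = 16 the standard M-estimator
  covariance is mildly liberal (measured type-I ≈ 0.073 at α = 0.05, a
  known small-sample property shared by reference implementations);
  calibration within ±2 SE of nominal holds from n ≈ 40, where the
  acceptance simulation operates;
- cluster-extent thresholding: connected components of voxels with
  p < 0.01 (26-neighbourhood default; 6/18 configurable) smaller than the
  minimum extent are discarded.  The classical 47-voxel extent is an
  *input* default — it depends on the smoothness and mask of the data it
  was derived for — and a Monte-Carlo estimator recomputes extents for any
  mask/smoothness: simulate smoothed Gaussian null volumes, standardize
  within the mask, threshold two-sided, take the 95th percentile of the
  maximum cluster size, plus one;
- ROI-level tests: subject-wise mean weight within each 6-mm sphere, then
  one-sample t and robust severity regression (through the reference
  scalar implementation — a deliberate second route next to the vectorized
  map-level IRLS).

## Motion control

Framewise displacement is the sum of absolute temporal differences of the
six motion parameters in native units (FD₀ = 0; no lever-arm conversion).
The control classifier reuses the *identical* feature matrix and CV
machinery as the condition decoder (asserted by call tracing in the tests)
with labels replaced by a high/low split at the median of FD concatenated
across the included runs (ties at the exact median go to "low").  On
motion-independent synthetic subjects it sits near chance (measured ≈ 0.55,
mean over seeds) while condition decoding is at ceiling; injecting a
motion-coupled artifact (gain 1) raises it to ≈ 0.63.  Larger artifact
gains paradoxically *lower* RBF accuracy — extreme-FD rows acquire outlying
norms and fall off the kernel — an instructive ceiling on what the control
can detect.

## Numerical conventions

- All randomness flows from explicit seeds; identical configurations
  reproduce bit-identical datasets and tables.
- Sphere masks snap the requested centre to the nearest voxel centre and
  use the inclusive boundary (≤ radius): a 6-mm sphere on a 3-mm grid
  contains exactly 33 voxels (strict inequality would give 27).
- Fold assignment: seeded permutation + even split; sizes differ by ≤ 1.
- Degenerate cases fail loudly: single-class training folds, all-equal FD,
  zero-variance similarity inputs and rank-deficient designs raise typed
  errors rather than returning silently wrong numbers.
- Masks whose MNI sphere centres fall off a desk-scale grid are retained
  as empty and flagged; the pipeline substitutes a deterministic stand-in
  circuit ROI set placed inside the phantom GM (provenance recorded on the
  mask set).

## Known limitations

- The phantom is one shared anatomy; between-subject variability enters
  only through noise, pattern placement and covariates.
- No hemodynamic convolution: condition onsets are steps, so preprocessing
  interactions with HRF shape are untested.
- The null-calibration pathology above means absolute accuracies from this
  (and the emulated) design carry a run-structure component; all
  conclusions should rest on within-design contrasts or permutation nulls.
- The motion control shares the run structure of the condition decoder but
  its labels cut across runs, so the two accuracies are not affected
  identically by run-level leakage; the reported gap is therefore a
  conservative demonstration that condition decoding is not motion-driven,
  not an unbiased estimate of motion information.
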