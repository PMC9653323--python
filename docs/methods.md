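# Methods

## Connectome construction

Each session is a T×N matrix of parcel-averaged BOLD-like signal
(optionally extracted from voxel data as the unweighted mean over voxels
with the region's label and gray-matter probability ≥ a threshold,
default 0.5). The FC matrix is the absolute Pearson correlation between
all region pairs, so entries lie in [0, 1]; the absolute value is taken
before any normalization. Global normalization divides every
off-diagonal entry by the subject-session's whole-brain mean FC, defined
as the mean over the N(N−1)/2 unique off-diagonal pairs — the diagonal
never enters any average. After normalization the off-diagonal mean is
exactly 1, which makes the operation idempotent and removes any global
multiplicative FC shift (multiplying a raw matrix by k > 0 leaves the
normalized matrix unchanged).

Regions whose voxels all fall below the gray-matter threshold are
flagged empty, dropped from that session's matrix with a logged count,
and the profile metrics renormalize over the surviving regions. Tumor or
resection cavities can empty parcels; dropping is preferred over
imputation so that downstream models see an honestly unbalanced design.
A zero-variance series that is *not* flagged empty is an error, because
its correlations are undefined.

## Hub partition and spatial profile

Hubs are fixed a priori by network label: DMN ∪ FTPN; everything else is
no-hub. No centrality measure is computed. The five profile metrics are
block means over unordered within-set pairs (within DMN, within FTPN,
within hubs, within no-hubs) or all cross pairs (between hubs and
no-hubs). The within-hubs metric includes the DMN–FTPN cross pairs: the
two networks are treated as one extended hub network. A within-class
metric whose class retains fewer than two regions is reported as missing
(NaN), never as zero, and missing observations propagate into the mixed
models by row-wise deletion.

A useful end-to-end identity: the pair-count-weighted average of
within-hubs, within-no-hubs and between equals the whole-matrix
off-diagonal mean, i.e. exactly 1 after normalization. The test suite
and the acceptance script verify this to 1e-9.

The packaged 333-region reference table carries the real 13 network
names and per-network region counts of the reference cortical
parcellation; its region names and voxel counts are synthetic stand-ins
(file `gordon333_synthetic.tsv`), since the atlas voxel geometry is not
shipped. Desk-scale work uses a configurable 60-region atlas with the
same schema (DMN 12, FTPN 10, two no-hub networks of 19).

## Baseline statistics

Continuous group comparisons use the pooled-variance two-sample t
(df = n1 + n2 − 2) or a Mann–Whitney U with normal approximation and tie
correction; categorical comparisons use Pearson chi-square without
continuity correction. Tumor lateralization is a whole-cohort left/right
split, so it is tested as a one-sample goodness of fit against equal
frequencies; a 2×2 independence variant is also exposed. Tumor-overlap
percentages are computed per patient (per hub class) and compared as
continuous variables. No multiple-testing correction is applied at
baseline.

## Longitudinal mixed models

All three families share: a random intercept per subject (a single σ² is
reported; no random slopes), REML estimation, nuisance covariates (age,
sex, baseline tumor volume, IDH mutation, MGMT methylation, WHO grade),
and per-term Wald t tests with residual degrees of freedom
(df = n_obs − n_fixed). Time is continuous months post-surgery; when
exact dates are absent, follow-up windows are coded at bin midpoints
2, 4.5, 7.5 and 12 months with baseline at 0. Coding: LGG = 1 / HGG = 0,
LEFT = 1 / RIGHT = 0, so a positive time × lateralization term reads
"left increases faster". Under the null generator the per-term rejection
rate at p < 0.05 is measured at ≈0.05 (within the binomial 95% band over
500 replicate cohorts), supporting the residual-df reference at this
design size.

Numerical choices: predictors are centered and scaled internally before
the variance optimisation — an exact linear reparameterization whose
estimates are mapped back, needed because FC outcomes (~1) and
covariates (age ~50) otherwise condition the profiled likelihood badly.
Optimizers are tried in the order bfgs, cg, powell; a failure of all
three is an error, and any convergence warning flags the fit rather
than hiding it. Data that an ordinary least-squares fit explains
exactly (constant or noiseless outcomes) short-circuit to a flagged
`perfect_fit` result with σ² = 0 instead of a degenerate variance
optimisation. A rank-deficient design is an error naming the collinear
columns when a term of interest is involved; redundant *nuisance*
covariates (binary covariates can coincide by chance in small cohorts)
are dropped with a logged warning, mirroring common mixed-model
practice.

Effect sizes: Cohen's d is the approximation 2t/√df; the standardized β
scales by sd(predictor)/sd(outcome) over the analyzed rows (both sides
standardized). Both are descriptive attachments to the Wald test, not
separate inferences.

FDR: Benjamini–Hochberg step-up within a family, applied per term. The
FC family is the five profile models; cognitive families are domains
from a packaged test→domain map (memory: Rey word list, Rey figure,
digit span, Corsi; language: naming, fluency; attention/executive:
TMT-A/B). The implementation is checked against a brute-force step-up
oracle and against an independent library routine.

## Synthetic cohort generator

Defaults emulate the study conditions: 28 subjects (11 LGG of whom 7
left-lateralized; 17 HGG of whom 8 left), categorical covariates drawn
with exact group counts (22 males, 6 IDH-mutated, 6 MGMT-methylated,
WHO grades I–IV), ages ~N(41, 15²) for LGG and N(54, 12²) for HGG,
tumor volumes larger in HGG, extents of resection near 92/97%. Visits
follow the schedule {0, 2, 4.5, 7.5, 12} months; baseline is always
observed and each follow-up is kept with probability 0.36 (with at
least one follow-up guaranteed), giving 73.0 expected observations per
cohort.

The time-series route draws T = 275 volumes over 60 regions from
zero-mean multivariate normals with block correlation structure: base
correlations r_hub = 0.45, r_nohub = 0.30, r_between = 0.18, and
per-month drifts d_hub_right = +0.008, d_nohub_right = −0.006,
d_between_right = +0.004 for right-lateralized subjects plus
d_dmn_grade = +0.004 for LGG in the DMN block. These drifts encode the
phenomenon the models should recover: right-lateralized patients gain
within-hub (especially DMN) FC over time and lose no-hub FC. Every
session's target matrix is checked for positive semidefiniteness; the
defaults never need repair (asserted in the tests), and an infeasible
configuration is projected to the nearest PSD matrix with a logged
count. Note that the absolute-value correlation biases small-|r| block
means upward at finite T, so empirical block means are compared against
Monte-Carlo truth, not the raw generating r.

The fast route skips time series and draws the five profile metrics
directly from a linear model on the profile scale:
value = μ_m + b_i + slope_m(group)·months + ε, with per-metric means
(1.30, 1.25, 1.20, 0.95, 0.92), right-group slopes per month
(+0.006, 0, +0.005, −0.001, +0.0023), a +0.004 DMN grade increment,
between-subject intercept SDs (0.10, 0.10, 0.10, 0.02, 0.01) and
residual SDs (0.030, 0.030, 0.025, 0.005, 0.010). The variance scales
were chosen so that the implied σ² and the Wald statistics of the
generated effects sit in the range the profile models report at this
design size; the implied mixed-model coefficients are recorded in the
truth record (e.g. the within-hubs time × lateralization contrast is
−0.005 under LEFT = 1 coding). This route is used for replicate-heavy
statistics (parameter recovery, type-I calibration) where thousands of
model fits are needed; at 28 subjects and ≈73 observations, interaction
estimates recover their generating values with mean bias below 5% over
200 replicates and the hubs-up/no-hubs-down sign pattern in ≥90%.

Cognitive scores are generated from the profiles:
score = base + b_i + b_time·months + grade/lateralization time
increments + Σ b_link·metric·months + noise. Defaults include a
learning effect on the Rey figure (+0.75/month), a DMN link for digit
span (+0.32) and negative-oriented links for the timed TMT tests, so
recovery tests can check both magnitudes and sign bookkeeping.

What the generator does *not* emulate: hemodynamics, realistic noise
spectra (1/f, physiological), head motion, spatial lesion geometry,
scanner drift, or preprocessing artifacts. Passing tests therefore
demonstrate statistical correctness of the pipeline under its model
assumptions — not robustness to real-world fMRI confounds.

## Problem sizes

The default test suite and the acceptance script use the 60-region
atlas with full-length (T = 275) sessions for single-run checks, an
8-subject/24-region configuration for pipeline determinism, and the
fast profile route for replicate studies (120–500 cohorts). These sizes
were chosen to keep a full validation run on a single CPU in minutes
while preserving the study's subject and observation counts wherever a
statistical claim depends on them.

## Known limitations

- Wald t with residual df is an approximation; no Kenward–Roger or
  Satterthwaite correction is implemented (calibration was verified by
  simulation at the study's design size only).
- Cohen's d = 2t/√df for a mixed model is a labeled approximation.
- The within-hubs metric's inclusion of DMN–FTPN cross pairs is a
  definitional choice; a sensitivity variant is easy to compute with
  `block_mean` but is not a packaged output.
- The voxel-extraction path averages thresholded voxels without
  probability weighting.
- No preprocessing (motion, nuisance regression, filtering) is
  performed or emulated; inputs are assumed clean parcel time series.
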