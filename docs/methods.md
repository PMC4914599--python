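# Methods

## Design and data model

The analysis targets a repeated-measures single-voxel ¹H-MRS design:
`n` subjects scanned in `S` sessions on different days, each session
acquiring one spectrum per region from a panel of cortical subregions
(default: aMCC, pgACC, pIL, pIR), quantified into a panel of metabolites
(default: mI, Cre, Glu, tCho, tNAA, Glx). The atomic observation is one
water-scaled concentration (arbitrary units) with its CRLB (% fitting
uncertainty) and optional SNR/linewidth/daytime metadata. All statistics
are defined for `S ≥ 2` (`S ≥ 1` for inter-subject quantities); the
reference design is `n = 9`, `S = 4`.

Spectral fitting, water scaling, segmentation and realignment estimation
are upstream tools' jobs; their outputs are this package's inputs.

## Quality gate

Inclusion is decided per (region, metabolite) from the CRLB summary of all
its acquisitions. The default rule is *mean below threshold* (20%): a
mean-based rule is the only one consistent with retaining a cell whose
per-acquisition CRLBs span up to exactly 20% while its mean is ~9%, which
the reference data contain. `all_below`, `any_below` and `median_below`
are available; the rule, threshold and excluded cells are reported. Whether
the original criterion was applied per acquisition or on the mean is not
documented anywhere; the default here is a reconstruction chosen for
consistency with the published per-cell table.

## Voxel geometry and CSF correction

A voxel is an oriented cuboid (center mm, edge lengths mm, orthonormal
rotation). Rasterization marks every grid cell whose center, mapped through
the segmentation affine, falls inside the cuboid; the per-axis test is
half-open (`[−dim/2, +dim/2)`) so lattice-aligned boundaries are never
double-counted. No partial-volume weighting of boundary cells is applied:
with ~1 mm anatomical grids against ≥ 11 mm voxel edges the error is
bounded by the one-cell surface layer (≲ 2·surface/volume), which the
convergence and pose-invariance tests verify. Tissue fractions normalize
the summed GM/WM/CSF probabilities by their total, so probabilistic maps
need no thresholding and near-zero-probability background contributes
nothing; hard label maps are the special case p ∈ {0, 1}.

The partial-volume correction is `C = C₀ / (1 − F_CSF)`, exact under the
assumption that CSF contributes water signal but no metabolite signal and
that GM and WM are not distinguished (no relaxation or tissue-water-content
correction — deliberately matching the reference procedure).

## Movement summaries

Each session's six realignment parameters (translations mm; rotations
converted from radians to degrees on ingest, configurable) are summarized
by the maximum absolute excursion relative to the session's first
(reference) scan — a deliberately stringent summary compared with mean
displacement. Batch summaries report mean, SD and range of the maxima
across sessions. The ANCOVA covariate is `d = √(x²+y²+z²)` of the
translations; rotations are summarized but excluded from `d`, since the
displacement vector is defined over the three translation directions only.

## Variability estimators

* `cv`: sample SD (denominator `n−1`) over mean, ×100. The `n−1`
  convention is used throughout; the original report does not state its
  denominator, but `n−1` is standard for small-`n` reproducibility work.
* Intra-subject CV (default `mean_of_subject_cvs`): per-subject CV across
  sessions, averaged over subjects; the reported intra SD is the mean of
  per-subject SDs. The alternative `mean_sd_over_mean` divides the mean
  per-subject SD by the grand mean. The default was chosen because the
  published per-cell values are consistent with averaged per-subject CVs
  and not with the ratio-of-means in at least one cell.
* Inter-subject CV: per draw, one session is selected independently per
  subject and the cross-subject mean and sample SD computed; the draw means
  and SDs are averaged separately (default 5000 draws) and the CV is
  100·avg(SD)/avg(mean). When the number of combinations `Sⁿ` is at most
  the enumeration cap (10⁶ by default — which includes the reference
  design's 4⁹ = 262 144) the estimator is replaced by exact enumeration,
  making it deterministic. A `shared_timepoint` mode (same session index
  for all subjects, `S` outcomes) exists but is not the default, because
  independent draws are what generates the "different combination
  possibilities" the estimator is meant to average over.
* Aggregates are arithmetic means: region means over metabolites,
  metabolite means over regions, study means over regions, and the
  inter-minus-intra gap.

Estimator expectation: the mean-of-per-subject-CVs estimator is not exactly
unbiased for `100·σ_w/μ` — for Gaussian data its expectation carries the
small-sample factor `c4(S) = E[s]/σ` (0.9213 at `S = 4`) and a second-order
mean-ratio term `(1 + (σ_b² + σ_w²/S)/μ²)`. The parameter-recovery test
checks agreement with this analytic expectation (within 3 Monte-Carlo SEs
per cell over 500 replicates), which is the correct recovery statement for
the estimator as defined. No `c4` correction is applied in the estimator
itself, matching the conventional CV definition.

## Inference

* Repeated-measures ANOVA over sessions: closed-form one-way
  within-subject sums of squares, `F = MS_sessions / MS_(session×subject)`
  with df `(S−1, (S−1)(n−1))`; sphericity is assumed by default (the
  reference analysis reports no correction) with Greenhouse–Geisser epsilon
  optional. The implementation is cross-checked against an independent one
  (pingouin) in the test suite. Subjects with incomplete sessions are
  dropped with a warning; the degenerate all-constant case returns
  `F = 0, p = 1`.
* ANCOVA: ordinary least squares of concentration on dummy-coded
  participant and region fixed effects plus the three continuous covariates
  (GM/WM ratio, daytime in decimal hours, displacement `d`), fitted per
  metabolite by default (a pooled variant standardizes within metabolite).
  Each covariate's partial F equals the square of its t statistic
  (single-df identity, asserted as a property and cross-checked against a
  type-II ANOVA). Rank deficiency raises an error naming the aliased
  columns. Whether metabolites were originally modeled jointly or
  separately is undocumented; per-metabolite is the default here because it
  avoids imposing a shared covariate effect across metabolites with
  different scales.
* CRLB–CV correlation: Pearson r with a two-sided t-test over
  (region, metabolite) pairs of mean CRLB and mean intra-subject CV.
* No multiple-testing correction is applied by default, matching the
  reference reporting. Intra-class correlation is deliberately not
  implemented: its dependence on population heterogeneity makes it
  non-comparable across studies, which is the stated reason the reference
  analysis rejected it.

## Synthetic data

The generator emulates the study conditions:

* Concentrations: `C = μ_cell + b + e` per (region, metabolite) cell with
  `b ~ N(0, σ_b²)` per subject and cell, `e ~ N(0, sd²)` per record,
  truncated at 0. Defaults: `μ` = printed cell means, `σ_w` = printed
  intra-subject SDs, `σ_b = √max(inter² − intra², 0)` back-solved so
  synthetic inter CVs land near the printed ones. A Gaussian (not
  lognormal) hierarchy suffices because every cell's CV is below 17%, so
  truncation is negligible.
* CRLBs are drawn per record from a Gamma law matched to the printed cell
  mean with SD = range/4, clipped to the printed range; the record noise SD
  is `σ_w · (1 + slope·(CRLB − CRLB̄)/CRLB̄)` (slope 1 by default, floored
  at 0.1·σ_w). The link makes noisier fits produce noisier concentrations
  while keeping E[SD] ≈ σ_w; the strong positive synthetic CRLB–CV
  correlation (~0.7–0.8 across seeds) then arises from the printed
  (σ_w, CRLB̄) pairs themselves.
* Tissue fractions: Dirichlet draws around the printed region compositions
  with concentration 200, giving fraction SDs of ~2–3 percentage points as
  printed. Daytime: uniform within one of four 90-minute late-afternoon/
  evening slots per (subject, session).
* Movement: each session's per-axis maximum is drawn from a Gamma law with
  exactly the printed mean ± SD of maxima; the scan trace is a random walk
  rescaled so its extreme equals the drawn value. Ground-truth extremes
  therefore coincide exactly with the session-maximum summary, and batch
  means converge to the targets by the law of large numbers.

What the generator does **not** emulate: spectral lineshapes, session-order
or frequency-drift effects, non-Gaussian outliers, realistic anatomy in the
phantoms, correlated CRLBs within a session. Passing recovery tests
therefore demonstrates correctness of the estimators under the declared
variance-component model, not robustness to every artifact of real spectra.

## Calibration checks and their null models

Type-I calibration of the session rmANOVA is checked on null Gaussian data
at the study design (1000 replicates; rejection within [0.03, 0.07] at
α = 0.05). For the ANCOVA covariates the calibration null generates data
satisfying the model's own error assumptions — between-subject spread as
subject main effects and a homoscedastic within SD with no CRLB link —
because under the study-like defaults two assumption violations
(subject×region random effects, region-dependent noise SDs) make the
covariate tests *conservative* (~0.01–0.02 empirical rejection). Both
deviations push toward under-rejection, so observed covariate
non-significance on study-like data is a fortiori credible.

Power checks use the closed-form noncentral-F power as the oracle: at
`n = 9, S = 4` a single-session mean offset of one within-subject SD has
analytic power ≈ 0.50 at α = 0.05, and the empirical rejection rate is
required to match it within binomial error. A covariate slope sized so the
covariate explains about half the residual variance is detected essentially
always.

## Problem sizes and numerical choices

Simulation-based tests use 500 replicates for parameter recovery (with the
inter-subject estimator in 200-draw Monte-Carlo mode), 1000 replicates for
type-I calibration, and 300–400 for power comparisons; the movement LLN
check uses 4000 sessions and the acceptance script 5000. These sizes give
Monte-Carlo SEs comfortably below the tolerances being asserted.
Enumeration replaces Monte Carlo for the inter-subject estimator up to 10⁶
combinations; random draws use numpy's seeded PCG64 generator, recorded in
the run manifest. Degenerate inputs (zero mean for a CV, zero WM fraction
for the GM/WM ratio, empty voxel–grid intersection, all-zero probabilities
in a mask, constant margins in a correlation) raise typed errors rather
than returning NaNs.

## Known limitations

* The original study's raw per-acquisition data are unpublished, so
  subject-level results cannot be reproduced; all real-data anchors are the
  printed summary tables shipped as fixtures, and synthetic data carry the
  rest of the test burden.
* The intra-subject SD row of the printed table is interpreted as the mean
  of per-subject SDs; a pooled-SD reading is within rounding of most cells
  and is not distinguishable from the publication alone.
* The displacement covariate is defined from translations only, and
  cross-session (as opposed to within-session) referencing of realignment
  is out of scope, as is intra-acquisition motion.
* The ANCOVA is a fixed-effects OLS, not a mixed model; variance-component
  estimation by REML is deliberately out of scope.
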