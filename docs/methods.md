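# Methods

`cortilong` implements a longitudinal surface-based analysis of cortical
thickness for accelerated multi-visit designs: a cohort scanned repeatedly
over months, with the question of whether thickness *slopes* differ between
clinical groups, and whether an individual's early rate of thinning predicts
a later clinical outcome (conversion to psychosis in the reference design).
This note records the models, the synthetic-data assumptions, the numerical
choices, and the limitations.

## Vertex-wise mixed model

At every mesh vertex v the thickness of scan i from subject s(i) is modelled
as

    y_iv = beta0 + beta_t * t_i + sum_g [ beta_g * G_gi + beta_gt * G_gi t_i ]
           + beta_a * age_s + beta_a2 * age_s^2 + beta_x * sex_s
           + scanner terms + b_{s(i)} + e_iv

with t_i the months from the subject's first scan, G_gi treatment-coded
group indicators (reference: healthy controls), age the age at first scan
centred at the sample mean (centring is a pure reparameterisation and
cannot change the interaction test), b ~ N(0, sigma2_b) a subject random
intercept and e ~ N(0, sigma2_e) i.i.d. residuals. The scientific term is
the group-by-time interaction: do thickness slopes differ by group?

Scans acquired more than 12 months after baseline are excluded before
fitting (`filter_scans`), guarding the linear time term against a
right-skewed tail of late visits; post-conversion scans can optionally be
excluded the same way.

**Estimation.** REML through a deterministic one-dimensional profile over
the variance ratio lambda = sigma2_b / sigma2_e. For fixed lambda the
marginal covariance V = I + lambda Z Z' is block compound-symmetric by
subject, so GLS for beta and the profiled sigma2_e are closed-form, and all
quantities reduce to per-subject sums. The profile criterion

    (N - p) log RSS(lambda) + log|V| + log|X' V^-1 X|

is evaluated on a fixed log-spaced grid (lambda = 0 handled as a boundary
solution) and minimised per vertex by safeguarded successive parabolic
interpolation in log-lambda inside the bracketing grid cell (12 iterations
by default; agreement with a dense-matrix generic-optimiser oracle is
~1e-6 relative). Because the design is shared across vertices, the grid
stage is evaluated for all vertices simultaneously and the refinement is
batched, which is what makes full model refits inside the permutation loop
affordable. The per-vertex RSS and log-determinant come from one batched
Cholesky factorisation of the bordered matrix [[X'V^-1 X, X'V^-1 y],
[y'V^-1 X, y'V^-1 y]].

**Inference.** Wald F (2 df) for the joint interaction, Wald T for pairwise
slope contrasts, both with the naive residual degrees of freedom
ddf = N_scans - rank(X) - (N_subjects - 1). Sign convention: a positive T
for "A vs B" means group A thins more slowly. Only the naive df convention
is implemented; a Satterthwaite approximation would require the REML
information matrix of the variance components and was judged out of
proportion for a second-order choice at these sample sizes (the `df_method`
switch documents this and refuses the unimplemented option explicitly).
Whether a random slope is warranted can be checked with
`compare_random_slope`, which fits both variance structures (via
statsmodels MixedLM) and reports the likelihood ratio against the
boundary-corrected 50:50 chi2(1)/chi2(2) mixture plus AIC/BIC; near the
boundary the slope model occasionally fails to converge and the comparison
is reported as unavailable rather than guessed.

## Surface operations

Vertex areas are barycentric (one third of each incident triangle), so
vertex areas sum exactly to the mesh area; the minimum-cluster-area rule
and all ROI means use them. Spatial means are area-weighted by default
because irregular meshes otherwise overweight densely triangulated regions.

Smoothing is iterated neighbour averaging with a symmetric, mass-preserving
one-step operator W = diag(a)^-1 K (K symmetric, row sums equal to the
vertex areas a), which preserves constants, conserves the area-weighted
mean exactly, and cannot increase variance. The iteration count for a
target FWHM uses the accumulation rule FWHM_n ~ c * mean_edge_length *
sqrt(n) with c = 1.54 calibrated on regular icospheres against the
edge-correlation smoothness estimator in the kernel-equivalent convention
(acf(d) = exp(-d^2/(4 sigma_kernel^2))); on a 10,242-vertex icosphere a
10 mm request yields an estimated 10.2 mm. The rule is approximate for very
coarse meshes whose edge length approaches the target FWHM.

Cluster connectivity is edge adjacency (two vertices connected iff they
share a triangle edge); cluster area is measured on the analysis mesh.

## Cluster-extent permutation inference

The interaction p-map is thresholded at p < 0.01 (uncorrected), components
below 100 mm^2 are discarded, and significance is assigned empirically:
subject-to-group labels are permuted (group sizes preserved, all scans of a
subject move together, covariates left in place), the entire vertex-wise
model is re-fitted per replicate, and the maximum retained-cluster area is
recorded — 0 when nothing survives. A cluster's p-value is
(1 + #{null max >= observed area}) / (B + 1), so p in [1/(B+1), 1].
Cluster-mass (area-weighted sum of F) is available as an alternative
statistic. The label shuffle is a permutation without replacement; a
with-replacement variant is deliberately not offered, since it breaks group
sizes and has no standard inferential interpretation. Because covariates
are not permuted, the test addresses group exchangeability conditional on
covariates; group-covariate confounding is therefore not protected against
and should be checked separately.

Per-cluster group contrasts refit the same mixed model on the area-weighted
cluster-mean thickness series; Benjamini-Hochberg FDR is applied across
clusters within each pairwise-contrast family (a pooled family across all
contrasts is available by flag). BH itself is delegated to statsmodels.

## Percent change and group comparison

For a subject with thickness T1 at the first scan and T2 at the second
(`scan2` variant, shortest observable interval) or last (`final`) scan,

    PC = ((T2 - T1) / T1) / delta_months * 100        [% per month].

The parenthesisation is chosen so that PC is a per-month normalised
relative change — the only reading that makes the statistic comparable
across subjects with different interscan intervals. PC is scale-invariant
in thickness. Subjects with one scan are excluded and counted. Group
comparisons are OLS with age, age^2, sex and scanner covariates (one record
per subject, so no random effects are needed), all three pairwise contrasts
tested and BH-corrected across ROIs within contrast.

The ROI is the union of same-hemisphere clusters from the discovery stage,
frozen and reused. This two-stage structure is inherently circular — the
ROI was selected on the same data — so PC group contrasts in the discovery
sample are descriptive; the individual-level prediction analyses are the
check against over-reading them.

## Conversion prediction

Logistic regression among CHR subjects only (controls excluded), four
nested predictor sets (pc + demographics + scanner; pc + scanner; pc only;
demographics only), deterministic Newton fits with separation detection;
linearly dependent predictor columns (e.g. a constant pc) are dropped and
reported with zero coefficients. Accuracy is the in-sample AUC, equal by
construction to the Mann-Whitney concordance with ties counted 1/2, hence
invariant to any strictly monotone transform of the scores. The 95% CI is
a case-resampling bootstrap (subjects resampled with replacement, model
refit, in-sample AUC per replicate; percentile 2.5/97.5), unstratified by
default with a stratified option; single-class resamples are skipped and
counted, and >20% skips abort with a diagnostic. In-sample AUC matches the
two-stage discovery design it serves; no cross-validation is applied by
default, and the optimism that implies is a documented limitation.

## Scanner reliability

Travelling-subjects design: every subject scanned at every site on two
successive days. The ICC form is ICC(2,1) — two-way random effects,
absolute agreement, single measurement — because systematic scanner
offsets are exactly the error of concern; ICC(3,1) (consistency) is
available for comparison. Between-site ICC uses day-averaged values with
sites as raters; within-site test-retest treats days as raters.
`average_icc` reports the unweighted mean across parcels before and after
excluding named scanners. Incomplete crossed tables are rejected rather
than imputed.

## Synthetic cohort generator

The generator is the package's test bed and defines its study conditions:

- Groups 62 HC / 338 CHR-NC / 42 CHR-C; scans targeted at 0/2/4/6/8 months.
- Visit jitter: Gaussian (sd 0.75 months) around the scheduled month,
  truncated so follow-ups stay after baseline; baseline itself is exact.
- Dropout: independent per-visit Bernoulli after baseline, NOT monotone (a
  missed visit does not end follow-up). Per-group probabilities 0.325 (HC)
  and 0.575 (CHR) calibrate the expected scans per subject to 3.7 and 2.7.
- Conversion times for CHR-C: N(8.8, 7.6) months truncated at 0.5; scans
  after conversion are flagged, never removed.
- Thickness: a smooth baseline field (white noise smoothed with the
  package's own smoother to a 25 mm scale, sd 0.3 mm around 2.5 mm), age
  (-0.01 mm/year) and sex (0.02 mm) effects, subject intercepts (sd 0.25
  mm), per-scanner offsets (sd 0.05 mm), a background slope of -0.002
  mm/month everywhere, and group-specific extra slopes inside a geodesic
  patch — defaults HC 0, CHR-NC -0.005, CHR-C -0.02 mm/month, encoding
  steepest thinning in converters with non-converters intermediate.
  Residual noise sd 0.12 mm per scan and vertex; values clipped at 0.5 mm.
- Travelling subjects: 9 subjects x 9 sites x 2 days x 68 parcels; subject
  sd 0.12 mm, site bias sd 0.04 mm, day noise sd 0.03 mm, with designated
  unreliable sites receiving 3x noise — levels chosen so that mean ICC
  sits near 0.7 with the noisy sites included and near 0.87 without them,
  emulating the reliability contrast such designs are meant to expose.

What the generator does *not* emulate: registration error, motion and
segmentation artifacts, spatially varying residual correlation beyond the
smooth baseline field, site-by-group confounding, non-linear trajectories,
and informative dropout. Passing tests therefore demonstrate statistical
correctness of the machinery under the stated model, not robustness to
those real-data pathologies.

Age is entered as age at first scan (time-invariant), matching a model
that carries separate age and time terms. Whether non-converter thinning
is spatially coextensive with converter thinning is left open in the
generator: each group has its own slope inside the (shared by default,
configurable) patch.

## Numerical and validation choices

- Determinism: every stochastic component takes a seed; permutation and
  bootstrap replicates derive per-replicate streams from spawned seed
  sequences, so results are bit-reproducible.
- The lambda grid spans [1e-4, 1e4] (plus 0); optima at the upper edge are
  returned as-is (they occur only when residual variance is essentially
  zero). Vertices with non-finite or non-positive residuals are flagged
  non-converged and reported as missing, never fatal.
- Validation strategy (the test suite): the REML path is checked against a
  dense-matrix profile-likelihood oracle and statsmodels MixedLM; cluster
  extraction against a flood-fill oracle; BH and ICC against literal
  hand-computed definitions; AUC against brute-force pairwise concordance;
  the interaction test's null calibration by pooled Kolmogorov-Smirnov
  uniformity (unsmoothed maps, since smoothing induces spatial correlation
  between vertex tests that a pooled KS test would misread); familywise
  error of the cluster permutation by 200-dataset Monte-Carlo at B = 199 on
  a 642-vertex icosphere; and effect recovery by Dice overlap with a
  planted ~300 mm^2 thinning patch. Simulation sizes (16-200 datasets,
  642-vertex meshes, 24-120 subjects) are chosen as the smallest designs
  whose Monte-Carlo error leaves the checked properties clearly decidable.

## Known limitations

- Mass-univariate: no cross-vertex covariance modelling; spatial structure
  is handled by smoothing and cluster-extent inference only.
- The naive df convention is slightly anticonservative in principle for
  small, unbalanced designs; at the reference sample sizes the effect is
  second order (the null-calibration test bounds it empirically).
- In-sample AUC overstates out-of-sample discrimination; the bootstrap CI
  quantifies sampling variability, not optimism.
- ICC assumes a complete crossed travelling design; unbalanced reliability
  data are out of scope.
- The generator's conversion flag is group membership by construction;
  prediction simulations therefore measure signal propagation through the
  pipeline, not clinical prognostic value.
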