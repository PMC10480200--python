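# Methods

## Measurement model

All measurements operate on binary rasters: a trophectoderm (TE) mask
tracing the outer embryo contour with the zona pellucida excluded, and an
inner cell mass (ICM) mask, one pair per time-lapse frame. The coordinate
convention is 0-based pixel indices with `x` = column and `y` = row;
bounding-box extents are inclusive (`max − min + 1` pixels); a rasterized
ellipse contains a pixel when the pixel *center* lies inside the
continuous ellipse. These conventions are stated so every geometric test
can be made exact.

**Blastocyst size** is the mean of the width and height of the tight
axis-aligned bounding box around the largest 8-connected component of the
TE mask, converted to micrometres. Axis-aligned (rather than minimum-area
rotated) boxes are the documented choice; combined with the
largest-component rule this makes the measurement robust to segmentation
speckle, which must not inflate the box. A secondary component at ≥ 50%
of the largest one triggers a logged warning. The μm/pixel scale is a
required input; when omitted it defaults to 1.0 with a warning so purely
synthetic tests stay exact.

**ICM size and shape** come from an ellipse fitted to the mask boundary.
The boundary is the set of foreground pixels of the (hole-filled) largest
component that have at least one 4-neighbor in the background — a thin
8-connected contour whose pixel count for a disk of radius r is ≈ 4√2·r.
Fitting boundary pixels rather than all interior pixels avoids the
systematic low bias an all-pixels fit would have. The fit is the direct
algebraic least-squares ellipse (the conic constrained to be an ellipse,
via scikit-image's numerically stabilized `EllipseModel`); at least 5
non-degenerate points are required. Fitted parameters are normalized to
`major ≥ minor` (swapping axes rotates the angle by 90°) with the angle
in [0, 180)°. ICM size is the long diameter in μm, shape the long/short
ratio (≥ 1 by construction), and the ICM ratio the exact quotient of ICM
size by blastocyst size. On rendered ellipses the boundary-pixel fit
recovers diameters with a ≈ 0.5–1 px inward bias (boundary pixel centers
lie inside the continuous contour), which is the discretization tolerance
used in the round-trip tests.

**Frame selection.** Measurements are taken at a fixed developmental
offset after pronuclear fading (tPNf = hour 0): the default target is
85.98 h, the cohort-mean interval to blastocyst expansion. The frame with
timestamp nearest the target is selected; exact ties go to the earlier
frame (deterministic, and pre-expansion frames are less likely to sit in
a transient collapse). Each embryo is measured on one mask pair; fusion
of multiple focal planes is upstream of this package.

## Segmentation agreement

IOU is |A∩B|/|A∪B| with two conventions fixed by fiat: two empty masks
score 1.0 (agreement on absence), empty versus nonempty 0.0. Summary
fractions count frames *strictly* above each threshold (0.5, 0.75).
Because "overlap in more than 50% of the pixels" is also readable as
pixel recall |pred∩ref|/|ref|, the evaluation stage computes and reports
both rather than guessing silently.

## Synthetic data

The generators stand in for proprietary clinical inputs and define the
conditions under which the pipeline is validated.

*Scenes.* A TE ellipse with aspect drawn uniformly on [1, 1.15] at a
uniform random orientation is sized so the mean of its continuous
bounding-box dimensions equals the requested blastocyst size; the ICM
ellipse has the requested long diameter and elongation, placed at a
random interior offset (falling back to a concentric co-aligned placement
when containment fails), and the image canvas adapts to the TE box plus
an 8 px margin. Masks are rendered by the pixel-center rule, so the ICM
raster is a subset of the TE raster by construction. "Predicted" masks of
controlled quality are produced by translating, dilating or eroding the
reference mask; a perturbation that would empty the mask is an error.

*Cohorts.* Covariates follow the study population's printed moments:
blastocyst size ~ N(147, 19.1) μm; ICM size ~ N(77, 12.5) μm floored at
1 μm (the by-outcome SDs are 12.0 and 12.8 with no pooled value printed;
12.5 is the midpoint and is configurable); ICM shape ~ N(1.41, 0.32)
truncated at 1 (midpoints of 1.43/1.40 and 0.344/0.298); maternal age
~ N(33.5, 6.2) truncated to [19, 45] years by rejection sampling, which
matches the printed range while shifting the mean only ≈ 0.3 y. Age and
the morphometrics are generated independently — no within-class
correlation is reported to calibrate against — which affects only joint
simulations, not recovery of individual coefficients. The ICM ratio is
derived, never sampled. The implantation outcome is Bernoulli with logit
`β₀ + β_size·size + β_age·age + β_icm·icm + β_crit·1[size > mean(size)]`;
the indicator term (against the realized cohort mean) exists so the
mean-split criterion can be the generating truth in recovery experiments.
When a target prevalence is requested the intercept is solved on the
realized covariates by bracketed root finding (Brent on
`mean(expit(β₀ + η)) − target`, bracket ±60), reported as an error when
unattainable rather than silently defaulted. Every generator is a pure
function of (config, seed).

What the generator does **not** emulate: real segmentation-mask
irregularity (lobed TE contours, partial ICM occlusion), optical scale
variation, correlated covariates, morphokinetic event sequences beyond
the tPNf/tEB timestamps, and embryo-level repeated measures. Passing
tests therefore demonstrate correctness of the geometry and statistics
under ideal elliptical masks and independent covariates, not robustness
to clinical segmentation noise.

## Statistics

Group comparisons use the pooled-variance two-sided Student's t-test
(Welch available as an opt-in) and the Pearson chi-square without
continuity correction — both at α = 0.05, with no multiple-testing
correction applied anywhere, stated explicitly. Logistic models are fit
by maximum likelihood (statsmodels' Newton IRLS); odds ratios are
`exp(β)` with Wald 95% intervals at z = 1.96 (not profile likelihood),
matching standard clinical reporting. Complete separation or a singular
information matrix raises a dedicated error; hitting the iteration cap
only flags non-convergence. Age enters models in years, untransformed.

AUC is the Mann–Whitney pair-counting estimator with half credit for
ties (required for the all-ties ⇒ 0.5 identity), computed via midranks in
O(n log n). Its standard error and the paired two-AUC test use DeLong's
structural components: `V10_i` averages the concordance of positive i
over all negatives, `V01_j` symmetrically; variances and the paired
covariance are sample (co)variances of these components scaled by class
size. This implementation is written here because no installed package
exposes the DeLong variance; it is cross-checked in the tests against
exhaustive pair counting and against a bootstrap of the AUC difference.
A zero-variance comparison with zero AUC difference (e.g. scores related
by a strictly monotone transform) returns p = 1 by convention.

The collinearity screen flags covariate pairs with |Pearson r| ≥ 0.6 and
p < 0.05 and recommends exclusions; the ICM ratio is flagged against its
parents by construction. The full report runs: descriptives by outcome,
univariable fits per morphometric, the three-covariate multivariable fit
(ICM size + blastocyst size + age — ICM size retained for clinical
relevance despite univariable non-significance), the variant with the
ICM ratio replacing blastocyst size, and a without-ICM-size variant
(both are emitted rather than choosing); the mean-split criterion with
unadjusted (rate-based and chi-square) and age-adjusted odds ratios; and
ROC for age + criterion versus age alone with the paired DeLong test.
Whether the combined classifier should carry the binary criterion or the
raw size is ambiguous in clinical practice, so the binary-criterion model
is primary and the raw-size variant is reported alongside.

## Recovery experiments and problem sizes

The logistic machinery is validated by parameter recovery: seeded
50,000-embryo cohorts generated with the published adjusted odds ratios
as truth (1.02/μm size, 0.898/year age, 0.987/μm ICM; criterion 1.74) at
32.9% prevalence. At this n the Wald SE of the size coefficient is
≈ 5×10⁻⁴ and of the age coefficient ≈ 1.7×10⁻³ on the log scale, so the
recovered size OR is stable at two decimals while the age OR carries
Monte-Carlo noise of a few 10⁻³ — hence the ±0.005 tolerance on its
3-decimal readout, and ±0.05 on the criterion OR (binary covariate,
SE ≈ 0.02). Property suites use smaller sizes chosen for statistical
sufficiency: 1,000 replicates for type-I-error calibration (binomial
3σ band around 0.05), 500 replicates for the DeLong-SE versus empirical-SD
check (15% band), 10,000 bootstrap draws for the DeLong p-value
cross-check, and 100–500-embryo runs for the end-to-end pipeline.

## Known limitations

* Measurements assume one mask pair per embryo at the measurement frame;
  multi-focal-plane fusion and frame-quality screening are out of scope.
* The bounding box is axis-aligned by definition, so blastocyst size is
  not rotation-invariant for eccentric embryos (the rotation behavior is
  pinned by the closed-form bounding-box tests instead).
* The ellipse fit is algebraic, not geometric, least squares; for the
  near-elliptical, densely sampled boundaries measured here the
  difference is far below the rasterization error.
* Simulated cohorts cannot reproduce the clinical tables themselves —
  the generator's independence assumptions and idealized masks are
  documented above — they validate the estimators, not the data.
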