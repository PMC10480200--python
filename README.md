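# blastomorph

Automated blastocyst morphometry for time-lapse IVF embryology, with the
implantation-association statistics used to evaluate it.

In day-5 blastocyst selection, embryologists grade expansion and the inner
cell mass (ICM) subjectively. Given binary segmentation masks of the
trophectoderm (TE, the outer embryo contour with the zona pellucida
excluded) and the ICM — as produced by a segmentation network or drawn by
an expert — this package computes objective morphometric parameters at the
expanded-blastocyst stage and relates them to known implantation data
(KID: implanted = KIDp, not implanted = KIDn). It is aimed at embryology
and reproductive-medicine researchers who want the measurement and
analysis machinery without the proprietary clinical images: every stage is
exercised end-to-end on synthetic masks and simulated cohorts with known
ground truth.

## The measurements and the model

For one embryo, measured at the cohort-mean interval from pronuclear
fading to blastocyst expansion (tEB − tPNf = 85.98 h):

* **Blastocyst size** `= s · (w_bbox + h_bbox) / 2` — the mean of the
  width and height of the tight axis-aligned bounding box around the TE
  mask, at scale `s` μm/pixel.
* **ICM size** — the long diameter `2a` of the direct least-squares
  ellipse fitted to the ICM mask boundary.
* **ICM ratio** `= ICM size / blastocyst size`.
* **ICM shape** `= a / b` of the fitted ellipse (1 = round, > 1 =
  elongated).

Segmentation quality is quantified by intersection-over-union,
`IOU(A, B) = |A ∩ B| / |A ∪ B|`, with the fraction of frames exceeding
0.5 and 0.75 reported.

Association with implantation uses logistic regression,

```
logit P(KIDp) = β₀ + β_size·size + β_age·age + β_icm·icm ,
```

reporting adjusted odds ratios `exp(β)` with Wald 95% intervals
`exp(β ± 1.96·SE)`; a mean-split criterion (size strictly above the
cohort mean) with unadjusted and age-adjusted odds ratios; and ROC/AUC by
the Mann–Whitney estimator with DeLong variance and the paired DeLong test
for comparing correlated AUCs.

## Worked example

```python
import numpy as np
from blastomorph import (CohortGenConfig, generate_cohort, sample_scene,
                         render_embryo_masks, measure_frame, analysis_report)

# Render one synthetic embryo and measure it back.
rng = np.random.default_rng(0)
truth = sample_scene(rng, blastocyst_size_um=150.0, icm_size_um=75.0, icm_shape=1.3)
result = measure_frame(render_embryo_masks(truth))
print(f"blastocyst size = {result.blastocyst_size:.1f} um")
print(f"ICM size        = {result.icm_size:.1f} um")
print(f"ICM ratio       = {result.icm_ratio:.3f}")
print(f"ICM shape       = {result.icm_shape:.2f}")

# Simulate a cohort with a true per-um size effect (OR 1.02), a per-year
# age effect (OR 0.898) and ~33% implantation, then analyze it.
cfg = CohortGenConfig(n_embryos=5000, seed=1,
                      beta_size=np.log(1.02), beta_age=np.log(0.898),
                      beta_icm=np.log(0.987), target_prevalence=0.329)
report = analysis_report(generate_cohort(cfg))
```

This prints

```
blastocyst size = 150.5 um
ICM size        = 74.1 um
ICM ratio       = 0.492
ICM shape       = 1.30
```

— the requested 150/75 μm geometry is recovered to within rasterization
error (≈1 px). The analysis report on the simulated cohort gives

```
adjusted OR per um of blastocyst size: 1.020 (95% CI 1.017-1.024)
implantation 39.3% above vs 26.5% below the mean size; unadjusted OR 1.80
AUC age+criterion 0.69 vs age alone 0.67 (DeLong p = 0.00)
```

i.e. the multivariable fit recovers the generating odds ratio of 1.02 per
μm, embryos above the mean size implant more often, and at n = 5000 the
criterion's AUC gain over age alone is large enough for the paired DeLong
test to resolve it (at clinical sample sizes the same gain is typically
not significant).

The same flow is available from the shell:

```sh
blastomorph full --seed 5 --out-dir runs/demo --n-embryos 200
```

which writes `cohort.csv`, rendered TE/ICM mask PNGs with ground-truth
JSON sidecars, perturbed "predicted" masks, `morphometrics.csv`,
`iou_report.json`, `report.json` and a run manifest.

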