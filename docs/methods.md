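# Methods

## The measurement problem

Anemia is defined by low blood hemoglobin (Hgb, g/dL); the reference
measurement is the complete blood count (CBC) from a venous draw. The
nailbed contains no melanocytes, so its color is dominated by blood Hgb:
anemic nailbeds are pale, healthy ones red. `nailhgb` estimates Hgb from an
ordinary smartphone-style photograph of the fingernails by combining three
information sources: the QC-filtered nailbed color, the lightness L* of an
adjacent skin patch (a melanin/skin-tone covariate), and the camera capture
metadata (exposure time, ISO, aperture, brightness value, flash flag),
which encodes the ambient lighting the pixel values were acquired under.

The estimate is a multi-linear form

    Hgb = C + Σᵢ Pᵢ·Wᵢ + bias

fitted by iteratively reweighted least squares with Tukey bisquare weights
w(u) = (1 − (u/c)²)² for |u| ≤ c, zero beyond, with tuning constant
c = 4.685, residuals standardized by 1.4826·MAD each iteration,
initialization at ordinary least squares, and convergence declared when the
largest coefficient change drops below 1e−8 (at most 50 iterations; a
non-converged fit is flagged and returns its last iterate). The
redescending weight gives gross outliers exactly zero weight, which is the
property the whole design leans on: a handful of mislabeled or
artifact-laden subjects cannot drag the calibration. When a fit has fewer
than ~p+1 residual degrees of freedom (saturated personal calibrations)
the MAD scale is meaningless and the reweighting is skipped; the fit is
then plain (minimum-norm) least squares, recorded in `fit_info`.

After the robust fit, a uniform bias adjustment — the mean raw residual on
the discovery set — is added so discovery residuals average exactly zero.

## Feature schema

Default (12 features): nailbed mean R, G, B; nailbed mean L*, a*, b*;
skin L*; exposure time (s); ISO; f-number; brightness value (EV); flash
flag (0/1). Nailbed color is averaged per ROI after pixel QC, then
unweighted across usable fingers; the thumb is always excluded. Per-ROI
averages use per-pixel values; Lab summaries are per-pixel Lab then mean
(the Lab transform is nonlinear, so the order matters and is fixed).

The nailbed L*a*b* summaries are smooth functions of the RGB means, so the
two triples are nearly collinear; this leaves predictions unaffected but
makes individual coefficients uninterpretable. Analyses that read
coefficients (recovery checks, insensitivity ablations) therefore use the
`RGB_SCHEMA` variant without the nailbed Lab features. Constant columns
(e.g. a fixed aperture in a single-device cohort) are pruned before
fitting and recorded.

Personal calibration uses `PERSONAL_SCHEMA` = {nailbed mean R} plus the
intercept. Four weekly calibration points cannot identify the full
parameter set, and fitting additional color channels that carry
session-to-session imaging variation rather than Hgb signal inflates
test error by interpolation — empirically it doubled test-week error and
inverted the personal-vs-population ordering. With fewer than 4 sessions
the schema truncates further; at least 2 sessions with distinct CBC values
are required (identical values leave the slope unidentifiable).

## Quality control

Flash glare and leukonychia produce bright, nearly achromatic pixels.
Two rules, both evaluated against the full ROI:

* **bright-achromatic gate** — reject when L* > 90 *and* chroma
  √(a*²+b*²) < 5. Nailbed tissue at any physiologic Hgb is strongly
  chromatic, so this gate never fires on clean pixels by construction.
* **robust-outlier gate** — reject when any channel's
  |x − median| / (1.4826·MAD) exceeds 3.5. This catches off-range pixels
  the absolute gate does not anticipate. On 8-bit images with pixel noise
  around 2 units the quantized MAD makes this gate trim roughly 1–2% of
  symmetric tails on perfectly clean ROIs; the trimming is symmetric and
  does not move the ROI mean.

An ROI retaining fewer than 50% of its pixels is unusable and excluded;
a subject with no usable non-thumb ROI is excluded with pooled
rejection-reason counts.

## Synthetic study conditions

No public dataset pairs fingernail photos with CBC Hgb, so the package
ships a forward model that generates the study conditions every test and
the acceptance script run on. Defaults:

* **Color law.** Nailbed sRGB = (180, 98, 92) at the 12 g/dL reference,
  changing by (5.5, 0, 0) per g/dL, so the physiologic 5.9–16.8 g/dL range
  spans ≈ 60 units of 8-bit red without clipping. The red channel is
  deliberately the only Hgb-coupled channel: green/blue receive independent
  per-session variation (sd 3 units). This makes the red mean a sufficient
  statistic, so the inverse regression has unique ground-truth
  coefficients (C* = 12 − 180/5.5 ≈ −20.73, W_R = 1/5.5 ≈ 0.1818, all
  other weights 0), against which recovery can be measured. No claim of a
  physiological color-vs-Hgb slope is made; the magnitude is chosen to
  exercise estimator linearity, not to model hemoglobin optics.
* **Measurement variability** is injected on the Hgb scale: the color is
  driven by an effective Hgb = true Hgb + subject offset (sd 1.1 g/dL) +
  session term (sd 0.5 g/dL). Total sd 1.208 g/dL puts the population 95%
  LoA near ±2.37 g/dL — screening-grade accuracy — while the split into a
  persistent and a transient part is what personalized calibration can and
  cannot remove (personal test LoA lands near ±1 g/dL).
* **Lighting.** Ambient lux is log-uniform over 79–790 (a 10-fold range).
  Flash-on photos are lighting-normalized (gain 1); flash-off photos get a
  multiplicative gain interpolated log-linearly onto [0.9, 1.1]. Metadata
  tracks lux: brightness value follows log2 lux (strongly without flash,
  weakly with), ISO and exposure time couple inversely to lux without
  flash, and all metadata carries 2–5% jitter (exactly constant metadata
  would make the training design singular; real auto-exposure is never
  exactly constant). The f-number stays fixed and is pruned at fit time.
* **Skin.** Surrounding skin is rendered at a subject-level L* drawn
  uniformly from [30, 90] with fixed chromaticity (a*, b*) = (13, 17),
  independent of Hgb by construction.
* **Geometry.** 640×480 images; five 30×30 px nailbed ROIs (900 px²,
  ≈10 mm² at the emulated magnification; thumb = finger 1) and one 30×30
  skin patch at fixed, emitted coordinates — ROI selection is manual in
  the intended use, so coordinates are data, not detections.
* **Artifacts.** Leukonychia = desaturated high-L* discs (235, 232, 228);
  specular flash highlights = near-white discs (250, 250, 250); both lie
  outside the expected color range by construction and are placed wholly
  inside non-thumb nailbed ROIs (artifacts in the excluded thumb cannot
  affect the measurement). Pixel noise is Gaussian, sd 2 units/channel.

Everything is deterministic given a seed; cohorts are generated lazily
(a rendered photo pair is ~1.8 MB).

What the generator does **not** emulate: real nail geometry and texture,
camera optics, white-balance processing, nail polish or disease
discolorations, and any physiologically calibrated color law. Passing
tests therefore demonstrate that the estimator recovers the structure it
assumes — monotone color coupling, metadata-encoded lighting, decoupled
skin tone — not that it measures Hgb in real photographs.

## Training protocols

**Population screening.** The cohort (337 subjects by default) is split
without replacement into a discovery group (237) and a testing group
(100); the model is fitted with bias adjustment on discovery and scored on
testing; the procedure repeats 1000 times with fresh random splits, and
the repeat with minimum test mean |residual| becomes the screening model.
The full per-repeat distribution of test MAE/LoA is returned because
min-selection is optimistic: over 1000 splits of fixed per-subject
residuals, the selected repeat's test LoA runs ≈ 0.75–0.9× the
generator's theoretical 1.96σ, while the median over repeats is unbiased.
Split hygiene is asserted by subject-id audit.

**Personalized calibration.** One subject, 8 weekly sessions: the first 4
(one transfusion cycle in the chronic-anemia use case) calibrate a
personal model; weeks 5–8 test it. The personal fit removes the
subject-level offset, which is why its LoA beats the population model's
on the same sessions.

## Evaluation statistics

* Bland–Altman: bias = mean(pred − ref), 95% LoA = bias ± 1.96·sd; the
  correlation between difference and pairwise mean is reported as the
  proportional-bias check. The 1.96 multiplier is used at all n.
* Repeated measures: differences are decomposed as d_ij = μ + b_i + e_ij.
  σ²_w is the pooled within-subject variance; σ²_b is the population
  variance of subject means minus its within-subject sampling share
  (floored at 0); LoA = μ ± 1.96·√(σ²_b + σ²_w). This moment estimator is
  chosen for closed-form reproducibility on 4-subject designs; it carries
  a (k−1)/k small-sample bias in σ²_b, negligible against the sampling
  noise of such designs.
* ROC/AUC: anemia = reference Hgb strictly below the cutoff (ties at the
  cutoff are non-anemic); score = −predicted Hgb; AUC is the Mann–Whitney
  pairwise probability with ties counted ½.
* Sensitivity/specificity CIs: Wilson score ("efficient-score") intervals,
  no continuity correction by default (a corrected variant is available).
  Exact coverage of the uncorrected interval dips to ~0.91 at n = 10 near
  the extremes — a documented property of the score interval, not an
  implementation artifact.
* ICC(2,1): two-way random effects, absolute agreement, single rater, from
  ANOVA mean squares with the standard F-based 95% CI; complete matrices
  only (no imputation).
* CLIA fraction: share of measurements with |pred − ref| ≤ 7% of the
  reference, boundary inclusive.

## Numerical choices and degenerate inputs

* IRLS scale uses the MAD about the residual median; a (near-)zero scale
  means an exact fit and terminates with unit weights.
* Rank-deficient designs raise an error naming the collinear columns
  (pivoted-QR diagnosis); the personal path opts into minimum-norm least
  squares instead.
* 8-bit quantization limits "noiseless" accuracy to ±0.5/5.5 ≈ 0.09 g/dL;
  exactness tests use Hgb values aligned to the color grid (multiples of
  1/5.5 g/dL around 12).
* User-facing Hgb is displayed at 0.1 g/dL (CBC convention); all internal
  comparisons use full precision.
* Prediction requires the feature schema to match the model's; supersets
  are subset by name, anything else is a schema error.

## Problem sizes

The test suite and the acceptance script use the study sizes above
(337-subject cohorts with 1000 split repeats, 300-subject insensitivity
cohorts, 200 QC trials, 8-subject serial studies); a full acceptance run
regenerates every input from its seed and completes in about half a
minute on one CPU.

## Known limitations

* The linear color law and the Hgb-scale noise model are stipulations;
  real nailbed colorimetry is nonlinear in Hgb, device- and
  white-balance-dependent.
* The bright-achromatic gate targets near-white artifacts; pigmented
  artifacts (polish, medication darkening) are out of scope, matching the
  intended exclusion of such subjects upstream.
* The screening model selected by minimum test MAE across repeats carries
  selection optimism (quantified above); the reported per-repeat
  distribution should accompany any headline number.
* ICC confidence intervals assume complete balanced matrices and
  normality.
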