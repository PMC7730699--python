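# Methods

## Scope and model

`pollensense` implements a sensometric fusion pipeline for bee pollen of
five botanical origins (lakeshore bulrush, sunflower, red clover, rapeseed,
spiny plumeless thistle; the first and last are polyfloral loads sharing
*Carduus acanthoides* pollen). Four instrument blocks describe the same 15
preparation units (5 origins × 3 replicates):

* **colour** — CIELAB readings per sample (10 per origin);
* **NIR** — transmission spectra, 900–1700 nm at 3 nm steps, 5 consecutive
  scans per unit (n = 75);
* **e-tongue** — 7 potentiometric sensors, 4 measurement sessions per unit
  (n = 60), subject to additive sensor ageing between sessions;
* **e-nose** — an ultra-fast GC sensor array (59 Kovats-index-labelled
  channels), one observation per unit (n = 15).

The analysis chain is: block-specific pretreatment → PCA / pooled-covariance
LDA classification by botanical origin → single-block and low-level-fused
NIPALS-PLSR prediction of 18 sensory attributes and 5 colour parameters,
with leave-one-unit-out cross-validation and a two-round prediction-based
outlier screen. A trained-panel quantitative descriptive profile (14
assessors × 2 sessions, 0–100 scale) is analysed by balanced two-way ANOVA
with Tukey HSD letters.

## Colour arithmetic

Chroma and hue are the polar form of (a\*, b\*): C\*ab = √(a\*² + b\*²),
h_ab = atan2(b\*, a\*) mapped to [0°, 360°). ΔE\*ab is the Euclidean
distance in (L\*, a\*, b\*), ΔC\*ab the absolute chroma difference, and
Δh_ab the plain absolute hue-angle difference taken the short way around
the circle — not the CIE ΔH\*ab chord metric; the plain difference is what
reproduces the published pairwise table. Perceptibility categories use
closed-left intervals at 1.5 / 3.0 / 6.0, so a ΔE of exactly 1.5 is already
"perceptible" (the published footnote's strict inequalities leave
boundaries unassigned; closed-on-the-left is chosen for determinism). The
achromatic point a\* = b\* = 0 has hue 0° by convention. All derived values
are computed from unrounded inputs; comparisons against published numbers
use tolerances reflecting their one-decimal rounding.

## Pretreatment

**Savitzky-Golay** smoothing uses a 21-point window, order-2 polynomial, no
derivative. At the spectrum ends the polynomial is fitted on the truncated
asymmetric window rather than on padded or reflected data — no samples are
fabricated. **MSC** regresses each spectrum on a reference (default: the
training-block column mean) and removes the fitted gain and offset; the
reference is returned so held-out spectra are corrected with the training
reference. Spectra are then truncated to the closed interval 950–1650 nm.

**E-tongue drift correction** ("additive correction relative to all
samples") re-centres, per sensor, each session's mean across all samples
onto the sensor's grand mean. Because every session measures the full
sample set comparably, this removes any additive per-session offset exactly
while preserving within-session contrasts. The external reference that
names this method gives no formulas; the re-centring reading is a declared
stand-in and is flagged as such.

**E-nose sensor selection** ranks sensors by the Fisher ratio
(between-class SS / within-class SS) and keeps the top k = 20, ties broken
lexically by sensor id. The instrument vendor's discrimination-power
formula is undocumented, so correctness is asserted through ordering
properties (constant sensors score 0, perfect separators rank first,
ranking is affine-invariant), not vendor-number matching.

**Autoscaling** uses the n−1 SD denominator throughout. By default every
fold-dependent statistic (scaler state, MSC reference, PCA compression) is
fitted on training folds only; a `leakage_safe=False` switch reproduces the
pretreat-everything-once workflow.

## Chemometric models

**PCA** is the SVD of the centred matrix; component signs are fixed so the
largest-magnitude loading element is positive.

**LDA** uses pooled within-class covariance with empirical priors. When
features ≥ observations the data are first compressed to PCA scores
retaining 99% variance, capped at n_obs − n_classes components, fitted on
the training rows only; a ridge of 1e−8 × trace is added if the pooled
covariance is singular. Recognition is the macro-averaged per-class
training accuracy of a refit on all rows; prediction the macro-averaged
stratified 3-fold cross-validated accuracy (default fold seed 42, reported
in output). Discriminant axes ("roots") and their discriminated-variance
shares come from the eigendecomposition of Sw⁻¹Sb. With very few rows per
class and near-isotropic high-dimensional noise, the 99%-variance
compression can retain as many dimensions as the pooled covariance has
degrees of freedom, which makes the metric unstable; this is documented
rather than patched because the spectra the pipeline targets are strongly
low-rank, where the issue does not arise.

**PLSR** is single-response NIPALS. For one response the inner power
iteration has the exact fixed point w ∝ X'y, so each latent variable is
available in one step; the iteration loop is retained with a
cancellation-aware tolerance and extraction stops once the residual X–y
covariance is numerically exhausted. Weight signs are fixed
(largest-magnitude element positive). Cross-validation is
leave-one-group-out over preparation units; for each LV count 1..max the CV
predictions are assembled, the count minimising RMSECV is selected (ties →
fewer LVs), and the final model is refit on all rows. The LV ladder is
capped by the smallest training-fold size, the feature count and the number
of units.

R² uses the n−1 variance convention, R² = 1 − MSE/Var(y, ddof=1), so that
RPD = SD(y)/RMSECV = √(1/(1−R²CV)) holds exactly; negative R²CV values are
reported unclipped. Against this identity the published tables are
internally consistent within 10% for every row with R²CV ≥ 0.4 once the
two-decimal rounding of the printed R²CV is honoured (at R²CV = 0.99 the
rounding interval spans RPD 8.2–14.1, which is why a printed 12.10 is
consistent with the midpoint 10.0).

## Fusion and the two-round workflow

Low-level fusion concatenates the pretreated blocks on the NIR row basis:
per preparation unit, e-tongue rows are paired with the NIR scans in
acquisition order when the counts match and averaged otherwise (default
study: 4 sessions vs 5 scans → the unit mean), and the unit's single e-nose
row is repeated. The fused matrix is autoscaled after concatenation and the
scaling state kept, so each source block is recoverable exactly.

PLSR runs in two rounds. Round 1 fits on all rows; its cross-validated
predictions are screened per sample with whiskers at median ± 1.5·IQR
(taken literally as written in the source protocol; the classic Tukey
quartile ± 1.5·IQR fences are available behind a flag). Values exactly on a
whisker are retained; groups smaller than 3 are skipped with a warning.
Flagged rows are dropped and round 2 refits; if a sample group would empty,
the run aborts with a diagnostic. Outliers are screened per predicted
attribute, so different attributes may retain different rows. Note an
inherent property of prediction-based screening: a corrupted response with
a clean fingerprint leaves the prediction unchanged and is invisible; the
screen catches predictor-side (instrument) outliers, which is what the
recovery tests inject.

## Synthetic study generator

No public data exist for this study, so the generator emulates its
statistical structure with declared, fixed defaults. Design counts follow
the study: 5 × 3 units, 5 NIR scans (n = 75), 4 e-tongue sessions, one
e-nose row per unit, 14 × 2 panel, 10 colour readings per sample.

* **Colour** observings are Gaussian around the published per-origin
  means/SDs.
* **NIR** spectra are a water-dominated base plus five absorption bands
  (1163, 1364, 1415, 1450, 1495 nm) whose class amplitudes are built from
  four orthonormal class contrasts; the dominant contrast loads on the
  1364/1450 nm water bands, so PC1 of the pretreated spectra peaks there.
  Each scan gets multiplicative gain U(0.9, 1.1), an additive offset and
  white noise (SD 0.002 absorbance), giving MSC real scatter to remove.
* **E-tongue** class centres place each monofloral origin far away (12
  signal units) along its own axis of a 4-D embedding while the two
  polyfloral origins sit 4 units apart, making them — and only them —
  confusable at the sensor noise level (SD 1). Additive session drift
  (SD 3) is shared by every observation of a session; drift vectors are
  centred across sessions and noise within sessions, because only the
  relative part of drift is identifiable — with that convention the
  additive correction recovers the drift-free block exactly.
* **E-nose** has 20 informative sensors with linearly graded signal
  strength (graded Fisher ratios) over a 59-sensor pool; the rest are
  noise.
* **Attribute targets** per unit are the published class means plus a
  linear function of three latent unit factors — one expressed in each
  block, each orthogonal to that block's class geometry — plus noise. The
  latent contribution is 0.55 of the between-class SD and the noise 0.03 of
  it, with every attribute's weight vector touching all three blocks. This
  is what makes fusion genuinely more informative than any single block:
  a single block misses the latent factors of the other two.

Rank-4 class geometry in every block is deliberate: with five classes, a
linear model can only represent arbitrary per-class attribute profiles if
the centred class means span the full 4-D class space. Lower-rank
geometries silently cap the achievable R²CV of any linear method.

The separation and noise scales were tuned once so the qualitative outcomes
of the real study emerge — NIR and e-nose perfectly separable, the
e-tongue at roughly 92–100% with only the polyfloral pair confused, fused
R²CV above 0.8 for every attribute — and then frozen; they are not fitted
to any data. What passing these checks shows is that the pipeline recovers
structure it is designed to recover; it does not certify performance on
real instruments, whose noise is not Gaussian, whose drift is not purely
additive, and whose class geometry is not known.

The sensory generator uses additive assessor effects only (no scaling
heterogeneity), since mixed-assessor-model analysis is out of scope. All
randomness flows from one master seed through spawned substreams; equal
seeds give byte-identical studies.

## Sensory statistics

The balanced two-way fixed-effects ANOVA (score = sample + assessor +
sample × assessor, sessions replicating cells) uses the closed-form
balanced sums of squares, which handle the zero-residual-variance corner
exactly (effects with positive SS become infinitely significant instead of
NaN). Tukey HSD compares sample means with the residual mean square and the
studentized range; the compact letter display is insert-and-absorb on means
sorted descending — any valid display is acceptable, tests check pairwise
consistency rather than letter identity. Panel repeatability is reported as
√(residual MS). Published SDs are treated as sample SDs (n−1) with n = 28
per sample-attribute cell. The published panel-performance table (F-Scal /
F-Disag / MAM decomposition) is third-party software output and is not
reimplemented.

A one-way ANOVA from summaries (means, SDs, n per group) reconstructs
significance verdicts from printed tables: MSB = n·Σ(mᵢ−m̄)²/(k−1), MSW =
mean of group variances, F ~ F(k−1, k(n−1)). On the published 18-attribute
profile this finds exactly 17 attributes significant at α = 0.05, with
aftertaste (F ≈ 2.09 < F₀.₀₅(4,135) ≈ 2.44) the sole exception.

## Problem sizes and reproducibility

The default study sizes (75/60/15 rows; 23 attributes × 4 blocks of
two-round leave-one-unit-out PLSR) run in roughly 10 s per study on one
CPU. `scripts/acceptance.py` repeats the full study for five consecutive
seeds derived from `--seed` and reports cross-seed summaries; the test
suite runs the same five-seed battery. All fold assignments, generators and
sub-streams derive deterministically from explicit seeds.

## Known limitations

* The e-tongue drift-correction algorithm is a literal reading of a
  method description whose defining publication gives no formulas.
* The published fused models report 70 observations for every attribute
  despite per-attribute outlier removal; how 75 aligned rows became a
  uniform 70 is not explained and is not emulated — retained counts here
  are attribute-dependent.
* Only single-response PLSR is provided (each attribute regressed
  independently, as in the published tables); no PLS2, OPLS or kernel
  variants, and no mid- or high-level fusion.
* The two-round screen cannot detect response-side contamination (see
  above); this is a property of the published procedure, not of the
  implementation.
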