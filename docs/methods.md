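# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `puncta`. Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## The enrichment estimator

The score targets the question "how much cargo sits on construct-positive
organelles, beyond what diffuse cytosolic cargo would contribute, per unit
of construct expression?".

Per z-slice `z` with a non-empty analysis mask `A_z` (marker mask ∧
construct-positive), with cell region `C_z` and full marker mask `M_z`:

```
raw_z  = mean(cargo | A_z) − mean(cargo | C_z \ M_z)
con_z  = mean(construct | A_z)
```

Cell-level values are unweighted means over the used slices, and
`normalized = mean(raw_z) / mean(con_z)`.

Choices that were genuinely open, and how they were fixed:

- **Unweighted slice averaging.** "Average across z-slices" is read
  literally as an equal-weight mean over slices with a non-empty analysis
  mask; a pixel-count-weighted mean is available via
  `slice_weighting="pixel"`.
- **Ratio of averages, not average of ratios.** `mean(raw_z)/mean(con_z)`
  is stable when a slice's construct mean is small;
  `normalization="mean_of_ratios"` gives the alternative.
- **Background excludes the full marker mask**, not just the analysis
  mask: the subtracted term is cargo signal outside the *organelle* mask,
  i.e. cytosol, not construct-negative organelles.
- **Mean, not integrated, intensity** over masks: integrated intensity
  would couple the score to organelle size. Background is computed per
  slice, then averaged like the other terms.
- **Negative raw values are reported**, not clipped: cargo depletion from
  organelles is informative and the statistics layer handles it.
- The mitochondrial variant is a **fold ratio**
  (`mean on organelle / mean on cytosol`, unity under a uniform cargo);
  `mode="difference"` subtracts instead.

Exactness: on small random stacks the implementation agrees with an
independent per-pixel brute-force oracle to the last bit (same means over
the same pixel sets), and it satisfies the linearity contracts exactly —
cargo gain `g` scales `raw` by `g`, a constant cargo offset cancels, and
construct gain `g` divides `normalized` by `g`.

## Segmentation

Per-slice thresholding (the stack is masked "in each z-slice"), default
Otsu with `fixed:<t>` and `quantile:<q>` overrides, recorded in a
`method_record` that reproduces the mask bit-exactly. An all-constant
slice yields an empty mask rather than an error. Components smaller than
`min_size_px` (default 2) are removed slice-wise.

Object identity for counting and radial analysis is the 8-connected
component of the **2-D maximum projection**: one punctum spanning 2–3
adjacent slices counts once. The construct-positivity threshold defaults
to the per-cell Otsu of the construct channel inside the marker mask — a
pixel-level, auditable version of the "visible construct signal on
organelles" inclusion rule. Cells whose analysis mask is empty on every
slice are excluded with a reason, never silently dropped.

## Radial shell analysis

Shell boundaries are scaled copies of the outline about the user-chosen
center (`center + (k/n)(v − center)`), so shells follow the cell's shape.
Each object's normalized radius is `r = |x − c| / B(θ)` with `B(θ)` the
ray-cast distance from the center to the outline along the object's ray —
for star-convex outlines this is equivalent to point-in-polygon tests
against every scaled boundary but needs a single geometric predicate.
Shell index is `ceil(r·n)` on half-open intervals `(lo, hi]`: a radius
exactly on a boundary goes inward (deterministic tie-break; radii are
rounded to 9 decimals first to absorb float noise). Objects outside the
outline are excluded with a logged warning. Non-star-convex outlines whose
scaled boundaries would cross are detected and reported as an error with
guidance to re-draw.

`n_shells` is configuration (default 10). Aggregation reports the
per-shell sample mean and SD (n−1); a single cell's SD is "not available"
(NaN), not 0.

## The synthetic generator

COS-7-like mode: a random star-convex polygon outline (radial function
with ±25% vertex jitter — star-convexity about the center is guaranteed
by construction, which is exactly what the shell analysis requires);
peroxisomes as 2-D Gaussian spots (σ = 2 px) spanning up to 3 adjacent
slices with a 0.5/1.0/0.5 axial profile; mitochondria as dilated random
polylines carrying `mito_spillover_fraction × construct_level` of
construct and nothing else; diffuse cytosolic cargo background inside the
outline; additive Gaussian noise clipped at zero. Neuron-like mode: a
soma disc, thin neurite and growth-cone fan unioned into one outline,
with requested numbers of peroxisomes placed uniformly inside each ROI
(0.2-µm slice spacing; COS-7 mode uses 0.3 µm).

**Closed-form truth.** Cargo spots reuse the construct spots' exact
spatial profile with amplitude `recruitment_fraction × construct_level`,
and the background is spatially uniform, so profile and background cancel
in the score and the true normalized enrichment is exactly
`recruitment_fraction` — independent of spot shape, mask, construct level
and background. This gives parameter-recovery tests a closed-form target.

**Radial law.** Normalized radius `r = u^(1/(1+radial_bias))` along a
uniform ray. Because shell membership depends only on the normalized
radius, `radial_bias = 1` reproduces the area-uniform law
`P(r ≤ t) = t²` of any star-convex cell (expected shell-k frequency
`(2k−1)/n²`), 0 is perinuclear, larger is peripheral. Expected shell
frequencies are `(k/n)^(1+b) − ((k−1)/n)^(1+b)` — analytically strictly
increasing in `b` for the outermost shell.

Default conditions (chosen once as the standard regime and used by all
calibration runs): 4 × 192 × 192 stacks, 40 peroxisomes, 6 mitochondria,
construct level 120, marker level 150, cargo background 20, noise SD 3,
spillover 0.3. Spots are placed with a 9-px minimum separation so that
projected puncta stay resolvable at Otsu's threshold; above ~25%
spot-area coverage this separation acts as a repulsive interaction that
visibly flattens the radial law, so dispersal calibrations use the
default density. Per-cell seeds are `crc32(master:label:index)`, keeping
panels reproducible and cells independent.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no optical PSF or axial blur beyond the 3-slice
profile, no photobleaching, no Poisson (shot) noise, no intensity
statistics matched to any instrument, mitochondria carry no cargo, and
the cargo capacity of every peroxisome is identical. Estimator biases on
real images (threshold-dependent mask erosion, chromatic offsets) are
exercised only insofar as the Gaussian-spot model reproduces them.

**Known estimator bias under these conditions.** Gaussian spot tails fall
outside the Otsu mask and are counted as background, and construct
spillover crossing the marker mask inflates the denominator; at
recruitment 0.8 the recovered normalized enrichment is ≈ 0.73–0.79 rather
than 0.80. The bias scales with the recruitment fraction (zero under the
null, which is why null calibration centers on 0), preserves ordering
(Spearman recovery ≈ 0.97), and mirrors what a threshold-mask macro does
on real images; it is documented rather than corrected.

## Statistics

- **Welch t** is computed from the closed form (statistic,
  Welch–Satterthwaite df, two-tailed p). Degenerate zero-variance inputs:
  equal means give t = 0, p = 1; unequal means give p = 0 with a warning.
- **Mann–Whitney** uses the exact distribution when n₁+n₂ ≤ 12 with no
  ties, otherwise the tie-corrected normal approximation; the method
  label records which.
- **Dunnett's T3**: all pairwise Welch-type statistics, each adjusted
  against the studentized maximum modulus SMM(k, ν) at that pair's own
  Welch–Satterthwaite ν (k = number of comparisons). The tail probability
  is a seeded Monte-Carlo estimate that integrates the max-modulus
  analytically: `P(SMM > t) = 1 − E_s[(2Φ(t·s) − 1)^k]` with
  `s = √(χ²_ν/ν)` drawn `mc_reps` times (default 100,000). This keeps
  Monte-Carlo noise far below the naive max-of-draws estimator, makes the
  adjusted p monotone in k for a fixed seed, and reduces exactly to the
  Welch p at k = 1. The Šidák bound `1 − (1 − p_raw)^k` is reported as a
  cross-check (the SMM p never exceeds it, by Jensen's inequality). The
  omnibus one-way ANOVA F is reported but gates nothing. Under the null
  (3 groups, n = 15) the measured family-wise error is ≈ 0.045 — T3's
  well-known mild conservativeness under the positive dependence of
  pairwise statistics sharing groups.
- **ROUT at rate Q** adapted to a univariate column (constant model):
  robust center by IRLS with Lorentzian weights `1/(1 + (r/RSDR)²)`
  starting from the median; `RSDR = P68.27(|residuals|) × n/(n−1)`;
  per-point scores `|r|/RSDR` referred to t(n−1); outliers by the FDR
  step-up ladder at rate Q — the i-th largest residual is compared
  against `(Q/100)·i/n` read in Benjamini–Hochberg order, so the single
  most extreme point faces Q/n. Measured on clean normal n = 15 data at
  Q = 1%: ~1.5% of datasets flag anything; a 10σ contaminant is flagged
  with power ≈ 1. Constant data yield no outliers.
- **Tukey box summaries** use type-7 (linear-interpolation) quartiles,
  fixed and documented because the outlier set depends on the quartile
  dialect; whiskers reach the most extreme points within 1.5 IQR.
- The outlier rule (none / ROUT / Tukey) is an explicit per-analysis
  configuration choice, applied per condition before testing, with
  flagged rows retained and marked in the output.

## Pipeline and provenance

Runs are driven by one YAML/JSON config (manifest, channel roles,
segmentation/enrichment flags, shell count, statistics block). Filename
blinding assigns order-scrambled opaque codes (`blind_0000`…) with the
reversal map stored separately. Outputs are CSV tables plus a provenance
JSON recording the package version, full config and per-run counts; runs
with fixed seeds are byte-identical. Library functions and scripts are
the primary interface; the `puncta` CLI (`make-fixtures`, `blind`,
`coloc`, `radial`, `counts`, `stats`) is a thin layer over them.

## Problem sizes

Calibration suites run at desk scale, chosen as the package's standard
validation conditions: 200 random small stacks for oracle equivalence;
50 cells for null calibration; 4 × 20 cells for recovery; 15 cells per
condition for the recruitment contrast (and 9 neurons per condition for
the ROI contrast), matching the study design the generator emulates;
10,000 simulated datasets for the T3 family-wise error (with
`mc_reps = 4000` per call) and for ROUT calibration.

## Limitations

No 3-D object splitting (touching organelles merge in projection), no
learning-based segmentation, no intensity-weighted or 3-D radial
profiles, no pixel-wise co-localization coefficients (Pearson/Manders),
and no mixed-effects modeling of replicate nesting — per-cell values are
pooled within conditions.
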