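# Methods

`ifhdr` implements a high-dynamic-range (HDR) processing chain for PD-L1
immunofluorescence (IF) microscopy, the area-proportion quantification used to
compare IF against chromogenic IHC, and the agreement statistics used to
compare raters and imaging conditions. Everything is exercised on a seeded
synthetic phantom so that each stage has a ground truth.

## Camera response recovery

A 12-bit camera observing scene irradiance E at exposure time dt records
Z = f(E·dt). Following the classic log-exposure formulation, the inverse
log-response g satisfies

    g(Z_ij) = ln E_i + ln dt_j

for sample pixel i in frame j. g is recovered by regularized linear least
squares over quantized intensity levels with the triangular ("hat")
confidence weight w(z) — zero at both clipped extremes, maximal at
mid-range — on both the data terms and a second-difference smoothness
penalty, and the gauge fixed by g(mid) = 0. Per-sample ln E_i nuisance
unknowns are solved jointly and discarded.

Two specializations adapt this to IF:

* **Nuclei-proximal sampling.** Candidate pixels lie inside the
  counterstain-segmented nuclei mask dilated by a disc (default radius 5 px)
  and at or above the 50th intensity percentile of that band in the medium
  exposure; 2048 samples are drawn without replacement, stratified over a
  4×4 spatial grid. The percentile keeps the samples on membranous signal
  rather than empty interstitium; it is deliberately not higher, because the
  least-squares system only constrains g at levels that receive samples and
  the full output range must be covered. With fewer than ~800 samples at
  12-bit resolution, too few levels receive 5+ informative observations.
* **Virtual exposures.** Each original PD-L1 frame contributes a second,
  "virtual" frame — a Gaussian blur (sigma 2) of its grayscale erosion
  (disc radius 3) — carrying the same exposure time. Virtual frames
  suppress isolated noise and enter both the fit and the merge. Because an
  eroded/blurred frame observes a locally modified scene, its observations
  get their own per-sample irradiance unknowns; tying them to the original
  frame's unknowns measurably biases the recovered curve.

**Resolution.** The system is solved at the native 4096 levels (sparse
normal equations with a 1e-9 ridge; ~0.1 s). Coarser binning is supported
but not used by default: with 256 bins, the lowest occupied bin spans
camera values 16–31 — 0.69 in log units — which both distorts the dim end
of the curve and collapses background and the dimmest signal decade to a
single value in the merge. Levels never observed with nonzero weight are
filled by linear interpolation between observed ones. Default smoothness
λ = 10 on the 4096-level scale.

## Radiance merge and display chain

Per pixel, over original and virtual frames,

    ln E(p) = Σ_j w(Z_j) [g(Z_j) − ln dt_j] / Σ_j w(Z_j).

Observations at or below a noise floor carry no weight. The floor defaults
to the histogram mode plus 3 robust standard deviations (1.4826·MAD) of the
longest original frame — a standard robust background ceiling for darkfield
images. Pixels with zero total weight are filled by a fallback: bright-clipped
pixels from the shortest exposure at its clipped level; dark pixels at the
floor radiance of the longest exposure. The merge therefore reports a
constant floor value where irradiance is genuinely unresolvable (a few
counts against read noise of similar size) instead of meaningless per-pixel
jitter.

For display and downstream 12-bit processing, exp(ln E) is affinely mapped
onto the [min, max] pixel range of the original frames, then enhanced by,
in order:

1. **Mean-anchored gamma.** With x = image/4095 and μ = clip(mean(x),
   0.01, 0.99), the exponent γ = ln(t)/ln(μ) maps the mean onto a target
   t (default 0.25); an image already at the target is unchanged, and the
   map is pointwise monotone with fixed endpoints.
2. **CLAHE.** Classic tile-histogram CLAHE (default 8×8 tiles, 256 bins,
   clip limit 2× the mean bin count): clipped excess is redistributed
   evenly, each tile's map is the min–max-normalized mid-point cumulative
   histogram, and pixels blend the four surrounding tile maps bilinearly.
   The mid-point/min–max construction makes the operator symmetric under
   value complement and reduces to global histogram equalization for one
   tile and a large clip limit. Constant images pass through unchanged.
3. **Top-hat contrast.** out = clip(image + whitehat − blackhat) with
   grayscale opening/closing by a disc (default radius 7), boosting bright
   membranous detail and deepening dark gaps.

The order gamma → CLAHE → top-hat is fixed. Over z-stacks the whole chain
runs independently per layer.

## IHC and IF quantification

IHC images are mapped to optical density, OD_c = −log10((pixel_c+1)/I0),
and the hematoxylin/DAB stain vectors estimated by the Macenko procedure:
discard pixels with any OD component ≤ 0.15, take the top-2 principal
directions of the uncentered OD cloud, and read the stain vectors at the
1st and 99th percentile projection angles. The vector with the smaller
blue OD component is hematoxylin (a blue stain absorbs blue least; the
conventional hematoxylin OD vector is (0.65, 0.70, 0.29)). Concentrations
come from the basis pseudo-inverse, clipped non-negative.

The area proportion of PD-L1 expression is the fraction of annotated-tumor
pixels strictly above a threshold — Otsu within the annotation by default,
or a fixed value; the rule and threshold are recorded in every result.
Physical area uses the scanner pitch (0.465 µm/px IHC, 0.334 µm/px IF).
The proportion approximates but is not the pathologist tumor proportion
score; TPS categories (<1%, 1–49%, ≥50%, boundaries per the labels) and
the <100-tumor-cell exclusion are separate, explicit operations.

## Agreement statistics

Rater-vs-reference confusion matrices over the ordered TPS categories are
summarized by accuracy (trace/total) and weighted kappa,
κ = (P_o − P_e)/(1 − P_e) with linear (default), quadratic, or identity
weights; the scheme is a mandatory field of every result. Linear weights
reproduce the published Pathologist-1 HDR value (0.783 → 0.78) on the
printed matrix; the other printed kappas are not exactly reproduced by any
of the three schemes (recomputed 0.79/0.52/0.82 against printed
0.78/0.56/0.83), so only accuracies and that one kappa are asserted
numerically. Reliability bands (poor/slight/fair/moderate/substantial/
almost perfect) apply to κ rounded to two decimals; a rounded 0.00 —
a gap in the conventional band list — maps to "slight". One-sided paired
Student's t-tests (Welch optional for unpaired data) compare absolute
quantification errors between imaging conditions.

## The phantom

A field of disc nuclei (radius 6–10 px) at rejection-sampled non-overlapping
centers; 80% carry a 3-px membrane annulus. Ring irradiances are a seeded
permutation of values evenly spaced in log10 over 3 decades (stratified
log-uniform — i.i.d. draws would fail the guaranteed max/min ≥ 1000 span),
anchored at 1 for the dimmest ring. Background autofluorescence is a
constant 0.55. The camera response is a gamma-0.8 power law quantized to
12 bits with additive Gaussian read noise (sd 2 counts), with full well at
(brightest ring irradiance) × 50 ms. Under the protocol's exposures
{6.5, 25, 55} ms this produces, by construction, the three failure modes
the HDR chain addresses: at 6.5 ms the dim decade falls into read noise
(some pixels at 0), at 55 ms the brightest rings clip at 4095 and the
background's upper noise tail crosses the detection threshold, and 25 ms is
the best single exposure. The same truth renders a brightfield IHC
counterpart by Beer–Lambert absorption with unit-normalized Ruifrok-style
H/DAB vectors: hematoxylin concentration 0.8 on nuclei, DAB affine in
log10 irradiance on membranes (0.2 + 0.3·log10 E).

What the phantom does *not* model: tissue texture, optics (PSF, glare,
bleed), shot noise, registration error, and spatially varying background.
Passing tests therefore demonstrate the numerical correctness and the
qualitative failure-mode phenomenology of the pipeline, not its performance
on real slides.

## The exposure-comparison experiment

Each synthetic case measures the PD-L1 area proportion four ways against
the generator's membrane fraction. The three single-exposure arms use the
protocol's fixed detection threshold — background + 5 read-noise sd,
calibrated once on the properly exposed 25 ms frame and applied unchanged
to all three frames, as a fixed-threshold instrument would be. This
instrument is what exposes the failure modes: the 6.5 ms arm loses dim
membranes below the threshold (under-measurement), the 55 ms arm lifts
background noise across it (over-measurement). An adaptive rule such as
Otsu cannot play this role: it is equivariant under the near-affine
intensity rescaling between exposures, so all three frames would select
essentially the same membrane subset. The HDR arm thresholds the merged
log-irradiance map — which has no camera-count scale — by the triangle
rule, the standard histogram threshold for a dominant unimodal background
with a sparse signal tail.

Median absolute errors over an 8-case study (512×512 fields, ~4 s total)
reproduce the published qualitative ordering — HDR < medium < short <
long — with significant one-sided paired t-tests; the published magnitudes
themselves (median errors of 0.15%/1.16%/9.32%/12.55%, P = 0.024 and
P < 0.0003, the interobserver-agreement counts, and the 3D depth gradient
of TPS) derive from the study's 30 real NSCLC cases and are not
reproducible from synthetic data; they are covered qualitatively only.

## Numerical choices and edge cases

* Thresholding is strictly-above; pixels at the threshold are negative.
* Otsu on a constant region, kappa with degenerate marginals, t-tests with
  zero-variance differences, empty annotations, and single-stain OD clouds
  all raise informative errors rather than returning NaN.
* quantize_levels maps v → floor(v·levels/4096), monotone with fixed
  endpoints; 4096 levels is the identity.
* 12-bit values travel in 16-bit TIFF containers; values above 4095 are
  rejected, not clipped, to surface acquisition errors.
* All randomness flows through explicit integer seeds; one
  `numpy.random.Generator` per operation, no global state.
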