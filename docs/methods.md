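# Methods

This note documents the models, numerical choices and limitations behind
`ramantdm`. The package implements a complete analysis chain for
resonance-Raman therapeutic drug monitoring (TDM) of piperacillin in urine:
spectral conditioning, PLS concentration calibration, estimation of
concentration losses caused by clinical sample preparation, donor-sex
classification, and reference-matrix-dependent detection limits. All
analyses are exercisable end to end on synthetic spectra from the built-in
generator.

## Spectral conditioning

Quantification pipelines condition raw spectra in a fixed order:

1. **Wavenumber calibration** — a least-squares polynomial maps measured to
   reference peak positions (calibration standards such as acetonitrile,
   Teflon and toluene); intensities are linearly resampled onto the target
   grid. The map must be strictly increasing over the fitted range.
2. **Truncation** to 1800–800 cm⁻¹ (closed interval).
3. **Savitzky–Golay smoothing** with polynomial order p = 2 in an n = 5
   window. Edges evaluate the terminal-window polynomial (scipy
   `mode="interp"`), so polynomials of degree ≤ 2 are reproduced exactly
   everywhere; interior white-noise variance shrinks by the sum of squared
   window weights, 595/1225 ≈ 0.486.
4. **EMSC** (extended multiplicative signal correction), degree 6, against
   the median spectrum of each sample's replicates. Each spectrum is
   decomposed as `x = b·reference + Σ aₖ Pₖ + e` with Legendre polynomials
   Pₖ on the axis rescaled to [−1, 1]; the corrected spectrum is
   `(x − Σ aₖ Pₖ)/b`. Dividing by `b` (the standard EMSC convention)
   removes multiplicative scatter; the polynomial term removes additive
   contamination up to degree 6 exactly. A scale factor |b| < 10⁻⁸ raises a
   degenerate-fit error. Using the *per-sample* median (rather than a grand
   median) keeps the correction local to each sample's replicate group; a
   different reference can be passed explicitly.
5. **SNIP baseline removal**, 20 iterations, clipping-filter order 2, with
   the log-log-sqrt (LLS) compression transform applied before clipping and
   inverted after. The clipping window grows from 1 to 20 channels.
   **On the meaning of "order":** in the peak-clipping literature (and the
   R implementation that popularized it) filter orders are even — order 2
   is the plain symmetric two-point mean `(y[i−m]+y[i+m])/2`, order 4 adds
   the four-point filter `(4(y[i−m/2]+y[i+m/2]) − (y[i−m]+y[i+m]))/6`. We
   follow that convention. An alternative reading ("second-order" = the
   four-point filter) leaves ~40 % of a σ = 8 cm⁻¹ band in the baseline at
   20 iterations, which would contradict the near-lossless band recovery
   the method needs (order 2 recovers ≥ 99 % of such a band on a linear
   ramp); both variants remain available through the `order` argument.
6. **Task truncation and normalization** — PLS models use 1750–1150 cm⁻¹
   and vector normalization (unit Euclidean norm); difference-spectrum
   quantification uses maxima normalization at the ~1605 cm⁻¹ urea
   C=O band (window ± 15 cm⁻¹).

The full chain is invariant to per-spectrum affine distortion (gain 0.5–2,
offsets of tens of counts) to better than 1 % channel-wise RMS.

## PLS calibration and component selection

PLS regression maps conditioned spectra to concentration. X is
column-centered (no per-channel scaling — channels share units), y is
standardized internally and predictions are returned in µM. The component
count is chosen from {3, 4, 5} by minimizing the mean cross-validated RMSEP
over 50 repeated random 80/20 splits; ties go to the smaller count.
"50-fold" cross-validation cannot mean 50 disjoint folds at these sample
counts, so repeated random splits are used. Two safeguards shape the
splits: replicate spectra of one physical sample always stay on the same
side (no leakage), and the training partition must span the full
concentration range (the minimum and maximum calibration levels stay in
training, so the model never extrapolates during selection). Out-of-range
predictions at predict time are flagged, never clipped.

## Treatment loss factors

A preparation step (freezing `froz`, filtration `filt`, centrifugation
`cent`, or filtration + centrifugation `filt_cent`) scales the effective
analyte concentration by (1 − f). Given set concentrations and PLS
predictions of treated aliquots, f minimizes

    RMSEP(f) = sqrt( 1/n Σᵢ (c_set,i − c_pred,i / (1 − f))² )

The objective is strictly convex in g = 1/(1 − f), so the minimizer is the
through-origin regression slope a* = Σ c_set·c_pred / Σ c_pred² with
f = 1 − 1/a*; a brute-force grid search exists in the test suite as an
independent oracle and agrees to 2·10⁻⁶. Uncertainty is quoted as the
median ± median absolute deviation of f over 10 random 80 % subsets, with
the before/after RMSEP evaluated on the full data at the median f.
Sequential losses compose multiplicatively, `1 − f_total = Π (1 − fₖ)`;
at few-percent magnitudes this differs from plain addition by < 0.1
percentage points.

Two known small biases of the estimator, both shared with any
errors-in-predictions through-origin slope: (i) regression dilution from
prediction noise (∝ the squared relative error, ~0.05 pp at the default
noise), and (ii) mild curvature of the vector-normalized calibration when
the drug contributes a non-negligible share of the spectral norm. The
c²-weighting also concentrates the information in the top of the
concentration range: a 0–2000 µM series of 24 spectra has an effective
sample size of ≈ 8 for this estimator.

## Donor-sex classification

Vector-normalized spectra are reduced by centered PCA (5 components, or
the smallest count reaching a cumulative explained-variance target; full
SVD solver for determinism; loading signs fixed so the largest-magnitude
element is positive). Classifiers: LDA, linear SVM (cost 1000) and
radial-kernel SVM (cost 10 000, γ = 1). Features are centered and divided
by one **global** scalar (the rms score scale) rather than standardized
per feature: per-feature standardization would amplify near-noise
components to the scale of the leading ones and destroy the variance
ordering that motivated the PCA reduction. Evaluation uses 20 repeated
stratified 80/20 splits grouped by donor (all spectra of a donor on one
side, at least one held-out donor per class), with SVM decision values and
LDA positive-class posteriors feeding a threshold-averaged ROC: the union
of observed scores forms the threshold set, each repeat contributes its
(FPR, TPR) at every threshold, and AUC is computed per repeat on its own
curve (mean ± sd over repeats). The female class is the positive class by
convention (alphabetical), configurable.

LDA discriminant directions are mapped back to wavenumber space as
weighting vectors `loadingsᵀ·coefficients` (rescaled to undo the feature
scaling); extrema above the 90th percentile of |weight| localize the
chemical bands driving a discrimination.

## ICH detection limits and reference matrices

For univariate quantification, maxima-normalized spectra are differenced
against the maxima-normalized median spectrum of a reference urine matrix,
and a Gaussian with constant offset is fitted to the piperacillin marker
band at ~1485 cm⁻¹ (window ± 30 cm⁻¹; fitted center constrained to
± 10 cm⁻¹ because the band position is known — a freely roaming center
makes the fit bistable when residual matrix structure sits at the window
edge; σ bounded to [1, 30] cm⁻¹; bounded restarts; non-convergence is
flagged, never silent). Fitted amplitudes against spiked concentrations
give an OLS line; with slope m and intercept standard error σₙ,

    LoD = 3.3 σₙ / m      LoQ = 10 σₙ / m

so LoQ/LoD = 10/3.3 identically. Concentrations convert to mg/L via the
molar mass; both the piperacillin sodium salt (539.5 g/mol, the default
for detection-limit reporting) and the free acid (517.55 g/mol, used for
clinical exposure ranges) are provided.

When the reference matrix differs compositionally from the sample matrix,
urea-normalized difference spectra retain residual creatinine and
uric-acid structure. The uric-acid band at ~1498 cm⁻¹ and the flank of
the creatinine 1525 cm⁻¹ band fall inside the marker fit window, so the
fitted amplitude becomes a mildly nonlinear function of concentration;
the resulting lack of fit inflates σₙ and therefore the LoD. This is the
mechanism by which a distant reference matrix (e.g. a male urine pool for
a female sample) degrades detection limits, while the sample's own matrix
— and, typically, a same-sex pool — preserves them.

## The synthetic generator

The generator replaces clinical samples in every test. One spectrum is

    I(w) = gain · [ Σ_comp conc_comp · Σ_bands rel·G(w; center, σ)
                    + c_drug · response · Σ_drug-bands rel·G(w)
                    + baseline(w) ] + offset + ε(w)

with Gaussian bands G (default σ = 8 cm⁻¹), a Legendre-polynomial baseline
plus a broad hump, per-spectrum affine scatter (gain sd 0.08, offset sd 4),
and i.i.d. channel noise. Band centers follow the assignments for urea
(1015, 1265, 1611 cm⁻¹), creatinine (850, 1050, 1525 cm⁻¹), uric acid
(1355, 1435, 1498, 1660 cm⁻¹) and piperacillin (1140, 1345, 1485 cm⁻¹).
The grid is 600–1900 cm⁻¹ at 1 cm⁻¹ so truncation is a real operation.
All randomness flows through named seeded streams; regeneration is
bit-reproducible.

Key default choices, with rationale:

* **drug_response = 0.1 a.u./µM** — the marker band reaches ~1/6 of the
  urea peak at 1000 µM, a matrix-dominated regime in which the
  vector-normalized calibration stays near-linear, consistent with the
  near-identity correlation the loss-factor method produces in practice.
* **noise_sd = 1 a.u.** — yields pipeline prediction errors (RMSEP ~10–30
  µM over a 0–2000 µM series) on the scale the method reports on real
  spectra.
* **composition_cv = 0.05** per component, log-normal — donor variation in
  a homogeneous healthy-young-adult cohort; deliberately small relative to
  the sex difference in mean composition, matching a regime where urine
  pools of different sexes are cleanly discriminable.
* **aliquot_cv = 0** — the calibration series is a set of aliquots of one
  homogenized urine sample; spiking changes the overall gain (removed by
  normalization), not the matrix composition ratios. A nonzero value is
  available for robustness experiments.
* **treatment_factors** — froz 8.42 %, filt 2.36 %, cent 2.80 %,
  filt_cent 5.05 %; treatment is modeled purely as concentration scaling
  `c → (1−f)·c`, exactly the assumption the loss-factor statistic makes.
  An optional matrix-perturbation knob exists for robustness tests and
  defaults off.
* **Classification geometry** — donors of the sex-classification cohort
  vary along a single composition axis u that trades creatinine against
  uric acid at constant total spectral energy ("norm-neutral"). Female
  donors occupy the central interval |u| ≤ 0.012, male donors both flanks
  0.025 ≤ |u| ≤ 0.05, with positions stratified within each segment.
  Because the male class brackets the female class, no linear score —
  not even one exploiting the quadratic curvature of the spectral
  embedding — can rank the classes perfectly, while a boundary radial in
  u separates them exactly. An earlier two-dimensional annulus design was
  rejected: vector normalization warps the ratio plane (directions that
  raise total intensity compress radially), so small cohorts cannot cover
  a ring uniformly and held-out donors fall into uncovered arcs. The
  1-D geometry preserves the scientific point (nonlinear, radially
  separable classes; linear classifiers strictly worse) while remaining
  learnable from 17 donors under donor-grouped cross-validation.

What the generator does **not** emulate: absolute photon counts and
detector response, cosmic-ray spikes, photodegradation kinetics, band
shape deviations from Gaussian, within-donor composition drift, and the
full chemical complexity of urine (only three matrix components).
Passing tests therefore demonstrate the correctness and calibration of
the *analysis* under the stated generative assumptions, not instrument-
level performance on clinical samples.

## Problem sizes

Default experiment sizes keep every analysis desk-scale: calibration
series use 8 levels (0–2000 µM) × 3 replicates; loss-factor estimation
uses 10 cross-validation subsets; the classification cohort is 8 female +
9 male donors × 20 spectra with 20 CV repeats; reference-matrix
comparisons use 4 reference matrices × 3 replicates and directional
claims are evaluated over 20 generator seeds.

## Known limitations

* The loss-factor estimator inherits the small negative bias described
  above (≲ 0.2 pp at default conditions); it is a property of the
  statistic, not of the implementation.
* Threshold-averaged ROC dispersion bands are descriptive; repeats share
  training data and are not independent.
* The univariate marker-band route assumes a single dominant drug band;
  strongly overlapping drug/matrix bands beyond the modeled ones would
  require the multivariate (PLS) route.
* The optional loader for published supplementary spectra is not
  implemented; its layout is unspecified, and all I/O goes through the
  documented long/wide CSV contracts instead.
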