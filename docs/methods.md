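# Methods

This note records the models implemented, the defaults and why they
were chosen, what the synthetic-data generators do and do not emulate,
and the numerical decisions that were genuinely open.

## RPPM dilution-series quantification

### Model and coordinates

A reverse-phase protein microarray prints each sample as a 1:1 serial
dilution series (after an initial fixed dilution, which is a constant
offset on the log-concentration axis and is absorbed into the sample's
apparent abundance).  Dilution step *k* is assigned log2 relative
concentration *x = −k*; the response is log10 net fluorescence.  The
five-parameter logistic is evaluated in log space,

    y(x) = D + (A − D) · exp(−G · log(1 + e^{B ln2 (x − C)})),

which is overflow-free for any *x* and exactly monotone from *A*
(high dilution) to *D* (saturation) for *B* > 0.  The asymmetric form
is used because immunoassay dilution curves are generally not symmetric
about their inflection; *G* = 1 recovers the 4PL.

### Workflow

1. **Background correction and filtering.**  net = raw − local
   background; a spot is excluded iff SNR < 2 or net < 10 AU, both
   strict (boundary values are kept).  The SNR is taken from the input
   table when the scanner reports it; the simulator uses raw/background.
   Replicate depositions (2 per spot by default) are averaged in linear
   AU after filtering, before any fit.
2. **Master curve.**  All usable points on the slide are pooled on the
   common dilution-step axis and fit by bounded least squares
   (`scipy.optimize.least_squares`, trf): *B*, *G* ∈ [0.1, 10], *C*
   within the data range ± 4 log2 units, tolerances 10⁻¹⁰, iteration
   cap 500, deterministic initialization from data quantiles.  Samples
   with different abundances are shifted copies of one curve, so the
   pooled fit sees a slightly flattened transition when abundances are
   spread; with equal abundances it is an unbiased estimate of the
   generating curve.
3. **FDR outlier rejection (ROUT-style).**  The robust residual scale
   is the 68.27th percentile of |residuals| (a robust σ estimate for
   Gaussian cores).  Each point gets a two-sided t p-value
   (df = n − 5) and Benjamini–Hochberg step-up at Q = 0.01 flags the
   outliers.  Exclusion and refitting alternate until the outlier set
   is stable, at most 5 rounds; each refit starts at the previous
   parameters, so the residual sum of squares over kept points never
   increases.  A residual scale below 10⁻¹² log10 units is treated as a
   perfect fit; only residuals above 10⁻⁶ (≈0.0002% in intensity) are
   then flagged, which keeps noise-free fits from flagging
   floating-point dust.
4. **Local block fits.**  Per printing block, a joint fit shares
   *A, D, B, G* across the block's samples with one free position C_i
   per sample, initialized at the master values.  A one-sample block
   degenerates to an ordinary fit.  Because a factor-f abundance change
   is exactly a log2(f) shift in C_i, noise-free positions of samples
   with abundances (1, 2, 4) are spaced by exactly one log2 unit.
5. **y-intercept readout.**  The "linear portion" is the set of
   observed points whose *fitted* response lies within 25–75% of the
   |A − D| range (configurable); an OLS line through those points in
   (x, y) is evaluated at x = 0 (the undiluted printed sample).  Fewer
   than two such points marks the quantification unusable rather than
   extrapolating.

### Discretization of the linear portion

Because observed points sit on integer dilution steps, the band
selects 2–4 points whose placement relative to C_i varies with the
fractional part of the sample's log2 abundance.  The resulting
intercept bias is bounded by ≈0.04 log10 for the default curve.  Two
consequences, verified numerically: (i) noise-free abundance *ranking*
is exact only for abundance gaps ≳0.15 log2 (the test uses 0.5-log2
spacing); (ii) the per-doubling intercept shift equals the fitted
linear slope exactly (≈0.54 log10 for the default curve) rather than
the idealized log10 2 of a perfectly proportional assay.

## Synthetic RPPM slides

The generator emulates: a 5PL response in log-log coordinates evaluated
at log2(abundance · 2^−k); multiplicative log-normal noise (additive
Gaussian in log10, default σ = 0.02); a constant background (50 AU)
added back to produce raw fluorescence; planted outliers (net intensity
× 10) and planted sub-threshold spots (SNR drawn uniformly from
[0.5, 1.9]), with counts floor(fraction × n) assigned by seeded
shuffle.  Identical seeds give bit-identical tables.

Defaults are the study conditions used throughout the tests: 16 samples
× 8 dilutions × 2 depositions, blocks of 4 samples.  The default
generating curve, A = 2.0, D = 4.5, C = −3.5, B = 1.2, G = 1.5, spans
2.5 decades (100 AU floor to ≈32 kAU saturation) with its transition
inside the 8-step window: a Monte-Carlo identifiability analysis showed
this is the regime in which all five parameters — the asymmetry *G* is
always the weakest — are recoverable from a single slide at σ = 0.02
(mean worst-parameter error ≈7%).  Flatter curves whose mid-range
response is exactly proportional to concentration cannot cover their
transition in 8 two-fold dilutions and leave *G* essentially
unidentified.  Sample abundances default to 1; `spread_abundances`
provides a geometric 8-fold inter-sample spread for ranking studies.

Not emulated: spatial slide artifacts, inter-block staining gradients,
antibody cross-reactivity, inter-slide normalization.  Passing tests
therefore validate the estimator chain, not robustness to spatially
structured artifacts.

## Diffusion metrics

Tensors are stored as the 6 unique elements (lower-triangular order
dxx, dxy, dyy, dxz, dyz, dzz) per voxel; eigenvalues come from
`numpy.linalg.eigvalsh` and are sorted descending.  FA is defined 0 for
an all-zero tensor.  Negative eigenvalues are never clamped — affected
voxels are flagged in a validity mask so downstream summaries can see
them.

Voxel convention: 0-based indices, voxel-centred world mapping through
the NIfTI affine, half-open extents [i − 0.5, i + 0.5) in voxel space.
Rasterization uses an exact amortized grid traversal
(Amanatides–Woo), which reports precisely the voxels whose half-open
box a segment crosses — the limit of dense supersampling, verified
against a brute-force segment/box slab-test oracle.  A finite-step
sampling oracle is provably a subset (it misses corner-grazing voxels
with chord shorter than its step), which is why the tests assert
containment plus convergence for sampling and equality for the exact
oracle.

Track-weighted maps: TDI counts each streamline once per voxel; APM
averages the *total* track length of the tracks through the voxel (not
the in-voxel portion); CURV averages the per-track mean Menger
curvature (inverse circumradius of consecutive point triples, averaged
over the track's interior points) — track-level, then voxel-level
averaging.  Per-voxel contributions are summed in sorted order so the
maps are bit-identical under streamline permutation.  APM/CURV are NaN
(masked invalid) where TDI = 0; the default ROI mean is the whole-ROI
mean with invalid voxels contributing 0, with a nonzero-only variant
available.

Note that Menger curvature is exact on circular arcs at any sampling
(three points on a circle have circumradius R); discretization error
appears only where curvature varies along the chord, so convergence is
demonstrated on the helix phantom.

Phantoms: analytic line, circle and helix centerlines sampled at the
requested step, with optional rigid perpendicular jitter of the whole
centerline (preserving the analytic length/curvature of each copy).
They stand in for real tractograms only geometrically: no fanning,
crossing, or length dispersion.

## Group statistics

`two_way_anova` delegates the linear-model algebra to statsmodels
(OLS + `anova_lm` typ 3 with sum-to-zero contrasts) behind the module
interface; correctness is cross-checked in the tests against an
explicit design-matrix projection oracle written with `numpy.lstsq`
only.  Type III with sum-to-zero contrasts matches the common
statistics-package default and remains meaningful for unbalanced
cohorts; in balanced designs it coincides with sequential sums of
squares (tested).  An empty design cell makes the interaction
inestimable and raises an error naming the cell.

Post-hoc comparisons are protected pairwise t tests per time level
using the pooled ANOVA residual mean square, Bonferroni-adjusted by the
number of usable levels (those with both groups present; default family
size 5), adjusted p = min(1, m·p).  Significance is p ≤ 0.05
(inclusive).

The 2×2 mixed design is computed by the exact split-plot decomposition:
the between-group effect is tested on per-subject means against
subjects-within-groups; the within effect (first vs second injury) and
the interaction are tested on per-subject differences against the
subject×within residual — each stratum a small Type III OLS, rescaled
to original-unit sums of squares.  Subjects missing a measurement are
dropped with a warning.  The degenerate case of a constant per-subject
change (zero residual stratum) is handled explicitly: F = 0 when the
change is zero, infinite otherwise.  Results are cross-checked against
an independent stratified projection oracle and against pingouin.

The behavioral generator draws independent normals per cell of the
2 (injury) × 5 (recovery day) between-subjects layout with
user-specified means, a common residual SD, and per-cell counts
(unbalanced allowed, minimum 2).

## End-to-end injury experiment

`injury_experiment` carries a planted group difference through the full
RPPM chain: per recovery day one slide holds 8 sham and 8 injured
samples; log2 abundances are N(0, s²) for sham and N(d·s, s²) for
injured with inter-animal spread s = 0.5 log2 units (a 2-fold
biological coefficient of variation, realistic for plasma proteins and
large enough that the planted effect is expressed in abundance rather
than swamped by the band-discretization noise of the readout).  Two
recovery days are simulated (32 samples per run), slides are quantified
independently, and the y-intercepts are analyzed with the two-way
ANOVA.  At d = 1.5 this design detects the injury effect with ≈97%
power; the acceptance script measures it over 200 independent runs.

## Problem sizes in the acceptance script

Each quantity is recomputed from scratch at fixed, deliberately
desk-scale sizes: 20 slides (16×8×2, σ = 0.02) for 5PL recovery and
Spearman ranking; 5 slides for filter exactness; 100 null + 100
outlier-spiked residual vectors (n = 200) for FDR control; 3 canonical
eigenvalue triples + 100 random rotations for tensor scalars; a 7-track
line bundle, a 3-track 1°-sampled circle (R = 10 mm), and 100 random
polylines for the track-weighted maps; 3 unbalanced designs vs the
projection oracle + 1000 null simulations for the ANOVA; 200 runs of
the injury experiment for detection power.

## Known limitations

* The master curve pooled over samples with spread abundances estimates
  a slightly flattened Hill slope; the shared-parameter block fits, not
  the master curve, carry the quantification.
* Quantification readout inherits a discretization bias from integer
  dilution steps (see above); ranking resolution is ≈0.15 log2 units.
* No inter-slide or inter-antibody normalization is implemented (none
  is defined without a calibrant).
* The mixed-design ANOVA supports exactly two within-subject levels.
* Track-weighted maps hold whole tractograms' voxel sets in Python
  sets; suitable for phantoms and ROI-scale analyses, not for
  multi-million-streamline whole-brain tractograms.
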