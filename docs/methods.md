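# Methods

This note documents the models, algorithms and numerical choices behind
`hsipipe`, and what the synthetic experiments do and do not establish
about real data.

## The measurement model

A push-broom VNIR camera records raw digital numbers (DN) over
400–1100 nm in 176 bands (band *i* centred at 400 + 4·*i* nm). Dark
current and illumination are removed with the two-point black/white
correction

    C = 65552 · (R − D) / (W − D)

where D is the all-dark frame, W the full-scale white reference, and
65,552 the camera's full-scale quantization value. The pipeline keeps
the reflectance fraction C/65552 in [0, 1]. Pixels with W = D carry no
radiometric information; they are flagged invalid and excluded from
leaf masks rather than imputed, and more than 1% of them fails the
correction outright. The correction is exactly invariant to any common
positive rescaling of R, W and D.

## Segmentation

Leaves are separated from the background on a scalar band-math image.
The default is the NDVI-style ratio (R₈₀₀ − R₆₇₀)/(R₈₀₀ + R₆₇₀) using
the bands nearest 800 and 670 nm — vegetation is bright in the NIR and
dark in the red, background materials are not — thresholded with Otsu's
method, followed by keeping the largest connected component to remove
background speckle. The ratio makes the mask invariant to global
multiplicative illumination changes. Both the band-math expression
(a single band is also supported) and the threshold are overridable;
a constant band-math image (no contrast) raises an error rather than
returning an arbitrary mask. Mean spectra are arithmetic means over
mask pixels, band by band, stacked in acquisition order.

## Preprocessing

* **MSC** — each spectrum is regressed (ordinary least squares) on the
  calibration-set mean spectrum; the fitted affine map is inverted:
  `corrected = (x − b)/m`. This removes per-sample multiplicative
  scatter and additive baseline exactly: MSC(a·x + b) = MSC(x) for
  a > 0. The reference mean is computed from calibration rows only and
  reused unchanged on prediction rows (the all-sample alternative is a
  one-line change but invites leakage).
* **Derivatives** — plain forward differences, (y₍ᵢ₊₁₎ − yᵢ)/Δλ and
  (y₍ᵢ₊₁₎ − 2yᵢ + y₍ᵢ₋₁₎)/Δλ², Δλ = 4 nm on the default grid. These
  are exact for linear/quadratic spectra and deliberately *not*
  replaced by smoothed (S-G-embedded) derivatives; the derivative trims
  the bands its stencil cannot reach instead of padding.
* **Savitzky–Golay** — local least-squares polynomial smoothing
  (scipy's filter) with polynomial order 2 by default — the common
  chemometrics choice; window widths 5–21 are typical — and mirror
  padding at the edges. Polynomials up to the filter order pass through
  unchanged; white noise is attenuated by the squared weight norm.
* **Chains** — stages compose strictly left-to-right as written in
  names like `MSC+2D+S-G (17)`, which parse back to an identical
  configuration. Whether smoothing should precede or follow the
  derivative is a genuinely open convention; executing as written keeps
  the name authoritative.

## Wavelength selection

All three selectors consume the preprocessed calibration matrix and one
target. Selector-internal PLS component counts are chosen by 5-fold
contiguous-block cross-validation, capped at 15. Ranking ties break
toward the lower band index, and all sampling flows from one seed, so
every selector is deterministic given data and seed.

* **UVE** appends as many artificial uniform-noise bands as real ones,
  scaled to 10⁻⁵ of the mean |X| (small enough never to predict y,
  large enough to keep coefficients numerically stable), runs
  leave-one-out PLS, and computes per-band coefficient stability
  mean/SD. The cutoff is the 0.99 quantile of |stability| over the
  noise bands; real bands above it survive. Eliminating every band
  raises an error that suggests lowering the cutoff.
* **CARS** runs 50 Monte-Carlo iterations. Each iteration fits PLS on
  an 80% row subsample of the live bands, force-retains the top
  r·p bands by |coefficient| along the exponentially decreasing
  schedule r₁ = 1 → r₅₀ = 2/p, then resamples bands with probability
  proportional to |coefficient| (adaptive reweighted sampling, with
  replacement; duplicates collapse). The live-band count is therefore
  non-increasing. The iteration whose band set minimizes the 5-fold
  CV RMSE wins.
* **SPA** grows a chain from each candidate start band by repeatedly
  adding the band with the largest column norm after orthogonal
  projection onto the complement of the chain's span (columns centred
  first). Chains are scored by the CV RMSE of an ordinary
  least-squares fit — the classical SPA scoring — over subset sizes
  5–30; the full-band reference model in comparisons is PLS with
  CV-chosen components, because full-band OLS is singular when bands
  exceed samples.

## Regression and evaluation

PLS1 is implemented with the NIPALS decomposition; with as many
components as the data's rank it coincides with ordinary least squares
(asserted to 1e-8 in tests), and its `"cv"` mode picks the component
count minimizing the contiguous-block RMSECV. SVR (RBF kernel, inputs
standardized by a scaler fitted on calibration rows only; C/γ/ε from a
small deterministic CV grid unless given) and random forests (500
trees, seeded) are delegated to scikit-learn behind the same model
surface. Models serialize to a JSON manifest (PLS entirely in JSON;
sklearn payloads via joblib) and reload bit-identically.

The calibration/prediction split sends every 4th sample of the
time-ordered list to the prediction set (3:1), so both sets span all
drought periods; 6 × 30 samples give 135/45. A trailing-block variant
is available. Cross-validation folds are contiguous time blocks to
respect the temporal design. RPD uses the prediction set's reference
sample SD (ddof = 1) over RMSEP — the standard chemometrics
definition — with grades excellent (≥ 2), rough (1.4–2), unusable
(< 1.4). Because usage in the field wavers between R and R², reports
carry Pearson R in the table columns and R² alongside in the JSON.

## Drought damage degree

MDA, EL and SS (the analytes that rise with drought; Fv/Fm falls and is
excluded) are z-scored, their 3 × 3 correlation matrix is
eigendecomposed, and components are retained until the cumulative
eigenvalue fraction exceeds 0.85. The loading→weight recipe is a
documented design choice: each analyte's weight is the
contribution-weighted sum of its absolute loadings over retained
components, normalized to unit sum — this reproduces the unit-sum
property of the fixed reference weights (0.359, 0.341, 0.300) and gives
exactly equal weights under symmetric (exchangeable) correlation. For
tied eigenvalues the individual eigenvectors are arbitrary, so the rms
loading over the tied group stands in for each member's |loading|,
which makes the weights basis-invariant. Weight derivation is invariant
to affine rescaling of any analyte (correlation-based). The raw
composite Y is centred at 0; an affine display transform
(offset 6.07, scale 1.40 per SD of Y) maps it onto a positive "level"
scale for reporting — a display convention only, with no claim about
the level scale's origin.

## The synthetic experiment generator

Defaults encode the reference study design: 6 drought periods × 30
leaves, 3 assay repeats per leaf (averaged into the modelling table; a
`keep_repeats` switch returns the 540-row long table), 176 bands over
400–1100 nm.

* **Biochemistry** — a latent drought level d rises linearly from 0 to
  1 over periods. Each analyte responds linearly in d inside its
  published descriptive range (MDA 3.26–9.61 mmol/kg, EL 18.76–49.70%,
  Fv/Fm 0.92→0.60, SS 5.1–13.1 mmol/g), inset by 3.5 total noise SDs so
  noisy draws stay in range (a hard clip is the safety net). Leaf-level
  variation is Gaussian with SD 5% of each range; per-assay noise half
  that. Soil moisture falls 50% → 10%. These levels were chosen once as
  representative of controlled greenhouse assays: large enough that
  preprocessing and selection have real work to do, small enough that
  the biochemistry is recoverable from spectra.
* **Spectra** — a vegetation-like reference curve (green peak ~550 nm,
  chlorophyll well ~670 nm, red-edge sigmoid at 700–750 nm, NIR plateau
  ~0.55, water band ~970 nm) plus feature amplitudes *affine* in the
  design z-scores of the four analytes, with drought pushing visible
  reflectance up and NIR reflectance down. The coefficient matrix is
  exported in the ground-truth ledger. This linear forward model is a
  deliberate stand-in — no radiative-transfer realism is attempted — so
  that (a) PLS can recover the biochemistry exactly in the noise-free
  limit and (b) informative bands are localized, giving the selectors a
  planted signal. Per-band iid reflectance noise (SD 0.002) is added to
  leaf-mean spectra.
* **Cubes** — an elliptical leaf over a spectrally flat background
  (reflectance 0.25), per-pixel multiplicative scatter
  slope ~ N(1, 0.05), additive baseline ~ N(0, 0.01), pixel noise
  SD 0.005, encoded as DN = D + (W − D)·reflectance with flat reference
  frames so correction inverts the encoding exactly. The desk-scale
  default is 64 × 64 pixels; the full 960 × 1101 camera geometry is
  available through `SceneSpec` but never needed for testing. With all
  nuisances off, generate → correct → segment → extract is the identity
  on spectra to 1e-9 relative.

**What passing tests show — and don't.** On this generator the planted
signal is linear and the noise Gaussian and independent, so high
prediction R (≥ 0.9 across analytes) demonstrates that the pipeline's
plumbing, leakage guards and selectors work, not that any real crop's
biochemistry is predictable to that accuracy. Real leaves add
nonlinearity, structured illumination, genotype and water-status
confounds that this generator deliberately omits; published accuracies
on real data are typically lower.

## Problem sizes and determinism

Test and acceptance runs use the default 180-sample design, desk-scale
cubes, 20-seed replications for selector properties and a 90 × 176
planted-signal matrix — sizes chosen so the whole suite completes in a
few minutes on one core while leaving the statistical assertions sharp.
Every stochastic component (generator, UVE noise draw, CARS sampling,
SVR grid, RF) draws from seeds derived from one root seed via a stable
configuration hash, and run manifests contain no wall-clock metadata,
so identical seeds reproduce manifests bit for bit.

## Known limitations

* The spectral forward model is linear by construction; nonlinear
  model back-ends (SVR, RF) can only be exercised for contract
  properties here, not for their real-data advantages.
* SPA's exhaustive start-band search is O(bands) chains per target;
  for axes much longer than ~500 bands, restrict `spa_starts`.
* The ENVI reader covers only the subset of the header grammar the
  writer emits (BSQ, float32/64, little-endian).
* UVE's leave-one-out loop refits PLS n times; for n in the thousands
  switch to a grouped jackknife (not implemented).
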