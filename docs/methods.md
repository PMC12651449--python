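# Methods

This package implements a complete, synthetic-data-driven mirror of a
hyperspectral workflow for scoring kiwifruit quality during shelf life: a
composite index is built from destructive reference measurements by factor
analysis, and that index is then predicted non-destructively from VNIR
reflectance spectra, band-selected and regressed with chemometric and neural
models, and finally mapped pixel-wise over the fruit surface.

## The composite index

Six reference parameters are measured per fruit: soluble solids content
(SSC, °Brix), flesh firmness (F, kg cm⁻²), and the CIELAB colour coordinates
L\*, a\*, b\* with chroma C = √(a\*² + b\*²).  After z-scoring, adequacy is
checked with the Kaiser–Meyer–Olkin measure (KMO > 0.5 required) and
Bartlett's sphericity test (χ² = −(n−1−(2p+5)/6)·ln det R, df = p(p−1)/2).
Factors are extracted as principal components of the Pearson correlation
matrix, retained up to 80 % cumulative variance, varimax-rotated, and
parameters are kept when they load |λ| > 0.5 on a retained factor without
cross-loading.  The cross-loading screen inspects **all** factor columns: a
parameter is cross-loaded when its second-largest |loading| is ≥ 0.4 and
within 0.2 of its largest.  On the published loading pattern this keeps SSC,
F, L\*, b\* and C and excludes a\* (loadings −0.698 / 0.494 / 0.504); factors
on which no retained parameter is dominant are dropped.

The kept parameters combine, positively loaded terms in the numerator and
the negatively loaded SSC in the denominator, into

    KCQI = ln( 1000 · F · L* · b* · C / SSC )

a unitless score that decreases monotonically as fruit soften, darken and
sweeten.  The constant 1000 is a pure offset (ln 1000) and is kept verbatim;
the formula uses unit exponents — loading-weighted exponents would be an
alternative reading of "weighted by their factor loadings", but the printed
formula is authoritative and is what we implement.  a\* is generated,
reported and analysed throughout but never enters the index.

## Synthetic data generator

No public dataset accompanies the study design, so the generator *is* the
experiment: 2 cultivars × 4 shelf-life days (0/3/6/9) × 30 fruits = 240
fruits by default.

**Quality parameters.**  Each primitive variable v ∈ {SSC, F, L\*, a\*, b\*}
follows, on its standardized scale,

    z_v = l1_v·θ₁ + l2_v·θ₂ + u_v·ε_v ,   u_v² = 1 − l1_v² − l2_v²

where θ₁ is a shared *ripeness* latent whose mean increases linearly with
shelf-life day (within-day SD 0.15 on the day-fraction scale) and θ₂ is a
small independent nuisance latent.  Chroma is derived, not generated.  A
single latent cannot reproduce the target correlation pattern: the ratios
r(SSC,a)/r(F,a) ≈ 0.79 and r(SSC,L)/r(F,L) ≈ 1.03 demand incompatible
loading ratios, leaving ≥ 0.05 residuals.  With the second latent
(|l2| ≤ 0.24) the least-squares calibration reproduces all ten printed
pooled correlations to < 0.001 analytically and < 0.02 empirically at
n = 10,000 — including the derived r(b\*, chroma) ≈ 0.996 and
r(SSC, firmness) ≈ −0.78.  Trajectory endpoints (day-0 → day-9 cohort
means) are SSC 12 → 16.5 °Brix, F 13.5 → 7 kg cm⁻², L\* 55 → 45, a\* −9 → −6,
b\* 30 → 22; with the balanced day design these fix each variable's pooled
mean and SD exactly, so no further noise parameters are free.

**Spectra.**  256 bands, evenly spaced over 400–1000 nm (the quoted 2.8 nm
"resolution" is treated as optical FWHM, not sampling — 256 bands over a
600 nm span imply ≈ 2.35 nm sampling).  A fruit's ROI-mean reflectance is a
smooth sigmoidal baseline (≈ 0.30 visible → 0.55 NIR) plus six Gaussian
features whose amplitudes are affine in the fruit's standardized quality
state: chlorophyll absorption dips at 420 and 670 nm driven by a\*, a broad
visible level near 550 nm driven by L\*, a yellow shoulder near 600 nm
driven by b\*, a NIR reflection shoulder at 830 nm driven by firmness and
SSC (declining over shelf life), and the 970 nm water band driven by a
moisture proxy (loading −0.9 on ripeness).  Homoscedastic per-band Gaussian
noise (SD 0.005 reflectance, typical of ROI-averaged VNIR measurements) is
added last and values are clamped to [0, 1].

**Explainable fraction.**  Each feature driver is blended as
√f·(quality driver) + √(1−f)·η with independent standard-normal distortions
η, f = `explainable_fraction` (default 0.9).  A single feature therefore
carries fraction f of its driver's variance; because the distortions are
independent across features while the drivers are correlated, a joint linear
readout of all six noiseless amplitudes recovers KCQI with R² ≥ f (the
documented contract; empirically ≈ 0.93 at f = 0.9).  f is thus a *floor*
on the information the spectra encode, and the main dial for stress-testing
the regression stage.

**Cubes.**  Pixel-level cubes place an elliptical fruit (semi-axes 0.38 h ×
0.32 w) on a dark background (reflectance 0.03); fruit pixels carry the
fruit's spectrum modulated by a spatially smooth multiplicative brightness
field (cubic-upsampled 8×8 Gaussian grid, SD 1 %).  Raw intensity cubes are
constructed by *inverting* the white/dark correction (flat white 3000
counts, dark 100), so `radiometric_correct` recovers the generating
reflectance to float precision — a built-in round-trip oracle.  The default
desk-scale cube is 64×64 px (not the instrument's 1392×1040); the 110 px
ROI scales proportionally with cube height (110·h/1040, minimum 3).

**What the generator does not emulate:** radiative-transfer realism,
cultivar-specific spectral libraries (both cultivars share one parameter
set), specular highlights, scattering anisotropy, wavelength-dependent
noise, or treatment effects.  Passing tests therefore demonstrate that the
*pipeline* behaves correctly under the study's statistical structure, not
that the models would reach the same accuracy on real fruit.

## Partitioning and band selection

* **SPXY** — joint distance d(i,j) = dX/max dX + dy/max dy, Kennard–Stone
  max–min greedy selection of round(0.8 n) calibration samples; ties break
  to the lowest index.  Note a structural consequence used throughout: the
  calibration set captures the data hull, so the prediction set is
  interior and has smaller response variance; prediction R² is therefore
  systematically harder than calibration R² at equal RMSE.
* **SPA** — chains grown from every starting band by maximal
  orthogonal-projection residual norm; chain prefixes scored by OLS
  calibration RMSE; smallest prefix whose F = RMSE²/RMSE²_min passes the
  F-test at α = 0.25 (df = n−k both sides) is returned.
* **CARS** — 50 Monte-Carlo runs, 80 % subsampling, |PLS coefficient|
  weights, exponentially decaying forced-retention ratio
  r(i) = a·e^(−ki) with r(1) = 1 and r(N) = 2/p, adaptive reweighted
  sampling among survivors, and 5-fold RMSECV (minimized over ≤ 10 latent
  variables) as the run criterion.
* **Random frog** — 1000-iteration subset chain; proposal size
  ~ N(m, 0.3 m); uphill moves accepted, downhill with probability
  0.1·(err_cur/err_cand); per-band selection probability thresholded at
  0.40.  The acceptance damping 0.1, initial size 10 and chain length are
  literature-standard values, config-exposed.

All selectors fit on calibration rows only; a poisoning test (prediction
rows set to NaN) asserts they can never touch held-out data.  The RMSECV
used inside CARS/random frog computes all latent-variable truncations from
a single NIPALS fit per fold (B_a = W_a(P_aᵀW_a)⁻¹q_a), which keeps the
frog chain tractable on one CPU.

## Regression backends

* **PLSR** — NIPALS (scikit-learn), latent-variable count chosen as the
  smallest argmin of 10-fold RMSECV.
* **Random forest** — 100 trees, minimum leaf size 8, seeded.
* **1D-CNN** — Conv(16,k=3,same) → BN → ReLU → Conv(32,k=3,same) → BN →
  ReLU → Dropout(0.2) → FC → scalar, trained with Adam (lr 10⁻³, batch 32,
  200 epochs) on the half-mean-square error ½·MSE; inputs standardized per
  band and the target standardized, both with calibration statistics; the
  epoch with the lowest calibration RMSE is restored.  Implemented directly
  in numpy (im2col convolutions, analytic batch-norm backward); gradients
  are finite-difference verified in development.  Training batches receive
  additive Gaussian spectral jitter (SD 0.5 on the standardized-band
  scale) — the standard augmentation for spectra→property networks.
  Without it the network memorizes the reference noise of individual
  calibration fruits (calibration R² → 0.99+) and loses ~0.15 prediction
  R²; with it, training stabilizes near the irreducible error.  Per-epoch
  loss and RMSE are recorded in evaluation mode, so loss = RMSE²/2 holds
  identically between the two curves.

Metrics: R² = 1 − SS_res/SS_tot against the evaluated set's own mean;
RMSE; RPD = population SD of the evaluated set's reference values divided
by RMSE (∞ sentinel for a perfect fit).  RPD ≥ 2 marks a usable model.

## Pixel-wise maps

The trained model (with its own calibration standardization) is applied to
every fruit-mask pixel restricted to the selected bands; background stays
masked.  The fruit mask is Otsu's threshold on the band nearest 830 nm —
the same mask used by ROI extraction (single source of truth).  A day
series shares one colour scale (global min/max) so temporal drift is
visually comparable.  Pixel spectra are standardized with calibration-set
statistics, identical to training (no per-pixel re-standardization).

## Problem sizes and numerical choices

The default experiment is 240 fruits; tight correlation checks use
n = 10,000 (1250 per group).  The pipeline's headline check — CARS + 1D-CNN
prediction R² averaged over 5 independent simulation seeds — runs the full
simulate → KCQI → SPXY → CARS → CNN chain per seed and completes in well
under a minute per seed on one CPU; test and demo configurations scale the
cube size (24–64 px), the frog chain (80–250 iterations) and CNN epochs
down where the full sizes add nothing to the property being checked.
Degenerate inputs are handled explicitly: constant columns are flagged
(correlations undefined) or rejected (z-scoring), singular correlation
matrices fall back to pseudo-inverse KMO with a warning, white ≤ dark
reference bands raise with the offending band list, and sub-receptive-field
CNN inputs are rejected.

## Known limitations

* The factor-analysis selection outcome on synthetic tables is
  seed-dependent (the synthetic correlation matrix is more one-factor-like
  than the real data's); the index formula itself is fixed and does not
  depend on the per-run selection.
* SPXY's hull-vs-interior asymmetry means calibration metrics exceed
  prediction metrics by construction; model comparisons should use the
  prediction set only.
* CARS subset sizes vary with seed (≈ 10–80 bands) because the synthetic
  informative features are broad; the run-selection criterion (minimum
  RMSECV) is honest but not sparsity-seeking.
* The numpy CNN is single-threaded and CPU-oriented; it is adequate for
  hundreds of spectra and desk-scale maps, not for full-frame instrument
  cubes.
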