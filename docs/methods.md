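# Methods

## The problem and the model

Raman microspectra collected from cannabis trichome heads carry a
cannabinoid fingerprint (600–1800 cm⁻¹) that differs between varieties
only through small band-intensity and band-position changes, while being
dominated by nuisance variation: chlorophyll fluorescence, laser-drift
wavenumber shifts, and large point-to-point brightness differences.  The
package treats classification as a two-level supervised problem —
genetics (Indica vs Sativa) on all spectra, then variety on the Sativa
subset — using OPLS-DA, which explicitly separates class-predictive from
class-orthogonal spectral variation so that the nuisance structure does
not leak into the discriminant direction.

## Synthetic data generator

No real spectra ship with the package, so the generator is a first-class
module that reproduces the statistical structure the analysis assumes.

* **Bands.** A fixed library of Lorentzian bands (Gaussian available):
  the assigned cannabinoid bands at 1666, 1623, 1600, 1570, 1438, 1297,
  1187, 1114, 1079, 836 and 786 cm⁻¹ plus weak low-wavenumber
  skeletal/lattice features.  Lorentzian is the default because it is the
  natural Raman line shape.  Amplitudes are free parameters chosen so
  that the CH₂ scissor band at 1438 cm⁻¹ is the global maximum — the
  natural normalization band, sitting in an uncrowded region.
* **Hierarchy.** Per class, 3 trichomes × 20 points = 60 spectra
  (default).  Each trichome draws one multiplicative brightness factor
  1 + N(0, 0.05) shared by its 20 spectra; each spectrum draws its own
  baseline, wavenumber shift N(0, 0.3 cm⁻¹) and iid intensity noise
  N(0, 0.01) (units: fraction of the tallest band's amplitude 1.0).
  These dispersions are the package's choice of a realistic regime —
  noise around 1% of peak signal, drift well under one resolution
  element, trichome effects a few percent — since no measured values
  exist for them; the generator's defaults ARE the conditions every test
  result refers to.
* **Baseline.** A random 5th-order polynomial on the normalized axis
  u = (x − mid)/halfspan, coefficients U(−0.8, 0.8) with a positive
  constant term, rejected and resampled until nonnegative over the grid.
  This mimics broad chlorophyll fluorescence several times the band
  signal; only its polynomial order is meaningful, the coefficient ranges
  are free parameters.
* **Class effects.** Each class multiplies the amplitudes of its
  discriminating bands by ×1.5: the Indica class at the 346–362 cm⁻¹
  skeletal region and neighbours (283–341, 380, 404, 570 cm⁻¹) plus 786,
  1297 and 1324 cm⁻¹; each Sativa variety at its own fingerprint subset
  (e.g. 1360/1438/1634/1666 for Amnesia Haze Hypro, 1313/1386/1570/1595
  for Y Griega).  Band-specific offsets are also supported (bounded by
  2×FWHM).
* **Seeding.** One master seed; every trichome and every spectrum gets a
  counter-derived `SeedSequence` spawn key, so identical (design, seed)
  pairs are bit-identical and any subset is reproducible.

What the generator does *not* emulate: photodegradation/burning, cosmic
rays, detector nonlinearity, heteroscedastic (shot-noise) intensity
noise, correlated baselines within a trichome, or any real biological
overlap between variety fingerprints.  Perfect classification on this
synthetic design therefore validates the pipeline's mechanics — that the
planted effects are recovered through baseline, shift and scale nuisance
— not the discriminability of real plant material.

## Pre-treatment

Fixed order crop → baseline → align → normalize, enforced by the
pipeline runner; each earlier stage removes an artifact the later stages
assume absent.

* **Baseline:** iterative peak-suppressed polynomial fit (modified
  polyfit): fit a 5th-order least-squares polynomial, clamp the working
  signal to the fitted curve wherever it exceeds it, repeat to a relative
  tolerance of 1e-6 (max 100 iterations).  Peaks progressively drop out
  of the fit without any peak annotation; a peak-free polynomial input is
  a fixed point.  The fit uses a normalized abscissa and a single
  pseudo-inverse shared across iterations for conditioning and speed.
* **Alignment:** per spectrum, the scalar shift maximizing the
  cross-correlation with the reference (first spectrum) over
  |δ| ≤ 10 cm⁻¹, refined below the grid spacing by a parabola through
  the three correlations around the best integer lag, then linear
  interpolation onto the reference grid.  Planted noiseless +4 cm⁻¹
  shifts are recovered to ~0.01 cm⁻¹; the interpolation residual after
  re-sampling is below 1% of the peak intensity.  Flat spectra get shift
  0 with a logged warning.
* **Normalization:** subtract the mean intensity, divide by the
  Euclidean norm of the centered vector (equivalent to SNV up to the
  constant √(n−1)); mean 0 and unit length hold to 1e-12.  Constant
  spectra are rejected.

## OPLS-DA

* **Scaling.** Pareto: weight $1/\sqrt{s_j}$ with $s_j$ the per-variable
  SD about the mean (ddof = 1); constant columns get weight 0 and are
  flagged.  The class response is a one-hot indicator matrix,
  column-centered; predicted class is the argmax of $\hat Y$ (ties go to
  the lowest class index).
* **NIPALS.** Components iterate w = Xᵀu/(uᵀu) (normalized), t = Xw,
  c = Yᵀt/(tᵀt), u = Yc/(cᵀc) to a relative score change of 1e-10,
  capped at 2000 iterations (the cap covers the slow linear convergence
  that occurs when the two leading eigenvalues of XᵀYYᵀX nearly tie, as
  happens for late components on noise-dominated residuals); genuine
  non-convergence raises.
* **Orthogonal filtering.** Each orthogonal round takes the NIPALS
  loading p and removes its projection onto an orthonormal basis B of
  span(XᵀY): w_o = p − B Bᵀp, normalized; t_o = X w_o;
  p_o = Xᵀt_o/(t_oᵀt_o); deflate X.  For a rank-one response (one column
  or two classes) this reduces to the textbook
  w_o = p − (wᵀp/wᵀw)·w; projecting against the full Y-covariance
  subspace is the multi-response generalization, adopted here because
  the single-weight version demonstrably strips class-predictive
  variation in the 4-class variety model (observed as systematic
  OriginalAmnesia→YGriega confusion).  Orthogonal scores satisfy
  ToᵀY ≈ 0 and TᵀTo ≈ 0 to 1e-8.
* **Bookkeeping.** R²X per component = its deflation sum of squares over
  the initial (scaled, centered) X sum of squares; fractions plus the
  residual close to 1 within 1e-10.  R²Y accumulates analogously over Y.
* **Cross-validation.** Stratified k-fold (default k = 7, deterministic
  given a seed; k = n reproduces leave-one-out).  Scaler and model are
  refit on each training split; Q² = 1 − PRESS/SS(Y) accumulated over
  held-out rows with the training-split class means as the centering
  reference.  Stratification avoids folds missing one of the 5 classes —
  the reason it is the default.
* **Autofit.** Greedy: starting from one predictive component, add the
  better of (+1 predictive, +1 orthogonal) while Q² improves by more
  than 0.01, subject to n_pred + n_orth ≤ 4 (fewer than five latent
  variables).  The pipeline defaults are fixed rather than autofit:
  (1 predictive, 1 orthogonal) for genetics and (3, 1) for the 4-class
  variety model — one discriminant direction fewer than classes, plus
  one orthogonal filter.
* **Outliers.** None are removed by default; scores outside the 95%
  Hotelling ellipse remain in the model.  (An explicit subset step is
  available through the dataset API if a user wants to drop them.)

## Diagnostics

* **Hotelling's T².** For m score axes and n observations,
  T²crit = m(n−1)(n+1)/(n(n−m)) · F₁₋α(m, n−m), α = 0.05 by default;
  half-axis j = sd_j·√T²crit, membership Σ(t_j/sd_j)² ≤ T²crit.
  Monte-Carlo coverage on Gaussian scores is 95% ± 1% at n = 10⁴.
* **Contributions.** Bars = model weight × (scaled group mean − scaled
  reference mean), in 1/√SD units; weights are the absolute predictive
  loadings averaged over components and normalized to max 1 (the model
  abstracts "weights derived from the underlying model"; this concrete
  choice is documented here because no standard formula exists).
  Reference defaults to the model average (zero vector in scaled space).
  Variables are flagged outside ±3 column SDs of the scaled training
  data — *global* SDs, not per class; since global SDs include the
  between-class spread this flag is conservative.  Contributions are
  antisymmetric under group swap.
* **VIP.** VIP_j = √(J·Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a) over the
  predictive components; mean VIP² = 1 exactly.

## Fisher's exact probability

The probability of a confusion table is judged against the multiple
hypergeometric null with both margins fixed: p = total probability of
all margin-preserving tables at most as probable as the observed one
(two-sided rule; Freeman–Halton for r×c).  Exact recursive enumeration
runs when a composition bound on the table count stays below 10⁷;
otherwise seeded Monte Carlo (default 10⁶ samples) draws
margin-preserving tables by permuting row labels against fixed column
blocks — an exact sampler for this null — and compares vectorized
log-probabilities.  Probability ties are resolved with a 1e-9 relative
tolerance.  The 2×2 path agrees with `scipy.stats.fisher_exact` and the
r×c path with R's `fisher.test` on reference tables.

## Problem sizes and numerical choices

The test and acceptance runs use the full study design (300 spectra ×
1601 wavenumbers, 7-fold CV on both levels) — chosen because it is the
design the generator emulates and it completes in seconds–minutes on one
CPU; unit tests use reduced designs (coarser grids, 2 trichomes × 4–8
points) where only the mechanics matter.  Degenerate inputs are errors,
not silent repairs: non-increasing grids, constant spectra under
normalization, classes with fewer than 2 members under stratified CV,
and component counts beyond the rank of X all raise with a description.

## Known limitations

* Orthogonal-component contributions are not weighted into the
  contribution plot (predictive loadings only).
* The MC Fisher p is 0 whenever no sampled table is as improbable as the
  observed one; for near-diagonal tables the true p is far below 1/n_mc
  and "0.00" is the honest two-decimal report, but the returned float is
  a point estimate, not a bound.
* The ±3 SD contribution flag uses global column SDs; with strong class
  effects the between-class spread inflates the SDs and few variables
  get flagged.
* Synthetic-data results do not bound performance on real plant
  material (see the generator section).
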