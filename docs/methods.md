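# Methods

This note documents the models, the numerical choices and the known
limitations of the `toccsl` package, in the spirit of a methods section a
maintainer can audit.

## 1. Brightness model and mixture deconvolution

A diffraction-limited spot containing N active fluorophores has
brightness B equal to the sum of N independent single-fluorophore
contributions, so its density is the N-fold autoconvolution ρ_N of the
monomer density ρ₁.  The pipeline assumes:

* photon contributions of co-located fluorophores add independently
  (no homo-FRET or quenching between subunits);
* ρ₁ is stationary between the calibration measurement and the
  experiment (same excitation intensity and exposure);
* every subunit carries one mature fluorophore (labelling fraction 1 by
  default, configurable; no correction for dark fluorophores is applied).

**ρ₁ estimation.** Gaussian kernel density with Silverman bandwidth on a
uniform grid of 2,048 points spanning `[0, ~1.08 · N_max · q_0.999]`, so
the grid provably holds the N_max-fold convolution support.  Fewer than
20 calibration spots is a hard error; fewer than 200 warns.  A degenerate
(zero-variance) calibration is represented as a narrow spike two grid
steps wide.  KDE smoothing inflates ρ₁'s variance by the squared
bandwidth; at the default calibration size (5,000 spots, CV 0.35) this is
a ≈4 % variance inflation whose effect on the recovered fractions is well
inside the bootstrap error (verified by parameter recovery).

**Autoconvolution.** FFT-based linear convolution (full output, implicit
zero padding, no wrap-around), truncated back to the grid.  If truncation
would lose more than 1e-4 of probability mass the grid is declared too
short and an error is raised rather than silently biasing the tail.
Each ρ_N is renormalized to trapezoidal integral 1; mean and variance
additivity (N·mean, N·var) are enforced by test at 0.1 % / 0.5 %.

**Mixture fit.** The default criterion is maximum likelihood of the raw
brightness samples under Σ α_N ρ_N, constrained to the probability
simplex.  The optimizer is EM (300 warm-up iterations; monotone and
feasible by construction) followed by an SLSQP polish with analytic
gradient (ftol 1e-14); if the polish fails or degrades the likelihood,
EM continues to convergence instead.  The likelihood in α is concave, so
the optimum is global; agreement with exhaustive grid search on discrete
toy alphabets is tested at 1e-3.  Samples outside the component support
are excluded and counted in the result's warnings.  A binned non-negative
least-squares mode (`method="lsq"`) is provided as a cross-check and is
required by test to agree with ML within bootstrap error.  A monomer PDF
with CV < 0.05 makes the components near-collinear; the fit still runs
but emits an ill-conditioning warning.

**Errors.** Subsampling bootstrap: 100 random half-samples drawn without
replacement, refitted; the SE of each α_N is the SD over replicates
divided by √2 (the √2 compensates the half-sized subsamples).  Replicates
that fail to fit are skipped and counted; more than 10 % skips is an
error.

**Detection sensitivity.** The smallest reliably detectable fraction per
oligomer size is quantified operationally: inject a candidate α_N into a
background mixture, simulate `n_spots` spots, and call the injection
detected when the fitted α_N exceeds twice its bootstrap SE; the minimal
detectable fraction is the smallest candidate detected in ≥ 95 % of
simulations.  Because these simulations draw from the very components
used in the fit, the resulting sensitivities are optimistic relative to
real data with model mismatch.

## 2. Spot detection and fitting

Counts convert to photons as `(counts − offset) · inverse_gain`; clipping
at zero is reported, and is disabled for integrated-intensity density
estimation so read noise averages to zero.  Candidates are local maxima
above a photon threshold after global-median background subtraction;
maxima within 2 px merge to the brightest (shot-noise ripples on one
PSF), and any two candidates closer than `min_separation` (default 5 px)
are **both** discarded — an unbiased brightness PDF matters more than
completeness.  Each candidate is fitted in a 7×7 window with a
pixel-integrated 2-D Gaussian (`background + B · G`), so the fitted B is
directly the integrated photon count.  Fits are rejected with reason
codes on non-convergence, non-positive amplitude, centre escape, or a
width outside 0.7–1.5× the nominal PSF σ (rejects aggregates and
out-of-focus signal).  Background per spot is initialized from the median
of the window border.

Surface density uses integrated intensity — total background-corrected
photons / (monomer mean brightness × area) — which works at
non-resolvable densities; spot counting is available as a cross-check at
low density.  This estimator counts *fluorophores* per µm², which equals
molecules per µm² at labelling fraction 1.

## 3. Mobility

**FRAP.** The recovery of the central part of the bleached region
(rectangle eroded 25 % per side), normalized to pre-bleach, is fitted
with `I/I₀ = m·(1 − exp(−t/τ))`, m bounded to [0, 1], by weighted least
squares (lmfit).  The exponential recovery form with a negative exponent
is the standard saturating model for this readout.  Degenerate cases are
flagged, not hidden: m ≈ 0 makes τ unidentifiable; a series shorter than
2τ has no reliable plateau.

**MSD.** Time-ensemble averaged mean square displacements with
overlapping pairs inside tracks, pooled across tracks weighted by pair
counts.  D comes from the exact line through the first two MSD points
(`MSD = 4 D t_lag + offset`); the intercept estimates static localization
error and is reported, never subtracted.  The quoted MSD standard errors
treat overlapping pairs as independent and therefore understate long-lag
uncertainty — another reason the fit uses only the first two points.

## 4. The synthetic generator

The generator emulates the full experimental chain so every estimator can
be verified by parameter recovery:

* complexes are point emitters whose subunits are co-located; sizes drawn
  from the ground-truth α; surface densities 5–40 molecules/µm² (the
  experimental regime), configurable;
* single-fluorophore brightness per exposure is lognormal with mean 100
  photons and CV 0.35 by default.  The functional form of the empirical
  single-GFP brightness distribution is not prescribed by the analysis;
  the lognormal was chosen once as a realistic stand-in (positive
  support, right-skew typical of single-GFP TIRF signals) and is
  configurable, including empirical-sample input via
  `estimate_monomer_pdf`;
* 2-D Brownian motion at D = 0.118 µm²/s by default, with an immobile
  subpopulation (1 − mobile fraction, default 0.78 mobile) simulated as
  D = 0; immobile molecules inside the bleach region never recover, which
  is exactly why the protocol reports on the mobile pool only;
* protocol timings default to the standard sequence (50 ms pre-bleach,
  800 ms bleach, 40 ms post-bleach control, 15 s recovery; repeats every
  300 s, 10 runs);
* bleaching is binary per fluorophore with a configurable whole-pulse
  efficiency; the pulse is sampled at 8 sub-steps so molecules diffusing
  across the aperture edge during the 800 ms pulse are handled;
* camera: Poisson shot noise on the photon field, then
  `offset + photons/inverse_gain + Gaussian read noise` (defaults: offset
  100 counts, inverse gain 2 photons/count, read noise 1.5 counts, pixel
  0.16 µm, PSF σ 0.13 µm).  No EM-excess noise is modelled (the target
  camera class is a conventional CCD) and counts are kept as floats
  (no ADC quantization).

The movie generator simulates a reservoir extending a configurable margin
beyond the field of view with reflecting walls, so recovery is fed at a
stationary concentration.  Frame-level ground truth (true positions,
visible complex counts, crowding diagnostics) is recorded in the stack
metadata.

**Repeated TOCCSL** is additionally simulated at the population level
(`simulate_repeat_toccsl`): per run, a fraction of each cell's complexes
is bleached wholesale (subunits are co-located during the pulse), a
fraction of the visible complexes is observed, and between runs subunit
labels mix at the ground-truth exchange rate — each complex randomizes
completely with probability `1 − exp(−rate·Δt)`, implemented as a pooled
permutation of the mixing complexes' labels, which conserves the total
fluorophore count exactly and converges to binomial label assignment in
the fast limit.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: fluorophore blinking and triplet states,
photobleaching during readout, dark/immature GFP fractions, EM-gain
excess noise, membrane topography and TIRF evanescent-field decay, cell
boundaries and heterogeneous expression, and tracking-linkage errors
(trajectories are consumed with ground-truth linking; no tracker is
included).  Brightness-dependent detection is emulated faithfully,
however: dim spots near the threshold are preferentially lost, and the
image-level recovery tests quantify the resulting composition bias.

## 5. The repeat-TOCCSL verdict

Spots are pooled by run index across cells and each index fitted with
bootstrap errors.  The dimer fraction is regressed on run index by
weighted least squares.  Two deliberate robustness choices:

* the per-point bootstrap SEs see only spot-sampling noise, not the
  finite visible pool or the sample-size dependence of the constrained
  fit (α₂ acquires a small upward bias at depleted late runs as α₃ hits
  the zero boundary more often).  The slope SE is therefore inflated by
  √(reduced χ²) when the regression is overdispersed, and the verdict
  window is ±3 SE;
* subunit exchange can only shift the apparent composition *toward*
  monomers, so only a decreasing dimer trend argues for exchange, and the
  slope test must agree with an explicit model comparison: the per-run α₂
  series is scored against both the stable prediction (constant) and the
  binomial-mixing prediction, with the per-run unbleached fraction
  inferred from the visible-spot depletion trace.  Run k is imaged after
  k mixing intervals, so its thinning fraction is `survival^k`; the
  bleach pulse of run k removes whole complexes and does not change the
  visible composition.

`verdict = exchanging` requires a < −3 SE slope *and* a better mixing-
model fit; `stable` requires a |slope| < 3 SE *and* a stable-model fit at
least as good; everything else is `inconclusive`.  An optional
`equalize_run_sampling` switch subsamples every run to a common spot
count before fitting, trading precision for the removal of the
sample-size bias gradient.

Pooling across cells is unweighted (each spot counts once); per-cell
weighting is not applied.

## 6. Pipeline validity checks

A run is analyzed only if the post-bleach control frame is clean: the
residual density of fit-confirmed spots in the (eroded) bleach region
must stay below 0.01/µm², otherwise the run is invalid and yields no
mixture fit — surviving and recovered complexes would mix with unknown
stoichiometry bias.  The analysis region is the bleach rectangle eroded
by `region_margin_um` (default 0.6 µm) so PSF tails of unbleached
molecules just outside the field stop do not contaminate detection; the
image-level integration tests erode 1.2 µm because the recovered spots
concentrate in a band at the region edge where coincidence losses and
pair merging are strongest.

## 7. Problem sizes used in the tests

The suite chooses simulation sizes that make each statistical assertion
well-powered while keeping runs reproducible on a single CPU: 10,000
spots (5,000-spot calibration) for the mixture-recovery checks, matching
the order of spots pooled in the motivating experiments; 100 simulated
cells for the image-level end-to-end recovery (the experimental figure
pools ~100 cells); 30 cells × 400 complexes × 10 runs for the repeated
protocol; 11 noisy cells for the FRAP ensemble; 2×10⁴ pooled
displacements for the MSD check.  Movie-level tests use 64–96 px fields
at 2–10 molecules/µm² with an 8 s recovery so the analysis region stays
in the resolvable-spot regime the method requires (≲ 0.5 visible
spots/µm²).

## 8. Known limitations

* Coincidence bias: at recovery-region densities above ~0.5 spots/µm²,
  unresolvable co-localizations inflate the apparent dimer fraction (two
  monomers merge into one bright spot).  The generator reproduces this
  and the crowding diagnostic flags it, but the fit does not correct it.
* Brightness-dependent detection: spots near the threshold are lost
  preferentially, deflating the monomer fraction when the monomer peak
  signal is within a few σ of the noise floor.
* The bootstrap quantifies sampling error only; calibration error in ρ₁
  propagates into all components and is not included in the quoted SEs.
* The FRAP model is the empirical single-exponential bounded-recovery
  form; diffusive recovery of a 2-D hole has 1/t tails that the model
  absorbs into (m, τ), biasing the plateau slightly low at short
  acquisitions (quantified in the movie-level tests).
* No model selection over N_max is performed; N_max = 5 by default, and
  fractions at sizes the data cannot support simply fit to zero.
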