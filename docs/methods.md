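# Methods

This package estimates citrus-leaf relative water content (RWC) from
401–2400 nm reflectance using a three-stage chemometric route: continuous
wavelet transform (CWT) preprocessing, successive-projections (SPA) band
screening, and partial least squares regression (PLSR), with an optional
fusion step that augments the water-sensitive band set with
chlorophyll-sensitive (LCC, SPAD units) bands.  No public leaf spectral
library ships with the package, so every stage runs against a synthetic
generator calibrated to a realistic joint structure of traits and
spectra.  This note records the models, the defaults and
why, and what the synthetic results do and do not show.

## Trait model and its calibration

RWC is drawn uniformly on [0.56, 0.66] (the observed range; the true
marginal is unreported, so uniform is an explicit assumption).  With
Z = RWC − 0.61, chlorophyll follows

    LCC = 63.5 − 200·Z + 1884.8·Z² + ε,   ε ~ N(0, 7.488²)  (SPAD units).

Under a symmetric RWC law Z and Z² are uncorrelated, so the population R²
of a straight-line fit of LCC on RWC is c₁²v/(c₁²v + c₂²w + σ²) with
v = Var(Z) = range²/12 and w = Var(Z²) = h⁴·4/45 (h the half-range), and
the quadratic-fit R² adds c₂²w to the numerator.  The slope, curvature and
noise defaults were solved from this closed form so that the two
population R² values are 0.3648 and 0.3864 — the strength of the curved,
negative RWC–LCC relationship the analysis relies on.  The sign of the
curvature is not identified by a fit quality target; positive was chosen
arbitrarily.  Fresh weight is fixed at 1 g so dry weight is 1 − RWC and
the trait table is exactly consistent with RWC = (FW − DW)/FW.

Sample-level OLS R² at n = 232 is biased slightly above the population
value (order (1 − R²)/n); the calibration tests therefore compare means
over 200 replicates at a ±0.02 tolerance rather than single draws.

## Spectral forward model

Reflectance is a piecewise-linear leaf-like continuum minus Gaussian
absorption troughs, clamped to [0, 1]:

    r(λ) = C(λ) − Σ_f max(0, d₀_f + s_f·x_f) · exp(−(λ − c_f)²/(2σ_f²)),

where x_f is the driving trait (RWC fraction or LCC in SPAD).  Water
troughs sit at 970, 1200, 1450, 1940, 2250 and 2310 nm; pigment troughs
at 430, 460, 640 and 660 nm; and two weak chlorophyll features at 2224
and 2308 nm overlap the SWIR water troughs.  Three deliberate choices
shape the difficulty of the inversion problem:

* **Saturated cores.** The deep 1450/1940 nm water bands carry a large
  static depth but a small RWC slope, mimicking the saturation of strong
  absorption features in real leaves.  Usable water signal therefore
  concentrates in the weaker 970/1200/2250/2310 nm bands.
* **Rectified SWIR chlorophyll features.** The 2224/2308 nm features use
  the depth clamp as a threshold-linear response,
  depth = max(0, s·(LCC − 63.5)): below ~63.5 SPAD they vanish.  A model
  linear in (RWC, LCC) would make chlorophyll-band fusion pointless —
  any band set spanning both latent directions suffices — whereas the
  rectified contamination of the water bands cannot be removed by a
  linear combination of coarse-scale coefficients alone.  Bands that
  measure the contamination directly (fine-scale coefficients at
  2224/2308 nm) then add genuine information, which is the fusion effect
  the pipeline is built to exercise.
* **Scan noise as the only stochastic channel.** Each spectrum is the
  mean of 10 independent per-band Gaussian noisy scans (the replicate-
  averaging protocol).  The default per-scan sd of 0.08 reflectance units
  aggregates instrument noise and the residual biological variability a
  two-trait forward model cannot represent; it was set so that the
  Scale7 SPA water model reaches a held-out R² near 0.72, the difficulty
  regime of field studies of this kind.  The forward model itself is
  deterministic given the traits.

What the generator does **not** emulate: radiative-transfer leaf optics
(PROSPECT-style multiple scattering), instrument line shape, wavelength-
dependent noise, and sample-to-sample continuum variation.  Passing tests
therefore demonstrate that the pipeline recovers structure it is designed
to recover under controlled conditions — not field performance on real
leaves.

## Continuous wavelet transform

W(a, b) = Σ_λ f(λ)·a^(−1/2)·ψ((λ − b)/a)·Δλ on the 1 nm grid, evaluated
by FFT correlation with mirror padding wide enough to cover the wavelet
support (support radius 8, where the Gaussian envelope is < 1e-14).  The
a^(−1/2) weight keeps scaled wavelets at unit L² norm; a documented
`l1_norm` switch provides the amplitude-preserving 1/a convention, which
rescales every scale's coefficients by a constant and leaves correlations
and regressions unchanged.  The default mother wavelet is gaus1 (unit-norm
first derivative of a Gaussian); gaus2/Mexican-hat and a zero-mean-
corrected real Morlet are available for comparison.  Scales are dyadic,
a = 2¹ … 2¹⁰ ("Scale7" ⇒ a = 128); scale-numbering conventions vary across
analyses, so the dyadic ladder follows the common chemometric convention
and is flagged as such.  Scales above half the band count (a = 1024 on 2000 bands) are
computed but flagged edge-affected, since mirror padding dominates them.

Correctness is pinned by two independent oracles: trapezoid-rule
quadrature of the defining integral (agreement ≤ 1e-6 relative on random
signals) and the closed form for a Gaussian trough under gaus1,

    W(a, b) = −d·A·√(2π)·σ·a^{3/2}·(b − c)/(σ² + a²)^{3/2}
              ·exp(−(b − c)²/(2(σ² + a²))),  A = √2·π^{−1/4},

which also fixes the zero-crossing-at-center property and the matched
scale a* = √3·σ at which the response magnitude peaks.

## SPA band screening

The chain is the classical greedy construction on mean-centred columns:
starting from a candidate band, repeatedly select the unselected column
with the largest norm after projection onto the orthogonal complement of
the selected span (implemented by incremental deflation; verified
index-by-index against a from-scratch least-squares projection oracle).
Ties break to the lower wavelength; numerically vanished projections
truncate the chain with a flag.  Candidate subset sizes 1…30 are scored
by validation RMSE of an ordinary multiple linear regression (the
canonical SPA inner model; PLSR scoring is a config switch), and the
global (start, size) minimum wins, ties preferring fewer bands.

Because a full scan over 2000 start bands is needlessly expensive, the
start pool defaults to the 50 bands with the highest |Pearson r| against
the trait at that scale (computed on the training block only); the full
scan remains available.  SPA's validation block is an internal 75/25
split of the training set — the held-out test set is never consulted by
any selection step.

## PLSR and metrics

PLS1 by NIPALS deflation, collapsed to a single coefficient vector so
predict(X) = (X − x̄)β + ȳ.  With the full component budget on full-rank
data the fit reproduces OLS (tested to 1e-6), and predictions match
scikit-learn's `PLSRegression(scale=False)` to 1e-8; the component count
is chosen by seeded k-fold cross-validation (argmin RMSECV, ties to the
smaller count).  Reported metrics:

* R² = 1 − RSS/TSS per split (test-set R² may be negative; not clamped);
* RMSE = √(RSS/n), so RSS = n·RMSE² holds identically;
* RPD = 1/√(1 − R²).  Two readings of the R²-derived deviation ratio
  circulate in the applied literature, 1/(1 − R²) and 1/√(1 − R²); the
  square-root form is adopted here because only it makes the benchmark
  pair (R² = 0.756, RPD = 2.02) internally consistent.  The conventional SD(y)/RMSE
  ratio is reported alongside as `rpd_sd`, clearly labelled, since the
  two coincide only for unbiased predictions.

## Orchestration and protocol

One train/test split (default seeded uniform random at 4:1, floor on the
train count: 232 → 185/47; Kennard–Stone optional) is fixed per
experiment and reused by every comparison.  Fusion candidates are ranked
by a train-internal validation R² computed from pooled out-of-fold
k-fold predictions over the training block — deliberately a different
data carve-up than SPA's fit/validation split, so SPA-tuned band sets
enjoy no home advantage when competing against fused alternatives.  Test
metrics are attached only to the ranking winner.  A `rank_on_test`
switch reproduces the alternative of ranking directly on test metrics,
for comparison with studies that report test-ranked tables.

## Problem sizes

Defaults throughout the analysis scripts: n = 232 samples, 2000 bands,
10 scales, SPA start pool 50, subset sizes up to 30.  The test suite
exercises the same code paths at reduced sizes chosen for a fast,
deterministic suite: the fusion-benefit study runs 20 seeds at n = 232
with start pool 10 and sizes up to 25; the end-to-end determinism check
runs the full pipeline twice at n = 116 with start pool 15 and sizes up
to 15 (determinism does not depend on problem size); the planted-band
recovery study uses 300-band spectra with two narrow (σ = 1.5 nm)
independent features at the matched scale a = 2, where "recovered"
means both centers appear in the selection within ±1 nm.

## Known limitations

* The generator's two-trait forward model cannot express trait-independent
  spectral variability; scan noise is its stand-in.
* Uniform RWC is an assumption; skewed field distributions would change
  the calibration targets through Var(Z) and Var(Z²).
* SPA's start-pool restriction is a tractability deviation from an
  exhaustive start scan; on pathological designs the global optimum can
  start from a low-correlation band.
* The dyadic scale ladder is a convention; other logarithmic ladders
  (e.g. 2^(k/2)) would shift which "scale number" is optimal.
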