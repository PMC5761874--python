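# Methods

This note documents the models, numerical choices and limitations behind
`dynconn`. It covers what each stage assumes, which knobs matter and why
their defaults are what they are, and what the synthetic-data generator can
and cannot tell you about real fMRI data.

## Conditional-correlation model of dFC

Each network pair is modelled as a bivariate ARMA(2,2)–GARCH(1,1) process
whose innovation correlation evolves through a DCC(1,1) recursion (see the
README for the equations). The assumptions this carries:

* **Gaussian innovations.** The quasi-likelihood is Gaussian; parameter
  estimates remain consistent under mild misspecification (QML), but the
  reported log-likelihoods are only exact under normality. Heavier-tailed
  innovations are out of scope.
* **Weak stationarity.** `φ + ψ < 1` per margin and `η₁ + η₂ < 1` are
  enforced by construction; the estimator cannot represent integrated
  (IGARCH-like) dynamics.
* **Predictable conditional moments.** The variance recursion uses the
  *lagged* squared residual `ε²_{t-1}` and the correlation recursion the
  lagged outer product `u_{t-1}u'_{t-1}` — the standard Bollerslev/Engle
  forms, under which σ_t and Q_t are measurable at t−1 and the one-step
  Gaussian likelihood is well defined.
* **Order (2,2)/(1,1) is a default, not a dogma.** `mean_order` is
  configurable; there is no automatic order selection.

### Estimation

Two-step QML. Step 1 maximizes each univariate ARMA-GARCH likelihood
jointly over (α, β, θ, ω, φ, ψ); step 2 fixes Ξ at the sample correlation
of the standardized residuals ("correlation targeting") and maximizes the
correlation part of the likelihood over (η₁, η₂). Numerical choices:

* **Reparameterization, not box constraints**: ω through `log`, (φ, ψ) and
  (η₁, η₂) through a logistic simplex map, so the optimizer (L-BFGS-B,
  objective tolerance 1e-8, 3 random restarts, then a tight Nelder–Mead
  polish) works on an unconstrained smooth surface.
* **Pre-sample values**: the first `max(p, q)` ARMA residuals are set to
  zero conditional on the observed start of the series; σ²₀ is the sample
  variance of the mean-model residuals; Q₀ = Ξ.
* **Standardization**: each series is divided by its sample SD before
  fitting (estimates are mapped back). Correlation is scale-free, and this
  makes the fit exactly invariant to rescaling an input series; the
  standardized series is rounded to single precision so rescaling cannot
  move the optimizer between points of a weakly identified ridge through
  last-bit noise.
* **Ridge identification penalty**: ARMA(2,2) has an unidentified
  common-factor manifold (near-cancelling AR/MA pairs) along which the
  likelihood is flat; a small fixed L2 penalty (`arma_penalty = 15`, not
  scaled by T, hence asymptotically negligible) selects the parsimonious
  point on such ridges. Similarly, restarts only replace the base start
  when they improve the objective substantially (10 log-likelihood units),
  so noise-level gains cannot drag estimates along flat directions.
* **No-dynamics comparison**: after the (η₁, η₂) search, the constant
  correlation solution η₁ = η₂ = 0 (ρ_t ≡ Ξ₁₂) is adopted whenever it
  attains at least the same likelihood, so near-static data yields a
  near-static trajectory rather than boundary noise.
* **Diagnostics**: every univariate fit reports the Ljung–Box statistic
  (lag 10) of its standardized residuals, a convergence flag, and the DCC
  step flags solutions pinned near η₁ + η₂ = 1.

The full likelihood decomposes exactly into a variance part (the two
univariate likelihoods) and a correlation part; `log_likelihood` returns
both and their sum, which the tests verify to 1e-8.

## Feature extraction

Seventeen features per trajectory. Defaults and the reasoning behind the
ones the data do not dictate:

* **Welch settings** (unspecified upstream): Hann taper, segment length
  `min(T, 128)` samples, 50% overlap, one-sided density scaling, no
  detrending. At T ≈ 300–450 and TR = 2 s this gives ≥ 3 segments while
  still resolving the 0.01 Hz lower edge of the ALFF band
  (128 × 2 s ⇒ df ≈ 0.004 Hz).
* **Magnitude vs power weights**: the moment and ordering features (SCO,
  SPR, SKW, KURT, SMED, SRO) and CREST/FLAT/SLOPE weight by the magnitude
  spectrum `M_k = √PSD_k`; PSE uses normalized *power*; ALFF-dFC averages
  `√PSD` over 0.01–0.08 Hz. SPR is the second central moment (Hz²) — the
  skewness and kurtosis normalizations (`SPR^1.5`, `SPR²`) require it, and
  the flat-spectrum closed form (discrete-uniform excess kurtosis
  −(6/5)(K²+1)/(K²−1)) confirms it.
* **Two spectral passes**: PEAK and ALFF-dFC are computed on the
  mean-removed trajectory with the DC bin excluded (a DC peak says nothing
  about oscillation frequency); all other spectral features retain the DC
  bin of the mean-retained pass.
* **FLUX** needs successive spectra but Welch averages them away; it is
  defined over the per-segment magnitude spectra Welch already computes,
  each normalized to unit sum so FLUX is amplitude-invariant. It needs at
  least two segments.
* **PEAK binning**: 8 equal-width bins over (0, Nyquist]; the bin with the
  largest average power wins and PEAK is the frequency of the largest PSD
  value inside it. Bin edges use half-open (lo, hi] intervals.
* **ZC threshold** `c = 0.001`: a sign change only counts when the jump is
  at least `c`, suppressing crossings driven by numerical noise around
  zero. PAV counts strictly negative values; exact zeros are not
  anticorrelated.
* **Entropy base 2** (bits); any base is monotone-equivalent.
* **Ties** in the SMED/SRO cumulative search go to the first qualifying
  bin.
* **Degenerate inputs**: an all-zero spectrum makes the moment features
  undefined (NaN, reported rather than fabricated); SPR = 0 makes SKW/KURT
  NaN; a constant trajectory gives ALFF-dFC = 0 (genuinely zero) and
  PEAK = NaN (no dominant frequency). A zero magnitude anywhere makes the
  geometric mean, hence FLAT, exactly 0.

Two known departures from idealized expectations, both consequences of
Welch windowing rather than of the feature formulas: a constant trajectory
has a tiny nonzero SCO (Hann leakage spreads the DC mass into the first
bin), and time-reversal invariance of the spectral features is exact only
when segments align under reversal and the taper is symmetric (the test
uses a boxcar taper and aligned length to isolate the mathematical
invariance).

## Baselines

Static FC is the full-length Pearson correlation. The sliding-window
estimator uses rectangular 80 s windows with 50% overlap (hop rounded to
the nearest sample, minimum 1; trailing partial windows discarded; no
taper, matching common sliding-window practice), summarized by the mean and
unbiased variance of the window series.

## Group inference

Per feature (optionally per network pair), the difference in group means
gets a BCa bootstrap interval: stratified resampling (each group resampled
independently, B = 1000 by default), bias-correction z₀ from the fraction
of bootstrap statistics below the observed value (with a ½-weight on ties
and clipping at 1/(2B)), and acceleration from the pooled group-wise
delete-one jackknife skewness. Two-sided p-values invert the interval
family — the smallest α at which the 1−α interval excludes zero, found by
bisection — because the upstream convention reports both intervals and
p-values without fixing a p construction. With z₀ = a = 0 the interval
reduces exactly to the percentile interval of the same draws. A
zero-spread bootstrap distribution yields a flagged point interval.

FDR control is Benjamini–Hochberg at q = 0.05, applied jointly across the
feature × pair family by default (configurable to per-pair families). The
sign convention is first group minus second group in `group_order`
(sorted labels by default), so positive differences mean larger values in
the first group.

## Prediction

Random Forests (500 trees by default; forest size is not tuned) with an
inner grid search on the two standard knobs — features-per-split
{1, ⌈√p⌉, ⌈p/3⌉, p} × minimum node size {1, 3, 5} — fitted on training
folds only, inside repeated stratified 5-fold cross-validation (30
repetitions). Stratification keeps both classes in every training fold at
n ≈ 48. All seven comparison models (dFC-feature RF, static-FC RF,
static-FC logistic, sliding-window mean/var/mean+var RFs, and the
majority-class naive rule) are evaluated on identical fold assignments per
repetition, so accuracy differences are paired. Summaries report both
normal-theory and percentile 95% intervals over repetition means, since
either convention is defensible.

Conditional permutation importance: for each feature, its out-of-bag
values are permuted within strata defined by each tree's own split points
on the features whose absolute correlation with it exceeds 0.2 (the
conventional threshold for this procedure); the importance is the mean
decrease in out-of-bag accuracy across trees. With no conditioning feature
above threshold this reduces to marginal permutation importance. The
defining behavior — an exact duplicate of an informative feature scores
far lower conditionally than marginally — is exercised in the tests.

## Synthetic data

The generator emulates the study conditions end to end: bivariate series
of length T ≈ 300–450 at TR = 2 s (configurable), ARMA(2,2) means,
GARCH(1,1) variances, and a correlation path that is either DCC-driven or
prescribed (constant, sinusoid, step). Deterministic modes build the
correlated shocks by a Cholesky factor of the 2×2 correlation at each time
point, so the recorded ground truth is exact and independent of DCC
dynamics; 200 burn-in samples are discarded so fixtures carry no
initial-condition transients; prescribed trajectories are indexed so that
t = 0 is the first recorded sample. Two-group cohorts (default 23 vs 25
subjects, matching a typical patient/control study) shift named features
through explicit generative handles: MV/PAV through the correlation
offset, VAR/ALFF-dFC through the sinusoid amplitude, PEAK/SCO/SMED through
its frequency.

What the generator does *not* emulate: hemodynamic convolution, scanner
drift and physiological noise, motion artifacts, spatial structure, or
non-Gaussian innovations. Passing tests therefore demonstrate correctness
of the estimation and inference machinery under the model's own
assumptions — not robustness to fMRI preprocessing residue.

## Problem sizes used in tests and the acceptance script

Parameter recovery runs at T = 4000 (50 seeds in the test suite, 20 in the
acceptance script); trajectory tracking at T = 450 over 20 (suite) / 10
(script) seeds; BCa coverage over 500 / 200 replicates at B = 1000; null
FDR calibration over 10 cohorts of 20 + 20 subjects; classifier checks use
a 25 + 23 cohort with 30 (suite) / 10 (script) CV repetitions at reduced
forest size (30–50 trees) and a 2 × 2 tuning grid. These sizes keep the
whole suite and the script comfortably reproducible on a single CPU while
leaving every conclusion Monte-Carlo stable.

## Known limitations

* Bivariate only: no multivariate (> 2 ROI) DCC, no higher-order
  DCC/GARCH, no stochastic-volatility alternatives.
* The two-step point estimate of ρ_t is conditioned on in all downstream
  feature inference; the uncertainty of the trajectory itself is not
  propagated (a hierarchical or time-series-bootstrap treatment would be
  needed).
* Welch-based features assume within-scan spectral stationarity of the
  dFC trajectory.
* The p-value construction (interval inversion) is one defensible choice;
  a separate bootstrap test would be another.
* Input is ROI/network time courses in delimited text; imaging-stack
  concerns (NIfTI/BIDS, preprocessing, network extraction) are upstream
  and out of scope.
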