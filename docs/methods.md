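# Methods

## Growth model and estimator

Cultures are assumed to grow exponentially and density-independently
within a transfer: N(t) = N₀·e^{μt}, with N₀ = 100 cells ml⁻¹ at
inoculation and densities staying well below carrying capacity
(~10⁵ cells ml⁻¹ in this regime). The default estimator is the
two-point rate μ = (ln N_t − ln N₀)/t in day⁻¹, computed per transfer
(densities reset to the inoculum at each transfer; the 14-day direct
co-culture assay spans two 7-day transfers and its per-transfer
estimates are averaged per well). A log-linear OLS fit over all sampling
days is available as an opt-in robustness check; on noise-free
exponential data the two agree to machine precision, which the test
suite asserts. Lag phases and saturation are deliberately out of scope:
the experimental regime is maintained inside the exponential window.

## Social-milieu scenarios and reactiveness

A lineage's effective growth rate in a scenario is
μ_eff = μ_mono · r(scenario, partner), where the reactiveness r is a
dimensionless multiplier, fixed at 1 for monocultures and self-pairs
(self cues are the experimental control). The built-in
"regression-to-range" parameterization,
r = (μ_mid/μ_mono)^γ with γ ∈ [0, 1], encodes the observed pattern that
slow growers accelerate and fast growers decelerate toward the
mid-range rate μ_mid. Responsiveness is graded by scenario: γ defaults
to 0.5 (direct co-culture) > 0.35 (ThinCert) > 0.2 (supernatant spike).

The response ratio is response = μ_treatment/μ_alone. Treatment wells
are matched to the mean monoculture rate of the same focal lineage,
environment and biological replicate; where a scenario has its own
self-pair control (e.g. the same lineage on both sides of a ThinCert
membrane) that control is preferred. Technical replicates are always
averaged first; biological replicates are the inferential unit, which
avoids pseudo-replication. All formal statistics are run on absolute
growth rates; response ratios are reported as descriptive tables.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not the biology producing it:

* **Layout.** Full factorial ordered focal × partner pairs (including
  self-pairs) for ThinCert and spike; monocultures per lineage; direct
  co-culture pairs every focal lineage with one designated
  GFP-transformed partner and produces two interleaved count series per
  well. Defaults: 6 lineages, 3 biological × 3 technical replicates,
  daily sampling, 7-day transfers.
* **Noise.** Multiplicative lognormal, median-unbiased (log-scale mean
  zero, so the mean log-density residual vanishes — asserted as an
  invariant). Each biological replicate population draws one growth
  deviate and one photosynthesis deviate (CV `cv_bio`, default 10%)
  shared across all its wells and scenarios, mirroring evolved
  replicate populations that pre-date the assay; every observed density
  gets independent technical noise (CV `cv_tech`, default 5%). The
  growth deviate multiplies μ rather than the densities: a pure density
  factor would cancel out of the two-point estimator and could not
  generate within-lineage growth variance. The cytometry CVs are
  stand-ins, not measured values.
* **Calibration presets** (the calibrated profiles): ambient
  monoculture rates span 0.45–1.1 day⁻¹; elevated-pCO₂ lineages grow
  faster on average with a √3.9-wider between-lineage spread (a
  3.9-fold variance increase); ambient photosynthesis is set so the
  NP/growth carbon ratio is 1.92, with the elevated surplus 1.14-fold
  lower; elevated reactiveness exponents are renormalized so the mean
  |log response| is 1.3-fold below ambient (a naive 1/1.3 shrink is
  overwhelmed by the wider growth spread amplifying the
  regression-to-range pull, and would invert the effect). These
  literature-derived numbers are generator inputs. Round-trip tests
  that recover them demonstrate internal consistency of the pipeline,
  not reproduction of any experimental result.
* **Events.** Cytometry-like tables draw per-class lognormal channels:
  intact cells high in fsc/fl3, debris low in fl3, GFP cells high in
  the green channel. Cell counts are Poisson around density × sampled
  volume so gated densities are unbiased. A hidden `event_class` column
  is retained for validation only. Real instrument artefacts —
  spillover, doublets, drift, non-lognormal debris — are not modelled,
  so passing gating tests show the thresholding logic is correct, not
  that the default thresholds suit any particular cytometer.
* **Plausibility guard.** Designs whose μ_eff exceeds 3 day⁻¹ (far
  beyond this organism's range) are rejected at construction.

## Carbon budget

Per-cell net photosynthesis (µmol O₂ cell⁻¹ h⁻¹) becomes
biomass-specific carbon fixation via
np_c = (np_O₂/PQ · 12.011)/Q_C (h⁻¹), with photosynthetic quotient
PQ = 1.4 mol O₂ mol C⁻¹ (a documented, config-overridable default — the
literature conversion factors are instrument- and taxon-specific) and
carbon quota Q_C in µg C cell⁻¹ (default 1.5 × 10⁻⁷, a realistic
picoplankton value; no size-to-carbon allometry is hard-coded). Growth
demand uses the instantaneous form μ/24 (h⁻¹); the compound form
e^{μ/24} − 1 differs by < 2% for μ ≤ 1 day⁻¹. The NP/growth ratio and
surplus percentage (ratio − 1) × 100 follow; a surplus ≤ 0 is labelled
`storage_use` — it means no surplus photosynthate is available, not
negative photosynthesis. Wells with μ ≤ 0 get a null ratio with reason
code rather than a misleading number.

## Regression-to-the-mean null model

Monoculture and mixed-culture rates are drawn independently from the
same truncated normal on [0.45, 1.1] day⁻¹ (mean = midpoint 0.775,
s.d. = range/6 ≈ 0.1083, truncated so all draws are admissible; the
source description is under-specified and these choices are
config-overridable). Because the numerator of the response is
independent of the denominator, E[response | μ_mono] ≈ E[μ_mixed]/μ_mono
— an L-shaped, strictly decreasing curve with strongly negative Spearman
rank correlation, and mean response ≥ 1 by Jensen's inequality. The
module reports quantile-binned mean responses and a least-squares c/μ
fit whose c estimates E[μ_mixed]; a degenerate s.d. = 0 configuration
yields all responses exactly 1 with a flagged, zero rank correlation.

## Mixed-model inference

Models are linear mixed-effects fits with a single random intercept per
biological-replicate population (the lineage × replicate cell). With one
random level, the two readings of the nesting declaration ("replicate
within lineage", the conventional default, and the reverse) give
identical fits; both are accepted.

Because the random structure is a single intercept, the profiled
log-likelihood is a function of one scalar θ (random variance /
residual variance) with a closed form over block-diagonal marginal
covariances. It is maximized by a bounded scalar search on log θ, which
is exact and stable at the θ = 0 boundary where generic gradient
optimizers fail on a singular Hessian; fixed effects and their
covariance follow by GLS at the optimum. ML fits agree with lme4 to
nine significant digits on a reference dataset (frozen in the test
suite); REML uses the statsmodels objective. Boundary variance
estimates are reported through a `singular` flag, never dropped.

Lineage enters likelihood-ratio tests as a fixed categorical factor
(Δdf = levels − 1); LRTs compare ML fits of nested fixed-effect
structures on identical data against the asymptotic χ² reference (no
Kenward–Roger or bootstrap corrections). AICc = AIC + 2k(k+1)/(n−k−1)
counts fixed effects plus both variance parameters in k. Reactiveness
models regress the response ratio on the monoculture surplus-NP
percentage per scenario, with an intercept-only alternative; the model
with smaller AICc is retained.

### Operating characteristics and their study sizes

The Monte-Carlo studies characterise the procedures at sizes chosen for
the property being measured:

* **Type-I error** (nominal 5%): 6 lineages × 60 biological replicates
  × 3 technical, with realistic replicate-level variance, 1000
  repeats — a replication level at which the asymptotic χ² reference is
  accurate (measured rejection ≈ 0.05). At the experimental scale of
  only 3 biological replicates per lineage the same asymptotic LRT is
  markedly anti-conservative (rejection near 13% at nominal 5%), and
  with zero replicate variance it is conservative (~3%) because the
  boundary variance estimate is absorbed asymmetrically by the reduced
  model. This is a genuine small-sample property of asymptotic LRTs on
  few replicate units and a caveat for interpreting borderline p-values
  at such designs.
* **Power**: 6 lineages × 9 replicates (the experimental scale) with a
  planted lineage effect of one within-lineage s.d.; power > 0.9.
* **Slope recovery / CI coverage**: replicate-level predictor spread
  mirroring the pipeline's per-replicate allocation measurements; Wald
  95% CIs cover at ≈ 0.92.
* **Variance-fold recovery**: a planted 3.9-fold between-lineage
  variance contrast at 60 lineages × 10 replicates is recovered through
  the full generator → growth → variance-partitioning path (median
  within sampling bounds of a variance-ratio statistic). The
  between-lineage component is the sample variance of lineage means, so
  it carries a small upward contamination of within-variance/n_rep in
  both environments; at the study sizes used this biases the fold by
  < 5%.

## Numerical and I/O choices

* Scalar profile search bounds: θ ∈ [10⁻¹⁰, e¹⁰], xatol 10⁻⁸ on log θ;
  the θ = 0 boundary is evaluated explicitly and preferred on ties.
* Constant-outcome data (zero variance) short-circuit to a degenerate
  fit with slopes 0 and the residual variance floored at 10⁻¹², keeping
  the log-likelihood finite.
* An LRT with Δdf = 0 (identical models) returns χ² = 0, p = 1; a
  log-likelihood *decrease* under the full model beyond 10⁻⁸ raises a
  refit error instead of reporting a negative statistic.
* All CSVs are written with a fixed column order and `%.12g` float
  format; metadata sidecars carry seed, version and parameters but no
  timestamps, so a fixed seed reproduces every output byte for byte.
* Empty event tables gate to density 0 with a warning; missing channel
  columns are errors.

## Limitations

* The generator's exponential-growth, lognormal-noise world contains
  none of the real data's complications (nutrient drawdown near the end
  of a transfer, counting error structure, plate effects, bacterial
  co-inhabitants), so green tests validate the analysis logic, not the
  biology.
* The calibration constants (growth range, 1.92 carbon ratio, 3.9-fold
  variance contrast, 1.3-fold response damping, 63.78/49.63/44.36%
  allocation) are inputs chosen to make the synthetic world resemble
  the published system; recovering them is a consistency check only.
* The asymptotic χ² LRT should be treated with caution at ≤ 3
  biological replicates per lineage (see operating characteristics).
* The O₂→carbon conversion assumes a fixed photosynthetic quotient and
  carbon quota per lineage; both are config inputs, not estimates.
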