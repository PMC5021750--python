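# Methods

## Observation model

Beaker-level juvenile growth of clone *i* at dietary EPA concentration
*S* (µg EPA mg C⁻¹) is modelled as

    y_ij = g0_i + (g∞_i − g0_i) · S_ij / (S_ij + K_S,i) + ε_ij,
    ε_ij ~ N(0, σ²),

where g0 is the growth rate without EPA supplementation (day⁻¹), g∞ the
asymptotic rate, and K_S the half-saturation constant. Growth rates are
either given directly or derived from dry masses, g = (ln Wt − ln W0)/t.

Fixed-effect families: **A** (a single K_S) and **B** (K_S,i = K0 + K_L·L_i
with body size L in mm). Clone-level random effects are independent
Gaussian deviations on the nested subsets {g0} ⊂ {g0, g∞} ⊂ {g0, g∞, K_S}
(models A1…A3 and B1…B3; Df = fixed effects + variance components +
residual variance = 5, 6, 7 for the A series and 6, 7, 8 for B). Where a
parameter has both a fixed and a random effect, a clone's total value is
their sum. Estimation is ML, not REML, because AIC and likelihood-ratio
comparisons across different fixed-effect structures require it.

## Marginal likelihood and optimisation

The random effects are integrated out per clone. The integrand's mode is
found by a damped (Levenberg-style) Newton solve, vectorised across
clones, using the analytic gradient and exact Hessian of the Monod mean;
the integral is then approximated by Laplace's method. Because g0 and g∞
enter the mean linearly, the integrand is exactly Gaussian for models
whose random effects involve only those parameters (A1, A2, B1, B2), and
the "approximation" is exact there; for a random K_S it is the usual
second-order approximation, and the package ships an adaptive 20-node
Gauss–Hermite evaluator (`marginal_loglik(..., method="gh")`) as an
independent cross-check (agreement to well within 0.05 log-units on small
instances).

Random-effect SDs are parameterised as ratios to the residual SD. Under
this parameterisation every log σ term cancels between the Gaussian prior
normaliser and the Laplace determinant, so the ML residual variance has
the closed form σ̂² = (penalised SSR)/N and is profiled out. The outer
optimisation (L-BFGS-B with finite-difference gradients, log-scale bounds
on K_S and the variance ratios) therefore runs only over the fixed effects
and up to three log variance ratios. Starting values come from per-clone
nonlinear least squares (profiled linearly in g0 and g∞, K_S searched on a
fixed log grid — also the deterministic per-clone fitter exposed as
`fit_per_clone_nls`); a five-point log-grid multi-start on K_S (family A)
or K_L (family B) selects the best starting point. If the quasi-Newton
pass reports failure, a derivative-free Nelder–Mead polish and one further
quasi-Newton pass are run (the fixed restart schedule). A variance ratio
at its lower bound (10⁻⁵) is reported as a collapsed (zero) random SD,
not an error. Convergence tolerances: relative objective change 10⁻¹³,
projected gradient 10⁻⁹.

K_S is kept positive by log-parameterisation in family A; in family B,
(K0, K_L) are unconstrained but parameter vectors making any clone's
K0 + K_L·L non-positive are rejected with an infinite objective, and
starting values are shifted minimally to keep the law positive over the
observed size range.

## Model selection, tests, thresholds, bootstrap

- AIC = 2·Df − 2·logLik; the six-model series is ranked on converged fits
  only, ties broken toward fewer parameters.
- Pairwise likelihood-ratio tests compare each A_k against B_k
  (χ² = 2·ΔlogLik floored at 0, one degree of freedom, upper-tail
  chi-square p).
- Saturation thresholds: S_p = K_S·p/(1−p) (so S₅₀ = K_S and S₇₅ = 3·K_S),
  computed at full precision and rounded to two decimals only for
  presentation.
- Residual bootstrap: residuals about the conditional (clone-specific)
  fitted values are centred, inflated by √(n/(n−p)) with p the number of
  fixed effects (a leverage-free small-sample correction), resampled with
  replacement at the observation level pooled across clones, added back to
  the fitted values, and the same spec is refit (warm-started at the
  original estimates). Default 1000 replicates; replicates that fail to
  converge are dropped, with more than 20 % dropped treated as an error.
  Both a full refit and a fixed-variance mode are available; the latter
  pins the variance *ratios* at their point estimates, the natural pinning
  under the profiled likelihood.

## Clutch-size analysis

Clutch counts exceed 1, while the arcsin-square-root transform
c′ = 2·arcsin(√c)/π needs values in [0, 1]; counts are therefore rescaled
by a ceiling (the dataset maximum by default, or a known scale) before
transforming, and the constant is reported with the fit. Clones that never
develop eggs and treatment cells without any eggs are omitted before
fitting, mirroring the growth analysis of reproduction. The transformed
values are then fit with the same mixed-model machinery.

## The synthetic-data generator

The generator emulates the study design the analysis was built for: twelve
clones of three species (body sizes 1.43–3.54 mm at first reproduction),
seven dietary EPA levels spanning 0–10 µg EPA mg C⁻¹, three replicate
beakers per treatment, six-day duration. The seven concrete grid values
{0, 0.5, 1, 2, 4, 7, 10} are a documented choice; only the range and count
are anchored.

Default truth values:

- K_S follows the size law with K0 = −1.239, K_L = 1.039 (ordinary least
  squares of the per-clone half-saturation anchors on body size; residuals
  < 0.005 µg EPA mg C⁻¹ everywhere, so the anchors and the law agree).
- g0 by species: 0.174 / 0.312 / 0.432 day⁻¹ for the small, medium and
  large species.
- g∞ = 0.55 day⁻¹, common to all clones. A common fixed asymptote keeps
  the generative process inside the fitted model family (model B1's
  structure: clone variation only in the baseline and through the size
  law), so that the model-selection operating characteristics have a
  well-defined true member. Per-clone optimal-food growth ceilings are
  retained as reference constants and can be supplied via
  `true_ginf_by_clone`, but data generated that way lie outside every
  member of the six-model series (unmodelled asymptote heterogeneity) and
  selection then favours the random-g∞ models.
- Clone-level random variation on g0 with SD 0.02 day⁻¹; beaker residual
  SD 0.02 day⁻¹, chosen to visually match the scatter of real growth-rate
  data at this scale. Both are free knobs. K_S deviations, when enabled,
  are redrawn until the clone's realised K_S is positive.

Clutch data are generated from the assumption the clutch analysis makes:
the Monod curve lives on the transformed scale, a(S) = a∞·S/(S + K_S),
with raw clutches c = c_max·sin²(πa/2) (c_max = 8 eggs) and the
transformed asymptote a∞ calibrated per clone so the grid-average clutch
of egg-bearing clones matches the species anchors (1.31 / 1.35 / 2.48
eggs). Two small-bodied clones (Dg, Dh) are eggless by default. Noise acts
on the saturation fraction with a quasi-binomial SD ∝ √(x(1−x)), which the
arcsin-square-root transform stabilises — so the generator reproduces the
mean–variance coupling that motivates the transform.

Fatty-acid samples are generated around per-clone anchor totals for the
eight-clone analysis sub-panel (neonate contents and newly-built-biomass
quotas for total FA, total PUFA, total ω-3 and EPA), decomposed to FAME
level (LIN = PUFA − ω3, the ω3 remainder split 80/20 between ALA and ETE,
the non-PUFA rest pooled as "other"; internally inconsistent printed-
precision combinations are clamped at zero, and the two missing quota
entries of clone DlE are synthetic plausible fills). Day-6 contents are
derived by inverting the quota identity at the mean sample dry masses
(489.55 µg neonate, 575.91 µg day 6). Sample noise is mean-one lognormal
(CV 0.15) on contents and Gaussian on dry masses.

What the generator does *not* emulate: maternal effects, density or
container effects, non-Gaussian beaker noise, EPA degradation over the
feeding day, correlated random effects, and any temperature dependence.
Passing tests therefore demonstrate correctness of the estimation
machinery under the stated design, not robustness to those real-data
features.

## Aggregation conventions and rank tests

Species-level fatty-acid tables are unweighted means of clone means, with
SE = SD(clone means)/√(clones); replicate counts differ per clone, and the
unweighted convention reproduces the most reference cells. Missing clone
values are excluded with the divisor reduced; single-clone species get a
blank SE. Kruskal–Wallis (tie-corrected, chi-square upper tail) is applied
to clone-level means grouped by species by default — the only grouping a
clone-mean table supports — with sample-level pooling available by passing
sample values instead. All-identical data return H = 0, p = 1 by
convention.

## Problem sizes used in the test suite

The simulation studies run at deliberately chosen scales: the
model-selection operating characteristics use 100 datasets (seeds 1–100)
under the default design plus 50 datasets for the no-size-effect
specificity arm; bootstrap calibration compares 200 bootstrap replicates
against 200 fresh simulated experiments; interval coverage of the size-law
slope is checked at 40 datasets × 50 replicates. The coverage check
asserts only against under-coverage (the scientifically harmful failure);
at 40 datasets the upper tail of the binomial is too coarse to bound
over-coverage meaningfully.

## Known limitations

- The Laplace approximation is exact only for linear random effects;
  random-K_S models (A3, B3) carry the usual O(m⁻¹) Laplace error,
  cross-checked but not corrected.
- The bootstrap resamples residuals pooled across clones and so assumes
  homoscedastic beaker noise; clone-specific error variances would require
  within-clone resampling.
- Model B3 places its random deviation additively on the clone's full
  K_S (around the size-law value); placing it on K0 instead would be an
  equivalent reparameterisation for prediction but changes the reported
  deviations.
- The arcsin-square-root rescaling constant is data-dependent when no
  ceiling is supplied, which couples the clutch fit's scale to the
  largest observed clutch.
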