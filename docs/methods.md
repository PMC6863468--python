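# Methods

## The temperature-response model

Dark respiration of a tissue is modelled as an exponential-quadratic
(log-polynomial) function of tissue temperature T (°C):

    R(T) = exp(a + b·T + c·T²)

`a` is the natural-log rate at 0 °C, `b` (°C⁻¹) the relative sensitivity at
low temperature and `c` (°C⁻²) its curvature with warming; with c < 0 the
log response flattens toward high temperatures. Temperatures are used in °C
throughout — the parameterisation is defined that way, and no Kelvin
conversion appears anywhere in the APIs or files.

Fitting is performed per individual × tissue series. The default
(`log_ols`) is exact least squares of ln(rate) on (1, T, T²): the model is
linear in its parameters on the log scale, so the fit is closed-form and the
multiplicative (lognormal) error model makes the log-scale residuals exactly
Gaussian. An alternative (`original_nls`) runs iterative least squares on
the flux scale, initialised from the log fit, for users who prefer additive
error weighting; both report RMSE on the original flux scale so the two are
comparable. A fit requires ≥ 4 usable points and ≥ 3 distinct temperatures.
Non-positive rates (occasional negative instrument readings) are dropped
with a warning rather than aborting a batch; groups that then fall below
the preconditions are enumerated in a failure report, never silently lost.

## The mixed-model ANCOVA

Each curve parameter (and, separately, ln(R_d,acc/V_cmax,acc)) is the
response in

    value ~ species + T_a + tissue_class + T_a:tissue_class + (1 | individual)

with T_a continuous and tissue class a four-level factor (leaf,
photosynthetic stem, non-photosynthetic stem, root). The random intercept
reflects that the tissues of one plant share an individual effect. Species ×
T_a interactions are deliberately excluded: the scientific hypotheses are
tissue-specific, not species-specific, and per-species cell counts are
small. Estimation is REML (statsmodels `MixedLM`). Unbalanced designs are
handled by the likelihood itself; no cells are dropped. For numerical
conditioning the response is standardised internally and every estimate is
rescaled afterwards — Wald statistics, t ratios and degrees of freedom are
invariant to response scaling.

**Type-II Wald tests.** Each term's χ² is computed from the fixed-effect
estimates and their covariance C = (XᵀV̂⁻¹X)⁻¹. Terms contained in a
higher-order interaction (here: T_a and tissue class, contained in their
interaction) are tested on the orthogonal complement of the containing
term's coefficients within the joint span, under the covariance inner
product — the same construction R's `car::Anova(type = "II")` uses, which
the test suite verifies directly against it.

**Marginal (least-squares-mean) trends.** The slope of a parameter versus
T_a for tissue class t is the contrast x(T_a = 1, t) − x(T_a = 0, t) applied
to the fixed effects, with species levels averaged with equal weight (the
conventional marginal-means definition; the weighting is a convention, not
an estimate). The intercept is the equal-weight species average of the
prediction at T_a = 0. The planned contrast compares the unweighted mean
slope of {leaf, Ps stem} against {non-Ps stem, root}, reported as
photosynthetic minus non-photosynthetic. Species marginal means average
tissue classes equally at the observed mean T_a; pairwise species
differences use the studentized-range (Tukey) adjustment.

**Degrees of freedom.** Satterthwaite by default: for a contrast l,
df = 2·(lᵀCl)² / Var(lᵀCl), where the variance of the variance is obtained
from the gradient of lᵀC(θ)l with respect to θ = (τ², σ²) and the inverse
REML Fisher information ½·tr(P V_j P V_k), P = V⁻¹ − V⁻¹XCXᵀV⁻¹. A
`residual` option (n − rank X) is available. Kenward-Roger — which
additionally inflates the small-sample covariance — is not implemented;
estimates and standard errors are identical under both, and on this
design's sample sizes (~240 parameter records) the df differ negligibly.
The test suite checks the Satterthwaite df against `lmerTest`/`emmeans` to
about 1%.

## Acclimated surfaces and the homeostasis ratio

The per-tissue marginal trends define parameter values at any acclimation
temperature, a(T_a) = a₀ + a₁·T_a etc., and hence the acclimated surface
R_d(T_t; T_a). The acclimated rate is its diagonal, R_d,acc = R_d(T_a; T_a).
The homeostasis ratio compares R_d,acc with the 25 °C reference (the
temperature the plants grew at before acclimation):

    Acclim_Homeo(T_a) = R_d(T_a; T_a) / R_d(25; 25)   for T_a < 25 °C
                      = R_d(25; 25) / R_d(T_a; T_a)   for T_a > 25 °C

The orientation swap keeps the statistic on the same side of 1 for under-
and overshoot, so 1 always means complete homeostasis. Useful analytic
facts, all enforced by tests: the value at the reference is exactly 1; a
surface with no parameter trends and b = c = 0 gives 1 everywhere; a
non-acclimating pure-exponential surface with b = 0.07 gives e^(−0.7) ≈ 0.497
at both 15 °C and 35 °C; and adding any constant to the basal parameter `a`
of every tissue cancels in the ratio. The homeostasis grid is computed at
full precision; rounding to two decimals happens only when a report table is
written. A per-individual variant (`acclim_homeo_individual`) exists for
exploratory use; the canonical statistic is the population-level one built
from the reconstructed surfaces.

The respiration-to-photosynthetic-capacity analysis evaluates each tissue's
R_d curve and the same individual's leaf V_cmax curve (per-gram) at
T_t = T_a and models ln(R_d,acc/V_cmax,acc) with the same mixed model. The
log-linear formulation is a modelling interpretation: trend lines of the
ratio against T_a are exponential, i.e. linear on a log scale, which is the
natural scale for a ratio of two log-polynomial quantities. Records with a
non-positive or non-finite rate are excluded with a warning.

## The synthetic-data generator

The generator emulates the features of the motivating experiment that the
inference depends on:

- **Design.** The `table1` preset reproduces the unbalanced sampling: 84
  individuals over 8 species × 5 acclimation temperatures (15–35 °C), up to
  three tissues each, no stem measurements for Z. mays, and a reduced
  per-cell count for the paired V_cmax series. A `balanced` preset and fully
  custom designs support focused tests. Which stems are photosynthetic is a
  biological assignment: green-stemmed herbaceous crops (C. sativa, G. max)
  yes, woody species no — yielding the four tissue classes.
- **Parameter trends.** Defaults anchor every tissue at a = −6.5
  (ln µmol g⁻¹ s⁻¹), b = 0.10 °C⁻¹, c = −0.0005 °C⁻² at T_a = 25 °C —
  mid-range basal rates and an instantaneous response that roughly doubles
  per 10 °C at moderate temperatures. Non-photosynthetic tissues drift at
  b: −0.005 °C⁻¹ and c: +8.3×10⁻⁵ to +9.4×10⁻⁵ °C⁻² per °C of T_a (the
  magnitudes estimated in the motivating experiment); photosynthetic
  tissues do not acclimate. Species (SD 0.5) and individual (SD 0.2)
  effects enter only the basal parameter `a`, matching the finding that
  only basal rates differ among species.
- **Noise.** Multiplicative lognormal with SD 0.15 on the log scale:
  respiration is strictly positive, and this makes the default log-scale
  fit exactly correctly specified. The measurement grid is
  {14, 23, 32, 41, 45} °C with the top point jittered N(0, 0.5 °C) per
  series, representing the instrument-limited "~50 °C" setpoint that in
  practice achieved ~45 °C with small between-individual variation (the
  jitter distribution is a choice; only means ± SE of achieved temperatures
  are reported).
- **Randomness.** One master seed; every (purpose, individual, tissue)
  triple derives its own `SeedSequence([seed, purpose, i, j])`, so enlarging
  the design never perturbs unrelated draws and equal inputs give bitwise
  equal outputs.

What the generator does *not* emulate: instrument error structure beyond
lognormal noise, A/Ci-curve fitting for V_cmax (its temperature series are
generated directly), stomatal or leak artefacts, temperature-dependent
noise, or any species × T_a interaction. Passing recovery tests therefore
demonstrate that the inference machinery is correct under the stated
generating model, not that real gas-exchange data meet those assumptions.

## Calibration checks and problem sizes

The test suite includes end-to-end frequentist calibration at sizes chosen
to give informative Monte-Carlo precision while keeping the default test
run short: 95% CI coverage of the four tissue b-slopes over 200 replicates
of the full 84-individual design (binomial SE ≈ 0.8 points at n = 800,
acceptance band 90–98%); type-I error of the interaction Wald test over 500
null replicates (band 2–9% at nominal 5%); and recovery of the
root/non-Ps-stem > leaf/Ps-stem homeostasis ranking in ≥ 18 of 20 seeds
under a truth with strong non-photosynthetic acclimation (the root basal
trend set to cancel the diagonal exactly — perfect homeostasis — and the
non-Ps stem at 80% of that rate).

## Numerical choices and degenerate inputs

- Curve fits reject < 4 points or < 3 distinct temperatures (`FitError`);
  the quadratic needs 3 df plus at least one for error.
- The ANCOVA rejects designs where T_a does not vary or a tissue class is
  observed at a single T_a (`SingularDesignError`), and raises
  `ConvergenceError` with diagnostics after exhausting an optimizer
  fallback chain (lbfgs → bfgs → cg → powell).
- A boundary REML solution (τ̂² = 0) is handled by pseudo-inverting the
  Fisher information; if the Satterthwaite denominator degenerates, the
  residual df is used as a fallback.
- With zero residual and random-effect variance the mixed model reproduces
  OLS exactly (the GLS estimator is invariant to V when the data sit on the
  fixed-effect surface) — kept as a test oracle.
- Ties at the homeostasis reference: `acclim_homeo` returns exactly 1.0 at
  T_a = T_ref by definition, avoiding 0/0-style round-off.

## Known limitations

- Kenward-Roger df are not offered; Satterthwaite is the only small-sample
  approximation (see above).
- The Wald χ² tests are asymptotic; at much smaller designs than the
  default they can be mildly anticonservative (the type-I calibration test
  bounds this at the design sizes used).
- No Arrhenius/Q10 model family, no model selection, and no per-parameter
  uncertainty from the curve-fit stage is propagated into the ANCOVA (each
  fitted parameter enters as a point estimate, as in the standard
  two-stage workflow).
- The deposited-data adapter for externally published datasets is limited
  to the documented CSV schema.
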