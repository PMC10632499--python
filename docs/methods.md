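# Methods notes

## Scope and shape

`splitstat` compares two analytic routes for continuous predictors of a
continuous outcome: (a) discretize the predictors and run a factorial ANOVA;
(b) keep them continuous and fit a moderated/polynomial regression, probing
any interaction or curvature. The estimation core follows the statsmodels
idiom — a model object built from a DataFrame whose `fit()` returns a
results object — because everything downstream (partial statistics, simple
slopes, Johnson–Neyman regions) is a deterministic function of one fitted
OLS: its coefficients, their covariance, and the residual degrees of
freedom. Ordinary OLS estimation and the Type III ANOVA decomposition are
delegated to statsmodels; the probing algebra, attenuation theory, power
search, discretization bookkeeping and all Monte-Carlo engines are
implemented here.

## Synthetic study generators

Both generators draw a latent standard bivariate normal with the target
predictor correlation, map the latents onto instrument scales, evaluate a
deterministic truth model, add Gaussian noise, and clip the outcome to the
instrument range. Defaults (packaged in `configs/study1.json` and
`study2.json`):

| parameter | Study 1 | Study 2 |
|---|---|---|
| predictor 1 | health literacy, integers 0–9, mean 5.61, SD 1.54 | cognitive restraint, 1–4, mean 2.61, SD 0.56 |
| predictor 2 | nutrition knowledge, integers 0–20, mean 10.73, SD 3.26 | BMI, 17.0–60.7 kg/m², mean 27.99, SD 6.05 |
| latent correlation | 0.30 | 0.04 |
| truth model | ŷ = 1.53 + 0.17·NK + 2.52·HL − 0.20·HL² | ŷ = 276.10 + 24.22·CRc − 3.75·BMIc − 2.84·CRc·BMIc (c = centered at 2.61 / 27.99) |
| outcome range | label accuracy 0–16 | carotenoid score 29–709 |
| noise SD | 2.3163 (calibrated to model R² ≈ 0.17) | 110.8926 (calibrated to R² ≈ 0.059) |

Design choices:

- **Integer scales** (Study 1) are produced by an affine map of the latent
  to the target mean/SD, rounding to the nearest integer, and clipping to
  the instrument range. The latent correlation is used as-is: rounding
  attenuation at these granularities is under 2%, and all recovery checks
  run against the realized columns, not the latents.
- **Bounded continuous scales** (Study 2) are sampled by rejection from a
  normal whose underlying mean and SD are solved (once, deterministically)
  so that the *truncated* distribution has the target moments. Using the
  target moments as the untruncated parameters would shift the realized BMI
  mean by ≈ 0.5 kg/m² because the lower bound sits only 1.8 SD below the
  mean.
- **Noise calibration.** The residual SD is not reported for either study;
  the model R² is. Each default noise SD was found by bisection on the
  realized R² of a truth-model refit at n = 10⁶ and frozen as a constant, so
  routine generation involves no optimization.
- **Outcome clipping** is applied after noise, mimicking bounded instrument
  scores. This makes the realized data deviate slightly from the linear
  truth near the bounds: refitted coefficients carry a small systematic
  attenuation (up to ~1.5 Monte-Carlo SDs of a single n = 50,000 refit, a
  few percent relative). Recovery checks therefore compare estimates to
  truth on the scale of a single refit's Monte-Carlo SD, estimated across
  20 seeds.

What the generators deliberately do **not** emulate: item-level responses
(and hence reliability structure), demographic covariates, non-Gaussian
residuals, and any real-data missingness. Passing tests show the machinery
is internally correct under these idealized conditions, not that any real
dataset behaves this way.

## Discretization conventions

Values equal to a breakpoint go to the **lower** group ("X or lower is
low"), matching how fixed cuts are phrased in practice; the CDC BMI
classification is the exception and uses half-open [lo, hi) intervals so
that 18.5 is "healthy weight" and 30.0 is "class 1 obesity". The median is
the ordinary mid-order statistic (mean of the two central order statistics
for even n); a constant column raises a degenerate-split error, while a cut
that leaves one empty group is legal at this stage and rejected later by
the ANOVA (empty-cell error).

## Probing and Johnson–Neyman numerics

Both slope kinds share one form: ω(m) = b₁ + g·b₃·m with gain g = 1
(interaction) or g = 2 (quadratic — the *derivative* slope b₂ + 2b₃x, which
is the quantity whose significance band brackets the parabola's vertex).
Boundaries solve the quadratic A·m² + B·m + C = 0 with A = g²(b₃² −
t²V₃₃), B = 2g(b₁b₃ − t²V₁₃), C = b₁² − t²V₁₁, using the numerically stable
two-root formula. The critical value is the central t at the fit's residual
df (not the normal), matching standard macro behavior at these sample
sizes. Degenerate cases: |A| below 1e-12 of the coefficient scale falls
back to the linear equation; a discriminant within rounding of zero is
reported as a single boundary with a `touches` flag; a negative discriminant
means a uniformly significant or uniformly non-significant axis. Regions are
clipped to the observed moderator range (unclipped roots are also recorded),
and every interval is classified by a direct t test at its midpoint rather
than by inference from the root pattern. All moderator values live on the
design scale: if the fit centered the moderator, boundaries are deviations
from its mean, which makes centering equivariance (shift by −c) exact.

## ANOVA, effect sizes, power

Type III sums of squares with sum-to-zero effect coding are the convention
implied by unbalanced-cell analyses in SPSS-style software; marginal means
are unweighted means of cell means with SEs from the pooled error MS, and
Bonferroni contrasts multiply raw p by the number of level pairs (capped at
1). Partial η² is SS_effect/(SS_effect + SS_error); for regression terms the
squared partial is t²/(t² + df_resid) and the squared semipartial is the R²
drop from refitting without the term.

Power for an R² increment uses Cohen's noncentrality λ = f²(u + v + 1) with
u the numerator df and v = N − p − 1, evaluated as the noncentral-F survival
probability at the central-F critical value; the required N is the smallest
integer whose power reaches the target (bisection after doubling). This
convention — rather than the frequently quoted λ = f²N — is what reproduces
the planning numbers the studies report (e.g. N = 462 for ΔR² = 0.015 in a
3-predictor model at α = 0.05, power 0.80); the two differ by two
observations here.

Cohen's d is computed from the pooled within-group SD. The d values one
might print alongside a 2×2 ANOVA are not uniquely recoverable from
marginal means and SEs alone, so `cohens_d` takes its three inputs
explicitly.

## Dependent correlations

Comparing r(X,y) with r(split-X,y) on the same sample is a comparison of
two dependent overlapping correlations. The default test is Steiger's Z̄₁*
with the pooled correlation in the covariance term; the
Meng–Rosenthal–Rubin variant is available via `method="meng"`. Simulation
with an independent pair (both correlations null) shows the Steiger test
holds its nominal 5% level under median-splitting to within Monte-Carlo
error, even though the split variable is binary rather than normal.

## Monte-Carlo engines

- `spurious_increase_rate` re-estimates the sample median inside every
  replicate (as an analyst would) and compares absolute correlations, since
  "an increase in the correlation" is about magnitude. The default split
  rule dichotomizes **one** variable: at ρ = 0.10, n = 300 this is the
  regime where the population attenuation (≈ 20%) is small enough relative
  to sampling error for the rate to exceed 28%; splitting both variables is
  available as an option.
- `spurious_anova_rate` exploits the 1-df identity (Type III F = squared
  effect-coded t) for a fast vectorized 2×2 ANOVA per replicate, run in
  parallel with the continuous regression on the same draws.
- `power_comparison_study2` generates full Study 2 tables per replicate and
  tests the interaction both ways; the regression t of the product term is
  centering-invariant, so the raw-scale product is used internally.

Default problem sizes — 10,000 replicates for rate estimates, 2,000 for the
power contrast at n = 586, 10⁷ draws for closed-form vs. Monte-Carlo
agreement, 20 seeds × 50,000 rows for parameter recovery — keep binomial
Monte-Carlo error well below the margins being tested while the full suite
runs in well under a minute on one core.

## Known limitations

- The percent-reduction convenience returns exact arithmetic
  (100·(8.8 − 2.0)/8.8 = 77.27…); published one-decimal figures computed
  from unrounded inputs may differ in the last digit.
- The phi coefficient for arbitrary cuts relies on the bivariate-normal CDF
  (scipy), accurate to ~1e-8 — far below Monte-Carlo resolution but not
  exact arithmetic; the arcsine closed form for median cuts is kept as an
  oracle.
- `ModeratedOLS` refuses missing data (listwise refusal, not deletion) and
  rank-deficient designs rather than attempting repairs.
- Johnson–Neyman boundary endpoints reported for real datasets depend on the
  fitted coefficient covariance; two samples from the same population will
  not share boundaries, which is itself one of the arguments against
  sample-dependent cut points.
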