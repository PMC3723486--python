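# Methods

## Data-generating model

The synthetic-cohort generator and the power engine share one
data-generating process. Per participant,

    BMI_i = β₀ + β_G·G_i + β_E·A_i + β_GE·G_i·A_i + ε_i,  ε_i ~ N(0, σ²),

with defaults β_G = 0.154 kg/m² per allele, β_E = −0.313 kg/m² (active vs
inactive), β_GE = −0.07 kg/m² per allele per activity unit, σ = 3.5 kg/m²,
G ~ Normal(mean 11.2 alleles, variance 5.06 alleles²), and A ∈ {0, 1} with
30% inactive. These are the published base conditions for this study
design; σ is interpreted as the *residual* SD of BMI given the predictors
(the residual-vs-marginal distinction changes results by < 1% at these
effect sizes, but only the residual reading reproduces the standard
required-N benchmarks). The intercept defaults to 25 kg/m², putting the
mean BMI near 26.5 — a realistic adult European value; it affects no
inferential quantity.

Two GRS variance conventions circulate for this panel (SD 2.2 → variance
4.84, vs variance 5.06). We use 5.06: it is the value consistent with the
benchmark power results (83% at N = 20,000; dichotomization penalty
ratio ≈ 20.2), and the generator exposes it as an explicit parameter.

Genotype-level simulation draws each locus dosage as Binomial(2, f_j)
under Hardy-Weinberg proportions, loci independent (no linkage
disequilibrium — the score treats loci as exchangeable components). The
default frequency panel is two blocks (six loci at f = 0.2715, six at
0.6618) chosen so the summed-dosage GRS satisfies the arithmetic
identities Σ2f_j = 11.2 and Σ2f_j(1−f_j) ≈ 5.06; real panels with the
same sums behave identically for every quantity computed here.

Age (Uniform 30–70 years) and sex (Bernoulli ½) are generated as pure
noise covariates: they carry no BMI effect, so the adjusted and unadjusted
interaction estimands coincide and adjustment code paths are exercised
without biasing recovery checks. A 4-level CPAI consistent with the binary
variable (level 1 ⇔ inactive; levels 2–4 distributed 38/33/29% among the
active) is attached for interface completeness.

### Correlated exposure

When a GRS–activity correlation ρ is requested with a *binary* exposure, a
Gaussian copula is used: a latent standard normal Z with correlation
ρ_lat to the standardized GRS is thresholded at Φ⁻¹(p_inactive). Since
Cov(G_std, 1{Z ≥ z_p}) = ρ_lat·φ(z_p), setting
ρ_lat = ρ·√(p(1−p))/φ(z_p) makes the realized point-biserial correlation
approximate ρ while preserving the marginal inactive fraction exactly in
expectation. The mapping is exact for normal GRS and accurate to O(1/√n)
otherwise; requests with |ρ_lat| ≥ 1 (e.g. ρ = 0.9 at p = 0.05) are
rejected as infeasible.

A caveat discovered while validating the engine: with the thresholded
*binary* exposure, increasing ρ slightly *shrinks* the residualized
variance of the product term G·A (about −5% at ρ = 0.2), so power is
mildly decreasing in ρ under that coding. The familiar claim that
predictor correlation *raises* interaction power holds for jointly
*normal* predictors, where the residual product variance is
σ²_G·σ²_A·(1+ρ²). `PowerScenario(activity_normal=True)` selects that
coding — activity as Normal(1−p, p(1−p)) — and both the analytic formula
and the simulation then reproduce the increasing-power behaviour; the
monotonicity test uses this coding.

## GRS construction

Dosages are oriented to count the BMI-raising allele (d → 2−d flips where
the coded allele is the non-risk allele or its strand complement;
ambiguous A/T and C/G sites without resolvable strand raise a warning and
are kept as coded). QC reports per-locus call rate (threshold 0.95) and a
1-df chi-square Hardy-Weinberg test (threshold P > 0.001) without a
continuity correction — adequate at these sample sizes, and the exact test
adds nothing at a 12-locus scale. QC failures *flag* rather than drop:
retaining a flagged locus and re-running without it is the intended
sensitivity analysis.

Missing genotypes are imputed with the expected dosage
2 × (risk-allele frequency among called participants) for participants
missing ≤ 4 of the 12 loci; participants missing more are excluded. The
alternative — rescaling the observed sum by 12/(observed loci) — was
rejected because expected-dosage imputation keeps the score in allele
units and is unbiased under missingness at random (verified: the imputed
cohort mean matches the complete-data mean within Monte-Carlo error).
Complete-data scores are integers in [0, 24] by construction.

Dichotomization uses a strict cut (1 iff GRS > cut): 11 alleles for
descriptive stratification, the distribution mean for power scenarios. A
mean cut of a normal GRS yields an indicator of variance p(1−p) = 0.25,
the maximum; any other cut gives less — this variance collapse (5.06 →
0.25) is the entire mechanism of the dichotomization penalty.

## Activity index

The CPAI cross-tabulates occupational activity (4 categories) with
leisure-time exercise frequency (4 categories). The published index's
exact 4×4 cell assignment is consortium-internal; the default crosswalk
here is `level = min(4, occupational + leisure − 1)`, which satisfies the
documented anchor cells (sedentary job + occasional exercise → inactive;
physically straining job → active regardless of leisure) and is monotone
in both inputs. It is a config-overridable matrix so the exact mapping
can be substituted where known. Missing leisure is assigned the lowest
category before lookup (never raising the level); missing occupational
data yields no CPAI and routes the participant to the binary variable.

The binary variable splits any ordered activity measure at its empirical
20th percentile, ties going to inactive (keeping "bottom 20%" a lower
bound; the realized fraction is reported and can exceed 20% under heavy
ties). The split is invariant to strictly monotone transforms.

## Regression models

BMI models are OLS with both marginal terms always accompanying the
product term; obesity models are maximum-likelihood logistic on the
obese (BMI ≥ 30) vs normal (18.5 ≤ BMI < 25) contrast, excluding
overweight and underweight. Adjustment covariates are age (centered
before squaring, to avoid near-collinearity between age and age²), sex,
and study-center indicators for multi-center cohorts; a single-center
cohort drops the center term with a warning, and any residual rank
deficiency is resolved by dropping later collinear columns, warned.
Interaction p-values are large-sample Wald tests (t and z are
indistinguishable at these n). CPAI enters interaction models as a 1–4
trend variable — one interaction coefficient per cohort, as pooled
downstream — rather than as indicators.

Stratified genetic effects refit the GRS main-effect model within
activity strata; for a two-level stratification the slope difference
(with SE √(SE₀² + SE₁²)) approximates β_GE, exactly equal to the
interaction coefficient when the model is saturated in activity (no
shared covariate coefficients). Adjusted group means use a cell-means
parameterization with centered covariates, so each cell coefficient is
the predicted BMI at average covariate values.

The weight-equivalent conversion is grams = β × height² × 1000 at a
reference height of 1.70 m, exact and linear before display rounding.

## Meta-analysis

The primary pooling weights by cohort sample size (w_i = n_i), with
pooled SE √(Σw²se²)/Σw — the weighted-sum variance under independence
(the size-weighted convention does not itself define a variance formula).
Inverse-variance fixed-effect and DerSimonian-Laird random-effects
pooling (τ² = max(0, (Q−df)/C), C = Σw − Σw²/Σw) are sensitivity methods.
Heterogeneity is always reported on the conventional scale: Cochran's Q
with inverse-variance weights, df = k−1, I² = max(0, (Q−df)/Q)·100, and
an upper-tail chi-square p. All three pooling methods coincide when
cohorts share n and se (tested).

## Power engine

`simulate_power` draws (G, A, BMI) per iteration, fits OLS with the
product term by direct normal-equations solve (a 4×4 system — two orders
of magnitude faster than a full regression framework, and verified
against it to 10⁻¹⁰ on fixed data), and rejects when |β̂_GE/SE| exceeds
z_{1−α/2}. Singular designs (possible at tiny n, e.g. an all-active
draw) are redrawn and counted. Default 1,000 iterations gives a
Monte-Carlo SE of ≈ 1.3 percentage points near 80% power.

`required_sample_size` bisects the analytic power curve (exact to the
integer) whenever a closed form exists — independent predictors, or
correlated normal predictors via the (1+ρ²) factor — and falls back to
bisection on simulated power otherwise; an optional confirmation
simulates at the returned N. Reported values are rounded to the nearest
1,000, matching the precision at which such requirements are meaningfully
stated; the exact integer is retained. When the GRS is dichotomized, β_GE
is kept on the per-unit scale unchanged ("all else held equal"), which is
what makes the continuous-vs-binary comparison a pure variance story.

Problem sizes used by the test suite and the acceptance script — 200,000
participants for parameter recovery, 1,000–2,000 iterations for power and
size calibration, 500-iteration confirmations at the searched N — were
chosen so every Monte-Carlo comparison has its stated 3-SE resolution
while a full run completes in about a minute on one core.

## Numerical conventions

* Two-sided tests throughout; α = 0.05 unless configured.
* Strict inequality at dichotomization cuts (GRS > cut ⇒ 1).
* Ties at the activity split go to inactive.
* Bisection searches the smallest integer n with power ≥ target.
* All randomness flows through `numpy.random.default_rng` with explicit
  integer seeds; multi-cohort and sweep runs derive child seeds via
  `SeedSequence((master, index))`, so any sub-run is independently
  reproducible.
* Monomorphic loci report HWE p = 1 with a note (no information, not a
  violation).

## What the synthetic data do and do not show

The generator matches the first two moments and the interaction structure
of the target design, so passing tests demonstrate that the estimators,
pooling formulas and power calculations are correct *under the stated
model*. Real cohort data differ in ways the generator deliberately omits:
linkage disequilibrium between loci, activity misclassification,
confounding of activity with age/sex/BMI (reverse causation included),
non-normal BMI tails, and between-cohort differences in activity
instruments. Results on synthetic data therefore validate the machinery,
not the substantive interaction finding; the per-cohort estimates of any
real consortium cannot be reproduced from this package alone.

## Known limitations

* Power is implemented for the continuous-BMI interaction test only; the
  logistic (obesity) interaction test has no power machinery here.
* The simulation-bisection path for correlated binary exposure inherits
  Monte-Carlo noise into the returned N; treat it as ±2 MC-SE wide.
* Expected-dosage imputation assumes missingness independent of genotype;
  informative missingness biases the score slightly toward the cohort
  mean.
* The default CPAI crosswalk is a constrained reconstruction, not the
  published consortium mapping.
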