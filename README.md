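# gxepower

Gene × physical-activity interaction analysis for obesity genetics: genetic
risk score (GRS) construction, activity-index derivation, interaction
regression, multi-cohort meta-analysis, and — centrally — a Monte-Carlo and
analytic power/sample-size framework for interaction tests.

## Who this is for

Genetic epidemiologists planning or meta-analysing GRS × environment
interaction studies of BMI. Large consortium analyses of the 12 established
obesity-susceptibility loci (FTO, SEC16B, MC4R, …) test whether physical
activity attenuates aggregate genetic risk; such interaction effects are
small (|β_GE| ≈ 0.01–0.07 kg/m² per allele per activity unit), and the
sample size needed to detect them depends sharply on design choices —
dichotomizing the GRS or the exposure, the exposure's prevalence,
predictor correlation, and outcome measurement error. This package makes
those trade-offs computable, and provides the full analysis pipeline so
every stage can be validated on synthetic cohorts with known truth.

## The model

Per participant, BMI follows the linear interaction model

```
BMI_i = β₀ + β_G·G_i + β_E·A_i + β_GE·G_i·A_i + ε_i,   ε_i ~ N(0, σ²)
```

with `G` the unweighted count of BMI-raising alleles across 12 loci
(range 0–24; population distribution ≈ Normal(11.2, 5.06)) and `A` a
binary activity indicator (1 = active; 30% inactive by default). The Wald
test of β_GE has noncentrality

```
λ = n · β_GE² · v / σ²,    v = Var(G_eff) · p(1−p)
```

where `Var(G_eff)` is the GRS variance (5.06 continuous; 0.25 after a
mean split) and `p` the inactive prevalence, giving analytic power
`Φ(√λ − z_{1−α/2}) + Φ(−√λ − z_{1−α/2})`. The Monte-Carlo engine
simulates cohorts, refits the model per iteration, and counts rejections;
the closed form serves as its oracle.

Supporting stages: 12-SNP GRS building with call-rate/HWE QC and
expected-dosage imputation (participants missing ≤ 4 genotypes); the
Cambridge Physical Activity Index (CPAI) cross-tabulating occupational and
leisure activity into 4 levels, with an 80/20 binary fallback;
obese-vs-normal logistic regression; and sample-size-weighted
meta-analysis with Cochran's Q / I² heterogeneity and forest-plot export.

## Worked example

```python
import gxepower as g

cohort = g.simulate_cohort(g.CohortSpec(n_participants=50_000, seed=7))
res = g.BMIInteractionModel.from_cohort(cohort).fit()
est, se, p = res.term("grs:activity_binary")
print(f"interaction beta = {est:.4f} (SE {se:.4f}), p = {p:.3g}")

scenario = g.PowerScenario(n=20_000)           # base study conditions
print(f"analytic power at N=20,000: {g.analytic_power(scenario):.3f}")
sim = g.simulate_power(scenario)
print(f"simulated power: {sim.power:.3f} +/- {sim.mc_se:.3f}")
req = g.required_sample_size(g.PowerScenario(n=20_000, grs_binary=True))
print(f"required N, dichotomized GRS: {req.n_rounded}")
```

prints

```
interaction beta = -0.0428 (SE 0.0152), p = 0.00498
analytic power at N=20,000: 0.830
simulated power: 0.836 +/- 0.012
required N, dichotomized GRS: 374000
```

The cohort was generated with a true β_GE = −0.07 kg/m² per allele per
activity unit; the refit recovers it within sampling error (the estimate
−0.043 is 1.8 SE from the truth). At the base conditions a study of 20,000
yields 83% power for that effect, but collapsing the GRS to a
high/low indicator (variance 5.06 → 0.25) inflates the required sample to
roughly 370,000 — the dichotomization penalty, a ratio of about
5.06/0.25 ≈ 20.

A `gxepower` command-line tool exposes the same pipeline
(`simulate`, `grs`, `cpai`, `fit`, `meta`, `power` subcommands), reading
TSV/VCF inputs and YAML/JSON scenario configs.

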