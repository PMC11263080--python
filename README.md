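# mrmediate

Two-sample Mendelian randomization (MR) mediation analysis from GWAS summary
statistics.

Observational links between diseases — say, an autoimmune disorder and a
musculoskeletal condition — are confounded by lifestyle, treatment and
reverse causation. MR sidesteps this by using genetic variants as
instrumental variables: alleles are randomized at conception, so the
regression of outcome effects on exposure effects across independent,
strongly-associated variants estimates a causal effect from nothing but two
published GWAS. `mrmediate` implements that workflow end to end, and then
asks the follow-up question epidemiologists actually care about: *through
what intermediate does the effect run, and how much of it?* — screening
candidate mediators (e.g. hundreds of immune-cell phenotypes) by two-step MR
and quantifying each survivor's share of the total effect.

The package is aimed at genetic epidemiologists who have summary-statistic
tables and want a reproducible, fully seeded pipeline rather than a chain of
one-off scripts.

## What it computes

For harmonized per-variant effect pairs (β̂_Xj, β̂_Yj) with standard errors:

- **Wald ratios** θ̂_j = β̂_Yj/β̂_Xj, σ̂_j = se_Yj/|β̂_Xj|
- **IVW**: θ̂ = Σσ̂_j⁻²θ̂_j / Σσ̂_j⁻² (fixed or multiplicative random effects)
- **MR-Egger** (slope + directional-pleiotropy intercept), **weighted
  median**, **Cochran's Q / I²**, **MR-PRESSO** (global, outlier and
  distortion tests with one restart after outlier removal), leave-one-out
- **Multivariable MR**: MV-IVW, MVMR-Egger, MVMR-median (exact weighted LAD),
  MVMR-Lasso (per-variant pleiotropy intercepts, heterogeneity stopping rule)
- **Two-step mediation**: a (exposure→mediator, IVW), b (mediator→outcome
  MV-IVW adjusted for the exposure), indirect effect a·b, and the proportion
  mediated a·b/c with Delta-method CIs:

  se(a·b) = √(a²se_b² + b²se_a²),  var(a·b/c) ≈ se_ab²/c² + (a·b)²se_c²/c⁴

Instrument selection (p < 5×10⁻⁸, greedy LD clumping at r² ≥ 0.001 in a
10,000 kb window, confounder blacklist, F > 10), allele harmonization with
palindrome handling, and a synthetic summary-statistics generator with known
causal truth are all part of the package — no downloads are needed to test
or demonstrate anything.

## Worked example

Simulate a mediation system with known truth — exposure → mediator → outcome
with a = 0.2, b = 0.3, direct effect c′ = 0.04, so the total effect is
θ = 0.1 and the true proportion mediated is 0.6 — then run the full
pipeline:

```python
from mrmediate import (SimConfig, simulate_mediation_system,
                       PipelineConfig, run_mediation_pipeline)

exposure, mediator, outcome, truth = simulate_mediation_system(SimConfig(seed=3))
report = run_mediation_pipeline([exposure], outcome, [mediator],
                                PipelineConfig(seed=3))
print(report.uvmr_table[["exposure", "method", "n_snps", "odds_ratio",
                         "or_ci_low", "or_ci_high", "pval"]].round(4))
row = report.mediation_table.iloc[0]
print(f"a={row['a']:.3f}  b={row['b']:.3f}  c={row['c']:.3f}")
print(f"proportion mediated = {row['proportion_pct']:.1f}% "
      f"(95% CI {row['ci_low_pct']:.1f} to {row['ci_high_pct']:.1f}%)")
```

prints

```
    exposure          method  n_snps  odds_ratio  or_ci_low  or_ci_high  pval
sim_exposure      ivw_random      55      1.1008     1.0746      1.1278 0.000
sim_exposure           egger      55      1.0886     1.0246      1.1565 0.006
sim_exposure weighted_median      55      1.1024     1.0678      1.1380 0.000
```

```
a=0.169  b=0.300  c=0.096
proportion mediated = 52.8% (95% CI 31.0 to 74.6%)
```

Reading: of the 100 simulated exposure instruments, 55 survive selection and
harmonization; all three estimators agree on an odds ratio ≈ 1.10 per unit
exposure (true θ = 0.1, e^0.1 ≈ 1.105). The mediator passes all four
screening gates (a significant, no reverse signal, adjusted b significant,
sign-consistent), and its estimated share of the total effect, 52.8%, covers
the true 60% within its Delta-method CI. The same workflow is available from
the shell: `mrmediate simulate`, `mrmediate instruments`, `mrmediate uvmr`,
`mrmediate reverse`, `mrmediate mediate` (see `mrmediate --help`), driven by
a YAML config naming the summary-statistic files.

## Layout

- `src/mrmediate/sumstats.py` — table/LD/blacklist I/O and validation
- `src/mrmediate/instruments.py` — significance, clumping, blacklist, F
- `src/mrmediate/harmonize.py` — allele alignment and palindrome policy
- `src/mrmediate/uvmr.py`, `sensitivity.py` — estimators and diagnostics
- `src/mrmediate/mvmr.py` — multivariable MR (IVW/Egger/median/lasso)
- `src/mrmediate/mediation.py` — two-step screen, Delta proportions
- `src/mrmediate/simulate.py` — synthetic GWAS generator with known truth
- `src/mrmediate/pipeline.py`, `cli.py` — orchestration and shell interface
- `docs/methods.md` — full statistical methods note
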