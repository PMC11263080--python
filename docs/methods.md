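# Methods

`mrmediate` implements a complete two-sample Mendelian randomization (MR)
mediation analysis operating purely on GWAS summary statistics: instrument
selection, allele harmonization, univariable causal estimation with a battery
of pleiotropy-robust estimators and diagnostics, multivariable MR, and
two-step mediation with Delta-method proportions. This note records the
statistical model, the defaults and why they were chosen, and the places
where the design was genuinely open.

## Model and assumptions

A genetic variant j is a valid instrument for exposure X on outcome Y when it
is (1) associated with X, (2) independent of confounders of X–Y, and (3)
affects Y only through X. Under these assumptions each variant yields a Wald
ratio θ_j = β_Yj/β_Xj estimating the causal effect, with first-order standard
error σ_j = se_Yj/|β_Xj| (uncertainty in β_Xj is ignored at first order,
adequate for instruments passing an F > 10 strength filter). For binary
traits all effects are on the log-odds scale and estimates are also reported
as odds ratios.

- **IVW** combines ratios with weights σ_j⁻², equivalently a weighted
  regression of β_Y on β_X through the origin with weights se_Y⁻². The
  default "multiplicative random-effects" mode inflates the fixed-effect SE
  by √max(1, Q/(k−1)); the truncation at 1 means heterogeneity can widen but
  never narrow the interval, making the test slightly conservative under the
  null. The exactly calibrated fixed-effect variant is available as
  `mode="fixed"` and is what the calibration checks exercise.
- **MR-Egger** adds an intercept to the weighted regression after orienting
  every pair so β_X > 0. The intercept estimates average directional
  pleiotropy; the slope is a pleiotropy-adjusted causal estimate under the
  InSIDE assumption. SEs carry the multiplicative overdispersion factor
  √max(1, RSS_w/(k−2)).
- **Weighted median**: ratios are ordered, weights standardized, and the
  estimate interpolates the weighted empirical quantile function at 0.5.
  It is consistent when valid instruments carry more than half the weight.
  Its SE comes from a seeded parametric bootstrap (default 1000 resamples of
  β_X and β_Y from their reported normal errors).
- **Cochran's Q / I²** measure ratio heterogeneity around the IVW estimate;
  with the weights above, Q computed on the ratio scale is algebraically the
  residual weighted sum of squares of the origin regression.
- **MR-PRESSO** compares the observed leave-one-out residual sum of squares
  against a parametric simulation of the no-pleiotropy null; per-variant
  outlier p-values are Bonferroni-scaled by k and only reported when the
  global test rejects. Empirical p-values use (1+#)/(n_sim+1) and therefore
  never reach zero; the smallest attainable p is 1/(n_sim+1) with the default
  n_sim = 1000. When outliers are found the analysis is restarted once
  without them, and a distortion p compares the resulting shift in the IVW
  estimate against random removals of the same number of variants.
- **Multivariable MR** regresses β_Y jointly on m exposures' β_X columns
  (weights se_Y⁻², no intercept), giving each exposure's *direct* effect.
  MVMR-Egger adds an intercept after orienting rows by the first exposure's
  sign. MVMR-median minimizes the weighted absolute residual through the
  origin, solved exactly as a linear program (HiGHS); its SE is a seeded
  parametric bootstrap. MVMR-Lasso gives every instrument a pleiotropy
  intercept α_j shrunk by an L1 penalty; the soft-threshold acts on the
  residual in units of each variant's standard error, so the tuning
  parameter λ reads as a z-score cutoff. λ is chosen by the heterogeneity
  stopping rule: scanning from the largest λ downward, the first
  (least-exclusionary) valid set whose heterogeneity falls below the χ²
  95th percentile is accepted, and the reported estimate is MV-IVW on that
  valid set.

## Instrument selection

Defaults follow standard two-sample MR practice: genome-wide significance
p < 5×10⁻⁸ (strict inequality), greedy LD clumping at r² ≥ 0.001 within a
10,000 kb window keeping the smallest-p variant per region (p ties broken
lexicographically by variant id, which makes clumping deterministic), a
user-supplied confounder blacklist, and removal of instruments with
F = (β/se)² ≤ 10. The filters run in the fixed order significance →
blacklist → clump → F, because removing blacklisted variants before clumping
can promote a different index SNP per region; permuting the order can change
the result, so the pipeline never does. Variants absent from the supplied LD
matrix are retained as independent with a warning — the reference panel used
for published clumping is not shipped. An F statistic of exactly the
threshold is excluded (the convention adopted where "greater than 10" and
"less than 10 excluded" leave the boundary unstated). The squared-t form of
F is the default because effect-allele frequency is missing from several
public GWAS exports; the R²-based form F = R²(n−2)/(1−R²) is available when
eaf and n are present.

## Harmonization

Outcome records are aligned to the exposure's effect allele: identical
orientation is kept, swapped alleles negate β_Y and complement eaf,
complementary-strand records are mapped through A↔T/C↔G before the same
logic. Palindromic (A/T, G/C) variants cannot be resolved from alleles
alone; the default policy infers strand from allele frequency and keeps the
variant only when both frequencies fall on the same side of 0.5 and are
informative (MAF < 0.42, the customary cutoff), otherwise it is dropped —
also whenever either frequency is missing. A `drop_all` policy is available
for strictness. Every shared variant appears exactly once in an audit log
(`kept`, `flipped`, `dropped_palindromic`, `dropped_incompatible`).

## Two-step mediation

For an exposure with a significant total effect c (univariable IVW), each
candidate mediator M passes four gates: (1) the exposure→mediator effect a
(univariable IVW) is significant; (2) no reverse signal: mediator→exposure
and outcome→mediator MR are both non-significant where instruments exist;
(3) the mediator's direct effect b on the outcome, from MV-IVW adjusting for
the exposure, is significant; (4) sign consistency, implemented as
sign(a·b) = sign(c) — the product form rather than requiring a and b to
share a sign, since a mediator that is suppressed (a < 0) yet protective
(b < 0) contributes a positive indirect effect, which is the case realized
by one of the published paths.

The indirect effect is a·b with Delta SE √(a²se_b² + b²se_a²); the
proportion mediated is a·b/c with ratio-Delta variance
se_ind²/c² + ind²se_c²/c⁴ and a symmetric 95% CI. All coefficient
covariances are set to zero. This is exact for a and b when the mediator
GWAS cohort overlaps neither the exposure nor the outcome GWAS (the design
emulated here: a 3,757-sample immune-phenotype cohort against biobank-scale
disease GWAS), and an approximation for cov(a·b, c), since a and c share the
exposure's instruments.

**Reverse-instrument disambiguation.** When a forward effect M→Y truly
exists, Y's genome-wide hit list inherits M's instruments and a naive Y→M
reverse MR rejects by construction. The reverse tests therefore drop any
shared variant that is not clearly more strongly associated with the
instrument trait: a variant is retained only when its association z-score in
the instrument trait exceeds its z-score in the target trait by at least 2.
The 2-SD buffer keeps sampling noise on genuinely downstream hits from
leaking instruments through; without it roughly half of simulated
true-mediation systems failed their own reverse gate, while with it a
constructed mediator that is in truth a consequence of the outcome is still
caught, because its shared hits are decisively stronger in the outcome.
This is a deliberately lighter mechanism than full directionality (Steiger)
filtering, which is out of scope.

## Multiple testing

The primary exposure screen uses the Bonferroni threshold α/n_exposures,
carried unrounded internally (0.05/14 = 0.00357…; reports that print three
decimals show the conventional rounded value). Exposures with
p < α/n are classified *significant*, p < α *suggestive*, otherwise *null*.
The mediator stage uses nominal α = 0.05 by default — matching how published
mediation screens of hundreds of weakly-powered candidate phenotypes
actually advance candidates — with a Bonferroni option in the configuration.

## Synthetic data generator

The generator works directly on the summary level; no individual genotypes
are simulated. True instrument effects γ_j ~ N(0, γ_sd²) are drawn once;
each GWAS observes its causal image with sampling error
se = (2·maf(1−maf)·N)⁻¹ᐟ², the standard error of a per-allele regression
coefficient for a standardized trait. N is an *effective* sample size: for a
case/control GWAS, N_eff = 4/(1/n_cases + 1/n_controls). Defaults emulate
the targeted study design — exposure N_eff 32,000 (≈8k cases vs 409k
controls), outcome N_eff 24,500 (≈6.3k cases vs 222k controls), mediator
N 3,757 (a dedicated immune-phenotype cohort). γ_sd = 0.1 gives instrument
F statistics in the tens-to-hundreds, matching the published minimum F of
27.3. Mediator-specific instruments use a larger effect scale
(δ_sd = 0.5): immune-cell phenotypes are strongly heritable with large
per-allele effects, which is how a 3,757-sample GWAS yields genome-wide
significant instruments at all.

Mediation systems follow X→M→Y with mediator effect a, direct mediator→
outcome effect b and direct exposure effect c′, so the total effect is
θ = c′ + a·b and the true proportion a·b/θ. The canonical test system uses
a = 0.2, b = 0.3, c′ = 0.04 (θ = 0.1, proportion 0.6). Pleiotropy is
configurable as balanced (mean-zero) or directional direct effects on a
chosen invalid fraction. LD is block-diagonal with configurable within-block
r²; block members sit 1 Mb apart (inside the clumping window), blocks and
singletons 20 Mb apart (outside it).

What the generator does *not* emulate: realistic allele-frequency spectra
and LD decay, population stratification, sample overlap between cohorts,
winner's curse in instrument discovery, and binary-trait non-collapsibility
(case/control traits are approximated by the same normal error model on the
log-odds scale). Passing tests therefore demonstrate the correctness and
calibration of the estimators and of the screening logic under the stated
error model, not robustness to those real-data complications.

## Numerical choices

- Normal (not t) reference distributions throughout, the summary-data MR
  convention; 95% intervals use Φ⁻¹(0.975).
- p-values of exactly 0 in input files are clamped to 1e-300; empirical
  p-values are floored at 1/(n_sim+1) by construction.
- Weighted median interpolation clamps to the extreme ratios when 0.5 falls
  outside the quantile anchors (k small with very unequal weights).
- MV regression refuses condition numbers above 1e8 (collinear exposures).
- The LAD regression in MVMR-median is solved as an exact LP with the HiGHS
  simplex, making it deterministic; the bootstrap is seeded.
- All randomness flows from integer seeds through `numpy.random.default_rng`;
  identical configuration and seed reproduce reports byte-for-byte.

## Problem sizes used in the checks

The statistical checks run at desk scale, chosen to keep Monte-Carlo error
well inside the asserted bands: 1000 replicates with k = 50 instruments for
null calibration and CI coverage, 500 replicates for the weighted-median
robustness comparison and for end-to-end mediation recovery (50 exposure +
50 mediator instruments per replicate), and 100 seeded replicates for
MR-PRESSO outlier power with n_sim = 500.

## Known limitations

- First-order Wald SEs understate uncertainty for weak instruments; the
  F filter is the guard.
- The zero-covariance Delta method ignores the shared instruments between a
  and c; simulated CI coverage of the mediation proportion (≈0.95) shows the
  approximation is mild under the emulated design.
- The reverse-gate z-buffer is a heuristic; a mediator whose reverse effect
  is weak relative to sampling noise can slip through, and ~5% of true
  mediators still fail the gate by chance at α = 0.05.
- MVMR conditional instrument-strength diagnostics are not implemented.
- Multi-allelic variants and indels are outside the data model; variants are
  joined across traits by identifier only, never by position.
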