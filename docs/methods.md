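# Methods

## Scientific setting

The package analyses effect modification between a polygenic score (PGS)
for smoking initiation and adverse early psychosocial factors (EPFs) on
lifetime ever smoking, in the design used with Health and Retirement
Study cohorts: older adults, two ancestry groups analysed separately
(the PGS is standardized within group), one interaction logistic model
per group × EPF, and the results laid out per the Knol–VanderWeele
recommendations for presenting interaction on both the multiplicative
and the additive scale.

## Variable derivation

* **Ever smoking (Y).** Endorsement of "smoked 100 or more cigarettes"
  at *any* survey wave gives Y = 1; Y = 0 requires at least one observed
  wave with no endorsement; Y is missing only when no wave was observed.
  No recency logic is applied.
* **High genetic risk (G).** The within-group 75th percentile of the
  observed PGS (linear-interpolation quantile) is the cut; G = 1 strictly
  above it. Strictness puts boundary ties in the larger "low-to-moderate"
  group, keeping the flagged fraction at or below 25% under ties (all-tied
  scores flag nobody). At least four observed scores are required.
* **Maternal warmth.** Three items: two on 1–4 scales, one (relationship
  quality) on 1–5. The 1–5 item is linearly rescaled to 1–4
  (`x' = 1 + 3(x−1)/4`) before averaging, because the composite is
  defined to have range 1–4, which is impossible with an unscaled 1–5
  item; rescaling can be disabled. The adverse flag is score strictly
  below the within-group 25th percentile, ties to the normal side.
* **Financial burden.** Adverse iff perceived childhood finances were
  "poor"; "pretty well off" and "about average" are normal. Unknown
  categories raise rather than coerce.
* **Childhood stress.** Adverse iff any of three events (police
  involvement, parental substance problems, physical abuse) is endorsed;
  the indicator is 0 when at least one flag is observed and none endorsed,
  missing only when all three are missing. An event count (0–3 over
  observed flags) is also returned.
* **Parental education.** Adverse iff the parent did *not* attain more
  than 8 years of education.
* **Complete cases.** Listwise deletion is per model (Y, G, the one EPF,
  covariates), not global — this is what makes each block's N differ,
  as in the published tables.

Both quantile cuts are computed within each ancestry group separately,
mirroring the within-group standardization of the scores; the pooled
alternative is available by flag (`by_group=False`).

## Estimation and interaction scales

The logistic model is fit by iteratively reweighted least squares from a
zero start, convergence at max |Δβ| < 1e-8 (≤ 100 iterations), and the
covariance taken as the inverse observed information at the optimum.
Rank-deficient designs raise an error naming the dependent columns
(pivoted QR); separation raises an explicit error (singular information,
diverging coefficients with |β| > 30, or non-convergence) instead of
being masked by ridge or Firth corrections — surfacing the diagnosis is
deliberate, since small published cells (one block has a 4/7 cell) are
exactly where silent regularization would mislead.

All block quantities come from the **single** joint fit: stratified ORs
are coefficient sums (G within E=1 is `exp(bG + bGxE)`), not refitted
per-stratum models. The published values obey the single-model
identities exactly (1.73/1.21 = 1.43, 1.73/1.10 = 1.57), which fixes
this choice. Consequences: `OR11 = OR10·OR01·ratio`,
`RERI = OR11 − OR10 − OR01 + 1`, and the stratum identities hold to
machine precision in every result, and are asserted in tests at 1e-12.

The RERI variance uses the delta method: gradient
`(OR11 − OR10, OR11 − OR01, OR11)` with respect to `(bG, bE, bGxE)`,
propagated through the 3×3 coefficient-covariance block; CI =
RERI ± 1.96·SE and a two-sided Wald p. The published source pairs a CI
touching 0 with p = 0.03 for its headline RERI, which no single
convention reproduces exactly; the two-sided Wald convention is used
throughout and the discrepancy accepted. A case-resampling percentile
bootstrap (seeded; resamples with an empty exposure cell redrawn up to
10 times) provides an independent interval: on well-behaved synthetic
data at n = 5,000 the delta endpoints sit within 15% relative of
1,000-replicate bootstrap endpoints (the delta interval is symmetric, so
skew accounts for most of the residual gap).

RERI is computed from odds ratios as rare-disease approximations of risk
ratios. Ever smoking is *common* (~55–60%) in the motivating cohorts,
so the additive-scale numbers should be read with that caveat; results
carry a metadata note saying so. Significance is α = 0.05 with no
multiple-testing correction, matching the original analysis across the
five EPFs × two groups. A sensitivity model with the continuous score
(`Y ~ pgs + E + pgs·E + covariates`) is provided.

Covariates default to age + gender + five ancestry principal components;
the set is configurable because the source is inconsistent about whether
age is included (its two table footnotes disagree).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes —
not the biology. The PGS is drawn directly as Normal(0, 1) (published
scores are already standardized within ancestry group; no genotypes, LD,
or score construction are simulated). One designated *driver* EPF
(default maternal warmth) enters the outcome model with `beta_E` and
`beta_GxE`; the other four EPFs are independent Bernoulli noise, since a
single pair of exposure coefficients only defines one interaction.
Defaults are the stated world of the motivating EA sample, fixed once:

| parameter | default | basis |
|---|---|---|
| n_participants | 6,969 | EA genotyped sample size |
| age mean (SD) | 74.3 (14.3) years | reported EA demographics |
| prop_female | 0.572 | reported EA demographics |
| beta_G, beta_E, beta_GxE | ln 1.10, ln 1.21, ln 1.30 | published EA maternal-warmth ORs |
| beta0 | 0.28 | calibrated once to ~55% ever-smoking prevalence |
| beta_age | ln(0.944)/10 per year | reported 5.6% lower odds per 10 years |
| prev_E per EPF | 0.27/0.09/0.25/0.17/0.11 | back-calculated from published cell totals (approximation, not ground truth) |
| missing rates per EPF | 0.20/0.014/0.11/0.12/0.07 | back-calculated from per-block N vs 6,969 |

Missingness is MCAR only (no mechanism is documented for the real data);
a record's raw fields for an EPF go missing together. Raw survey fields
are generated consistently with the latent binary exposures: categorical
EPFs and the smoking waves round-trip through harmonization *exactly*;
maternal warmth is generated as two separated item clusters, so the
quantile-based low-warmth flag agrees with the generating indicator
closely but not exactly (the cut is 25%, the generating prevalence 27%).
A green test on synthetic data therefore establishes correctness of the
derivation/estimation machinery and calibration of the intervals under
a correctly specified model — not robustness to informative missingness,
measurement error, or confounding structure in real survey data.

Determinism: one top-level seed; per-field substreams are spawned from
`numpy.random.SeedSequence(seed)` in a fixed order (age, gender, PCs,
PGS, exposures, outcome, raw fields, missingness), so identical
parameters and seed give byte-identical cohorts, results and reports.
The exact-count mode places `cases` smokers in each G×E cell and
shuffles record order with the seed; its cross-tab equals the input
counts with equality (property-tested over 100 random tables).

## Numerical and formatting conventions

* 95% intervals use z = Φ⁻¹(0.975) = 1.959964.
* Crude 2×2 ORs use the cross-product with a Woolf log-scale CI; zero
  cells raise unless the Haldane +0.5 correction is requested.
* Display rounding is decimal half-up: two decimals for ORs/RERI, whole
  percents (cases/total); the TSV output keeps full precision (`repr`)
  so displayed values can be backed out exactly. One published cell
  prints 55% where its own counts give 54.5% → 54; the stated rounding
  rule is followed.
* The published column header reads "N (cases/controls)" but the second
  printed number is demonstrably the cell total (totals sum to the block
  N); outputs label it cases/total with a note.

## Known limitations

* No survey weights (the original analysis deliberately omitted them),
  no imputation, no attributable proportion or synergy index, no Firth
  correction, no plotting (the additive-effects table is exported for
  replotting).
* Published *adjusted* estimates are not reproducible without the
  restricted data; exact checks therefore target the tables' internal
  arithmetic and crude-count reproductions, with simulation-based
  calibration covering the estimation machinery.
* The bootstrap refits the full model per resample; with very small
  cells it can legitimately fail after repeated redraws, and a cohort
  whose outcome is constant within a cell cannot be bootstrapped at all
  (the model is separated by construction).
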