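# Methods

This note documents the models, the synthetic-data generator, numerical
choices, and the places where the design was genuinely open.

## Prescreen hazard model

Time from birth to ROP treatment is modelled as a proportional-hazards
process `h(t|x) = exp(f(t) + xᵀβ)` over postnatal weeks `t ∈ [0, 20]`,
fitted by the piecewise-exponential device: follow-up is split into
intervals (default 1 week), each contributing a Poisson observation with a
log-exposure offset and the baseline evaluated at the interval midpoint.
Predictions are insensitive to the split width (a regression test compares
1-week against 0.5-week splits); midpoint evaluation biases only the
baseline shape at second order in the interval width.

* **Covariates.** GA in decimal weeks centered at 28.5; BW per 100 g
  centered at 1172 g; a male indicator (girl = reference); indicator coding
  for the PND category with `<14 d` as reference and **unknown kept as its
  own level** — exposure missingness is informative in registry practice
  and must never be imputed away in a safety tool.
* **Baseline.** Restricted cubic spline, default 4 knots at the 5/35/65/95
  percentiles of observed event times (explicit knots can be passed). The
  published model's exact basis is in unavailable supplementary material,
  so the spline family here is this package's documented choice; 4 knots
  is the usual default for hazards with a single broad peak.
* **Interactions.** Candidate blocks sex×PND and GA×PND; the AIC-minimal
  subset is kept. AIC = −2·loglik + 2·(number of parameters).
* **Risk.** `p = 1 − exp(−H(T))` with `H` computed by composite Simpson on
  a 0.1-week grid (relative error < 1e−6 against closed forms for constant
  and log-linear hazards; tested). Horizon fixed at `T = 20` weeks.
* **Censoring.** When a record has no explicit last-examination time, 20
  weeks is assumed. The source registry's per-infant censoring rule for
  non-treated infants is unstated; the fixed-horizon assumption is
  conservative for risk estimation and is flagged here deliberately.
* **Degenerate fits.** Separation (a covariate level with all or no
  events) or non-convergence triggers a warning and an L2-penalized
  Newton fallback with an unpenalized intercept; the fit is flagged
  `penalized_`. Rank-deficient designs raise immediately.

## Screen models

One maximum-likelihood logistic regression per postnatal week 6–14 with
predictors: prescreen risk log-odds, a detection indicator (first ROP
diagnosis at PNA ≤ w, closed at the examination week), weeks since first
detection (0 for undetected infants), and an AIC-selected
detection×log-odds interaction. Infants treated strictly before week w are
excluded from week-w fitting since their outcome is already realized. The
coding of the age-at-first-detection term in the published model is not
printed; `w − age_first_detection` with a separate main indicator is this
package's choice, making the undetected reference coding explicit.

## Cutoff calibration and the discharge policy

`cutoff(stratum, stage) = min{risk of treated infants scored at that
stratum × stage} − ε`, with ε = 1e−6 on the probability scale so that a
risk tie with a treated infant never discharges. GA strata are completed
weeks ≤24, 25, …, 30, ≥31; a stratum with no treated infants inherits the
pooled all-strata minimum (the published table's pooling rule for sparse
strata is unstated; inheriting the pooled minimum is the conservative
option). Decisions run sequentially — prescreen at day 14, then weekly —
and an infant is discharged at the first stage with `risk < cutoff`.
Training sensitivity is exactly 1 by construction; the property is
verified on 1000 random cohorts. Infants with detected ROP remain eligible
for discharge by default because the screen model conditions on detection;
`forbid_discharge_if_detected=True` switches to the stricter policy.

## Statistical primitives

* Crude odds ratios use the Woolf (log-scale Wald) interval, which
  reproduces the printed registry intervals from the count tables.
* Miettinen–Nurminen limits invert the score statistic with the N/(N−1)
  variance factor; the constrained MLE uses the closed-form cubic solution
  and the inversion bisects to 1e−8. Tests compare against an independent
  numerical-optimization oracle to 1e−6.
* Clopper–Pearson intervals come from Beta quantiles; for x = n the lower
  limit is `(α/2)^(1/n)`.
* The Youden search scores `score ≥ cutoff` as positive and breaks ties
  toward the smaller cutoff (earlier prognosis preferred).
* Hosmer–Lemeshow uses risk deciles and χ² with (groups − 2) df; tied
  prediction quantiles merge groups with a warning.
* The sign test is the exact two-sided binomial test on discordant pairs;
  zero discordance returns p = 1 with a warning.
* Two-sided tests at α = 0.05 throughout, no multiplicity adjustment.

## Tool comparison

Superiority is lexicographic: sensitivity first — a method that releases
any treated infant loses outright against a 100%-sensitive method
regardless of specificity — then, among 100%-sensitive methods, the exact
sign test on per-infant discharge indicators among never-treated infants.
The growth-rule comparator fires on GA, BW, window weight gains (days
10–19, 20–29, 30–39, boundary weights linearly interpolated; postnatal
day 0 = birth day) and hydrocephalus; **any missing datum forces
screening**, which makes the rule monotone (removing data can only switch
no-screen to screen; property-tested). Whether the published criteria fire
on "below" or "at-or-below" the gain threshold is not stated in this
package's sources: strict below is the shipped default and is
configurable. The threshold numbers ship as an editable rule-set config;
the WINROP algorithm is not reimplemented (unavailable), but externally
produced decision CSVs can be compared through the same harness.

## Synthetic cohort generator

The generator emulates the registry's marginal structure, with every
conditional model anchored at GA 28.5 weeks so that shifting the GA mix
(`ga_mean`) emulates a temporal shift without silently changing the
BW-for-GA or PND-for-GA relationships:

| quantity | model | default target |
|---|---|---|
| GA | truncated normal on [21.9, 39.4] wk | mean 28.5, SD 2.4 |
| sex | Bernoulli | 45.5% girls |
| BW | 1172 + 140·(GA−28.5) + N(0, 186²) g, clipped to [307, 3540] | mean 1172, SD 384 |
| PND days | lognormal, log-mean 1.642 − 0.42·(GA−28.5), log-SD 0.95, capped at 279 | 24.2% ≥14 d among known; GA contrast 26.2 vs 29.2 wk |
| unknown PND | independent mask | 14.4% |
| treatment time | inverse-cumulative-hazard sampling from the same spline family the estimator fits (knots 6, 10, 13, 16 wk; bump peaking near 13 wk) | 5.4% treated, median 12.6 wk |
| any ROP (non-treated) | logistic in GA and true PND ≥14 | 28.5% overall |
| onset time | lognormal, median 8.4 wk at GA 28.5, later for lower GA | median 8.4 wk |
| max stage | latent severity in GA and PND days with fixed thresholds | stage-vs-PND rank correlation ≈ 0.43 |
| daily weights | per-infant growth rate N(16, 4²) g/day (floor 2), measurement noise SD 8 g every 3 days through day 42; 10% of series missing | — |

The hazard's true covariate coefficients (GA −0.35/wk, BW −0.10/100 g,
male +0.25, PND ≥14 +0.90, unknown +0.30, male×≥14 −0.45, male×unknown
−0.05) encode the qualitative structure reported for the registry: strong
GA/BW gradients, higher treatment rates with long PND, and the sex×PND
interaction in which girls fare relatively worse in the long-PND group.
The free constants (baseline intercept and shape, PND location, ROP
intercept, stage thresholds) were calibrated numerically once against the
marginal targets above and then frozen.

What the generator does **not** emulate: center effects, multiple-birth
clustering, secular trends in neonatal care, BW standardization against a
national growth reference (records carry `bwsds` only if supplied), and
real examination schedules (decisions are made on a weekly grid). Passing
tests therefore demonstrate correctness of the machinery and of the
statistical properties under the stated generating model, not clinical
performance on registry data; registry-reported discrimination numbers are
deliberately not asserted anywhere.

## Problem sizes used by tests and the acceptance script

Unit tests run cohorts of 300–20 000 infants; parameter recovery uses
50 000 infants with the true knots supplied (a well-posed recovery, since
the generator samples from the fitted family) and requires every
coefficient within 3 standard errors of truth. The acceptance script uses
8000 development / 2000 validation infants and a 20 000-infant recovery
run — sizes at which Monte-Carlo noise on the reported percentages is a
fraction of a point, chosen to keep the full run in the minutes range on
one CPU.

## Known limitations

* Cutoff tables inherit the fragility of any minimum-based rule: one
  atypically low-risk treated infant in training collapses the cutoff for
  its stratum (visible in synthetic runs as reduced specificity at larger
  cohort sizes). The source tool shares this property by design — safety
  dominates.
* Wald/Woolf intervals and the AIC search are asymptotic; behaviour in
  strata with a handful of events relies on the penalized fallback.
* The CSV reader validates invariants row by row and drops violating rows
  with diagnostics rather than attempting repair; bulk registry cleaning
  is out of scope.
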