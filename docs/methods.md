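# Methods

## Grading model

Each of six serum liver chemistries is graded on an ordinal ladder
anchored at multiples of the limit of normal, in the CTCAE style:

| analyte | direction | cutoffs (grade 1, 2, 3, 4) | units |
|---|---|---|---|
| BIL | high is worse | 1.5, 2.25, 4.5, 15 | mg/dL |
| AST | high is worse | 35, 105, 175, 700 | IU/L |
| ALT | high is worse | 35, 105, 175, 700 | IU/L |
| ALKP | high is worse | 120, 300, 600, 2400 | IU/L |
| INR | high is worse | 1.2, 1.5, 2.5 | — |
| ALB | low is worse | 3.5, 3, 2 | g/dL |

Boundary semantics are codified from the clinical interval notation:
grade 0 is inclusive of its boundary (`value ≤ c1`, or `value ≥ c1` for
albumin) and each higher band is `c_k < value ≤ c_{k+1}`
(`c_{k+1} ≤ value < c_k` for albumin). Composite scores sum member
grades: ALL6 over all six (maximum 22; the modelled cohort range is
0–10), ALL4 over BIL/AST/ALT/ALKP, ALL3 over BIL/AST/ALT. When a member
grade is missing, the default `require_complete` policy declares the
composite missing; a `sum_available` policy (sum of present members with
a completeness flag) is available by configuration because how real
cohorts formed baseline composites for patients with missing components
is not derivable from the data contract. Units are validated, never
converted. The sensitivity transformation multiplies *every* cutoff of
every analyte by one factor in [0.7, 1.3]; monotonicity of the ladders
is preserved by construction.

Same-day repeat tests collapse to the single worst grade per patient ×
analyte × calendar day (events are defined per visit day). A month is
30.4375 days in all date conversions.

## Event derivation

The comparison point for the first post-treatment visit is the latest
pre-treatment test in the open-low window (−7 days, 0]; if none, a
one-month fallback window applies; if still none, the first visit
initializes the comparator without being event-eligible. Every later
visit is compared with the previous visit. Any grade increase is an
event with `delta = new − previous`; a delta of 1 is a *1-grade* event,
otherwise *>1-grade*. A single visit jumping several grades is one
event. Events of ≥ 2 chemistries on one patient-day are *synchronous*;
each such day also yields exactly one combined (composite) event whose
delta is, by default, the **sum** of the same-day member deltas — chosen
because synchronous 1-grade upgrades must be able to aggregate into a
>1-grade combined event for the combined counts to exceed the individual
>1-grade counts, as observed cohort summaries require. A max-delta
alternative is provided (`magnitude_rule="max"`).

Follow-up is censored per scope at the last visit carrying that scope's
test (composite scope: any member test), so censor dates differ across
chemistries within a patient; events on the censor-day visit count, with
censoring immediately after. Incidence rates are events per summed
person-month within a stratum; a zero person-month stratum is undefined
(NaN), not zero.

## Counting process and the extended Cox model

Each patient × scope becomes contiguous `(0,t1], (t1,t2], …, (tk,C]`
intervals on the calendar (total-time, Andersen–Gill) scale — required
because the time-dependent terms are linear in months since treatment
completion. Baseline covariates are time-fixed; covariate-by-time
products `x·g(t)` (default `g(t) = t`) are evaluated **exactly at each
event time** inside the estimator rather than by episode-splitting,
which avoids both approximation error and data inflation. Clinical
target volume and normal-liver volume enter per 100 mL; patients with a
missing model covariate are excluded complete-case with a logged count.

The partial likelihood uses the Efron tie correction by default (less
biased than Breslow under the moderate ties produced by day-granular
visits; Breslow is available and the two coincide on tie-free data).
Maximization is Newton–Raphson with step-halving; convergence is
`|ΔLL| < 1e-9` within 50 iterations. Covariates are centered internally
(a partial-likelihood invariant) for conditioning. A rank check at the
null rejects collinear designs naming the offending terms; coefficients
whose magnitude exceeds 10 on the covariate-standard-deviation scale are
reported as suspected monotone likelihood (non-convergence), never
silently clipped.

All reported confidence intervals and Wald tests use the cluster-robust
sandwich `I⁻¹(Σ_g U_g U_g')I⁻¹`, where `U_g` sums the per-interval score
residuals of one patient; with Efron ties the residuals use the
tied-set-weighted risk means so that the residuals sum exactly to the
score. The proportional-hazards diagnostic computes Schoenfeld
residuals (event covariate minus risk-set weighted mean, averaged over
Efron subsets at ties), scales them by `m·V` (m events, V the
model-based covariance), and regresses on a time transform — identity
by default, matching the extended model's linear-in-time products; log
and rank transforms are available. Per-term statistics are 1-df
chi-squares, the global test has p df. The two-stage procedure refits
with an added `x·t` product for every term with PH p < 0.05 **and**
robust Wald p < 0.05; `exp(β_main + β_td·t)` then reads off the hazard
ratio at any time.

## Synthetic cohorts

Both generator tiers share the intensity
`λ_i(t) = λ0 · exp(x_i'β + (x_{i,td}'β_td)·t)` and are fully
deterministic given the seed (independent substreams per stage).

Defaults emulate a hepatic-radiotherapy cohort: 133 patients; per-
chemistry baseline grades drawn from cohort marginals concentrated at
grades 0–1 and summed into the composite score; female 25.6%, portal-
vein/IVC thrombosis 75.2%, HBV 56.3%, HCV 30.1%; age quartile uniform
1–4; CTV log-normal (mean 298.5, SD 415.4 mL), normal-liver volume
log-normal (1365.2, 638.5 mL), mean liver dose normal (17.7, 4.8 Gy).
Effect defaults: β_score = ln 1.17 per score unit, female main effect 0,
female-by-time ln 1.04 per month. Baseline intensity λ0 = 0.1/month;
administrative censoring at 24 months with exponential dropout at
0.06/month (mean follow-up ≈ 12 person-months, matching the observed
person-month to patient ratio). Visit gaps are uniform(0.5, 2) months —
denser than routine surveillance because the observed event density
implies frequent lab testing.

The event tier draws recurrent events by Lewis–Shedler thinning with
envelope `λ0·exp(x'β + max(0, slope·C))`; events are conditionally
Poisson given covariates. The lab tier evolves a latent grade chain per
chemistry: at each visit the grade steps up with probability
`1 − exp(−λ_i(t)·gap)` (per-chemistry λ0 = 0.04/month), otherwise steps
down with recovery probability 0.3, producing the fluctuating character
of real series; observed values are drawn strictly inside the realized
grade's cutoff band, guaranteeing exact grade round-trip.

What the lab tier does **not** emulate: correlation between chemistries
beyond shared covariates, informative censoring or death, assay noise
that crosses band boundaries, and the grade ceiling means the derived
event intensity only approximates the generating Poisson intensity —
end-to-end estimates are therefore mildly attenuated relative to the
generating log-hazard ratios, and end-to-end recovery checks are
directional/qualitative while exact calibration (bias, coverage, type-I
error) is established on the event tier. Likewise, because observed
values are uniform within bands, rescaling cutoffs in the sensitivity
analysis injects measurement noise that attenuates (but does not flip)
true effects on synthetic data; real values concentrated away from
boundaries would move less.

## Calibration results computed by the suite

The acceptance tests simulate at the default study conditions: 200
cohorts of 400 patients (λ0 = 0.1/month, 24-month follow-up, score HR
1.17, female-by-time HR 1.04/month) for parameter recovery and 95% CI
coverage, and 500 null cohorts of 150 patients over 12 months for the
type-I error of the robust Wald and Schoenfeld PH tests; problem sizes
were chosen so each study completes on a single CPU while keeping
Monte-Carlo error well inside the asserted bands. Engine correctness is
pinned separately by closed-form partial-likelihood values, brute-force
optimizer and naive-enumeration oracles, finite-difference derivative
checks, and coefficient agreement with an independent counting-process
Cox implementation.

## Known limitations

- No gap-time, marginal (WLW) or conditional (PWP) formulations; no
  frailty terms; no stratified baseline hazards.
- No unit conversion; inputs must already be in scale units.
- No imputation or interpolation of missing labs; no downgrade
  ("recovery") events; no competing-risk modelling of death.
- The Schoenfeld per-term statistic is the classic scaled-residual
  regression; refitting-based variants can give slightly different
  per-term p-values (the global statistic coincides).
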