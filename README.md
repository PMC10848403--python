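# lfevents

Recurrent liver-function event analysis after hepatic radiotherapy.

Patients irradiated for hepatocellular carcinoma show fluctuating serum
liver chemistries (bilirubin, AST, ALT, alkaline phosphatase, INR,
albumin) over years of follow-up. `lfevents` turns those fluctuating
numeric series into *recurrent upgrade events* on a CTCAE-style grading
scale and estimates how baseline risk factors drive the event intensity,
allowing the hazard ratio itself to change over time.

The analysis chain:

1. **Grading** — each lab value maps to an ordinal grade by fixed cutoff
   ladders (e.g. bilirubin 1.5 / 2.25 / 4.5 / 15 mg/dL for grades 1–4;
   albumin graded downward from 3.5 g/dL). Grades sum into composite
   scores (ALL6 over all six chemistries; ALL4, ALL3 over subsets).
2. **Event derivation** — a visit whose grade exceeds the comparison
   point (a pre-treatment reference for the first visit, the previous
   visit thereafter) is an upgrade event; same-day events of several
   chemistries are *synchronous* and aggregate into one combined event.
   Follow-up is counted in person-months per chemistry, censored at the
   last visit carrying that test.
3. **Counting process** — each patient's follow-up becomes
   Andersen–Gill `(start, stop]` risk intervals split at event times.
4. **Extended Cox model** — the intensity is
   `λ_i(t) = λ0(t) · exp(xᵢ'β + (x_{i,td}'β_td)·t)`;
   the partial likelihood is maximized by Newton–Raphson (Efron ties),
   inference uses the cluster-robust sandwich
   `I⁻¹ (Σ_g U_g U_g') I⁻¹` over patients, and the proportional-hazards
   assumption is tested by regressing Grambsch–Therneau scaled Schoenfeld
   residuals on time. Terms that violate PH *and* are significant get a
   covariate-by-time product in a second-stage refit.
5. **Synthetic cohorts** — generators with known ground truth (event
   tier via Lewis–Shedler thinning; lab tier with full fluctuating
   trajectories) support calibration and end-to-end testing.

## Worked example

```python
import numpy as np
import lfevents as lf

spec = lf.CohortSpec(n_patients=300, seed=5, dropout_rate=0.0, max_months=24)
cov = lf.simulate_covariates(spec)
events, follow_up = lf.simulate_recurrent_events(spec, cov)
intervals = lf.build_intervals(events, follow_up, cov, scope="ALL6",
                               covariate_cols=["score", "female"])
res = lf.fit_cox(intervals, lf.CoxModelSpec(
    ("score", "female"), td_terms=(("female", "identity"),)))
print(res.summary().round(4).to_string())
```

prints

```
               coef      hr  hr_low  hr_high  robust_se  model_se       z       p
score        0.1498  1.1616  1.1262   1.1981     0.0158    0.0143  9.4846  0.0000
female      -0.1350  0.8737  0.6822   1.1190     0.1263    0.1218 -1.0694  0.2849
female:time  0.0402  1.0411  1.0248   1.0576     0.0080    0.0080  5.0177  0.0000
```

The cohort was generated with a hazard ratio of 1.17 per unit of
baseline composite score, no initial gender difference, and a female
hazard growing 4%/month: the fit recovers HR 1.16 per score unit, a null
initial female effect, and HR 1.041 per month for the female-by-time
product, with 95% intervals (from the cluster-robust standard errors)
covering the generating values.

The same analysis runs end-to-end from raw lab tables via
`lf.run_pipeline(lf.RunConfig(...))` or the CLI
(`lfevents simulate | grade | events | intervals | fit | report |
sensitivity`); the sensitivity driver repeats everything with all
grading cutoffs multiplied by 0.7–1.3 and under ALL4/ALL3 composite
substitution.

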