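# condgrowth

Conditional growth modelling of infant anthropometry with parent-reported
neurodevelopmental screening — a reusable, fully tested pipeline for the
kind of question large birth cohorts ask: *is slower physical growth in
the first year of life associated with developmental delay in term-born
infants, and is it the linear-growth or the weight-gain component that
matters?*

Length and weight trajectories are strongly autocorrelated, so raw
interval gains cannot separate "grew longer" from "gained weight".
Conditional growth modelling residualizes them apart: with sex-specific
LMS z-scores z(t) for length and weight at birth and 4, 7 and 10 months,

* **conditional length** at age t is the standardized OLS residual of the
  length z-score on *all earlier* length and weight z-scores — linear
  growth in the interval, net of history;
* **conditional relative weight** at age t is the standardized residual of
  the weight z-score on the *concurrent* length plus all earlier sizes —
  weight gain net of linear growth;
* birth length and weight z-scores (stratified by parity and completed
  gestational week) serve as the conditional variables at birth.

By construction these variables are mutually uncorrelated, so they enter
one multivariable model without collinearity. Delay is screened with the
ASQ-3 questionnaire (five domains × six items scored 10/5/0; a domain
cutoff is the reference-sample mean − 2 SD; delay = any domain at or
below its cutoff). Associations are estimated per 1 SD as adjusted
relative risks from sex-stratified quasi-Poisson (log-link, dispersion-
corrected) regressions with six fixed covariates (maternal age, smoking,
parental education, family income, home speech stimulation).

Because cohort data of this kind are access-restricted, the package ships
a seeded synthetic-cohort generator (`condgrowth.simulate`) whose defaults
mirror the marginals of a large Japanese term-birth cohort, with delay
generated log-linearly in the true conditional variables so the
quasi-Poisson estimand equals the configured relative risk exactly — the
whole pipeline is testable end to end, including parameter recovery.

## Worked example

Simulate 50,000 children with a true protective conditional-length effect
of RR 0.85 per SD, run the pipeline, and fit the boys' 6-month model:

```python
import numpy as np
from condgrowth import default_config, simulate_cohort
from condgrowth.conditional import ConditionalGrowthModel
from condgrowth.pipeline import apply_eligibility, build_analysis_table
from condgrowth.risk import DelayRiskModel, exposure_names

cfg = default_config(n_children=50_000, true_log_rr={"cLength4": np.log(0.85)})
cohort = simulate_cohort(cfg, seed=3)
eligible, flow = apply_eligibility(cohort.data)
analysis, cutoffs = build_analysis_table(eligible)

boys = analysis[analysis["sex"] == "boy"]
cg = ConditionalGrowthModel(boys, variant="birth4", sex="boy").fit()
merged = cg.conditionals.join(boys[[c for c in boys.columns
                                    if c not in cg.conditionals.columns]])
res = DelayRiskModel(merged, "delayed_6_total", exposure_names("birth4")).fit()
print(res.summary()[["term", "aRR", "ci_low", "ci_high"]].round(3))
```

Output (seed 3):

```
      term   aRR  ci_low  ci_high
 intercept 0.079   0.047    0.131
   length0 1.061   0.999    1.127
   weight0 0.956   0.900    1.015
  cLength4 0.861   0.818    0.905
 crWeight4 1.000   0.951    1.052
 ...
events/n: 1406 / 16739   dispersion: 0.917
```

The fitted aRR for conditional length at 4 months, 0.86 (0.82–0.91),
covers the configured truth of 0.85; the null exposures sit at 1. The
derived 6-month domain cutoffs on this cohort are ≈ 35.6–36.2 points.
`condgrowth.risk.run_model_grid` fits the full grid — two sexes × (the
6-month model plus three 12-month variants, which differ in which
checkups a child needs) × (total delay + five domains) — and
`condgrowth.pipeline.run_all` materializes every stage to CSV with a
manifest. A CLI wraps the same calls:

```bash
condgrowth run-all --seed 1 --n 20000 --outdir out/
```

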