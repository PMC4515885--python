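# misens

Multiple imputation for irregular longitudinal outcome data, with a
clinical-significance-anchored sensitivity analysis for missing-not-at-random
(MNAR) dropout.

## The problem

Effectiveness studies and quality-assurance programs in outpatient
psychotherapy monitor patients with a symptom questionnaire (a 0–180 total
score, higher = more dysfunction) at intake, after every 5th therapy session,
and once after the end of treatment. Therapy length varies freely, so every
subject has a different number of measurement occasions over a different time
span, and the end-of-treatment outcome is missing for many patients — most
often the ones who discontinued. Standard wide-format multiple imputation
assumes a common occasion grid; naive comparators are biased: complete-case
analysis (CC) discards exactly the unfavourable courses, and
last-observation-carried-forward (LOCF) freezes patients at their last
monitored state.

`misens` implements an imputation and audit workflow for this setting:

1. **Trajectory summarization** — each subject's irregular process history is
   compressed into OLS intercept and slope of score on session number
   (`y_ij = β₀ + β₁ s_ij + e_ij`, process measurements only) plus the values
   of the last two process measurements, for the outcome scale and four
   therapeutic-alliance subscales.
2. **Chained-equation multiple imputation** — normal linear regressions with
   full parameter uncertainty (posterior draws of coefficients and residual
   variance), a single-pass monotone path where the missingness pattern
   allows it, and collinearity control: predictors with variance inflation
   factor above 10 are dropped highest-p-value-first (threshold 5 as a
   fallback on non-convergence). Estimates from the m completed datasets are
   combined by Rubin's rules.
3. **MNAR corrections** — a pattern-mixture *delta adjustment*
   (`E(Y|X,M=1) = E(Y|X,M=0) + Δ`, shifting every imputed outcome by Δ) and a
   *selection-model* weighted draw: per missing value, 10 MAR imputations are
   sorted ascending into `v`, 10 sorted uniforms on (0, 0.2) are normalized
   into a weight vector `p`, and the definitive value is drawn from `v` with
   probabilities `p` — encoding "the higher the dysfunction, the higher the
   dropout probability".
4. **Sensitivity trials** — composition-preserving resampling of a classified
   reference dataset (b improved + c not-improved observed, d outcomes
   deleted; default 132/78/50 of n=260). Improvement means a pre–post drop of
   at least 14 points, the reliable-change margin. Four trials (MAR1, MAR2,
   MNAR1, MNAR2) delete outcomes under MAR and worst-case MNAR mechanisms;
   every replicate is analyzed with MI, CC and LOCF; estimators are judged by
   the percentage bias of the standardized mean gain
   `γ = (mean(pre) − mean(post)) / SD(pre)` against the pre-deletion truth,
   with |PB| ≤ 5% as the robustness criterion and percentile confidence
   intervals.
5. **Synthetic cohorts** — a seeded generator emulates the study conditions
   (linear latent trajectories with random intercept/slope, truncated-normal
   session counts, alliance ratings correlated with concurrent symptom level,
   standardized mean gain ≈ 1.08, improved fraction ≈ 132/210), so the whole
   pipeline is testable without any clinical data.

## Worked example

```python
from misens import (CohortConfig, generate_cohort, assemble_wide, classify_cases,
                    TrialConfig, ImputationSpec, run_trial, assess_robustness)

cohort = generate_cohort(CohortConfig(seed=7))          # n=260, calibrated defaults
reference = classify_cases(assemble_wide(cohort).cases)

config = TrialConfig(trial="MNAR1", reps=100,
                     imputation_spec=ImputationSpec(m=5), seed=1)
result = run_trial(reference, config)
print(f"true effect size gamma = {result.gamma:.3f}")
for name, s in result.estimators.items():
    print(f"{name:>5}: mean {s.mean:.3f}  bias {s.percentage_bias:+.1f}%  "
          f"95% CI ({s.ci[0]:.2f}, {s.ci[1]:.2f})")
verdict = assess_robustness(result)
print(f"robust: {verdict.robust}, recommended delta = {verdict.recommended_delta:.2f}")
```

prints

```
true effect size gamma = 0.919
   MI: mean 0.991  bias +7.8%  95% CI (0.88, 1.10)
   CC: mean 1.130  bias +22.9%  95% CI (1.01, 1.26)
 LOCF: mean 0.986  bias +7.3%  95% CI (0.87, 1.09)
robust: False, recommended delta = 7.22
```

Reading: in the worst-case trial (all 50 deleted outcomes belong to
not-improved patients) complete-case analysis overstates the effect by ~23%;
the MAR-model MI estimator by ~8%. Because that exceeds the 5% robustness
criterion, `assess_robustness` recommends a delta — the average amount by
which the deleted cases' pre–post difference was overestimated — which can be
fed back through `run_trial(..., estimators=("MI_delta",), delta=...)` or
`mnar_impute(...)` to produce MNAR-corrected estimates.

A YAML-driven pipeline (cohort → accounting table → features → imputation →
trials → reports, everything written to a run directory) is available as
`misens all --config run.yaml`; see `misens --help` for the individual
subcommands (`generate`, `impute`, `trial`, `report`).

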