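# surveyattrition

Tools for analyzing **dropout attrition** in item-level survey response
data — participants who start a questionnaire but stop answering before the
end.  Web-based surveys make dropout both common and measurable: each
subject leaves a row of answered / not-answered indicators over the ordered
items, and that row is enough to locate *where* a survey loses people,
*whether* the losses are statistically real, and *who* is being lost.  The
package is aimed at survey methodologists and health-services researchers
evaluating instruments (e.g. EHR-linked patient questionnaires), and at
anyone who needs attrition analyses to be reproducible rather than eyeballed.

The workflow has three stages, in order of increasing depth:

1. **Visualize** — per-item respondent/skip/dropout tables, bar charts, and
   survival-type step curves (which may *rise* where items can be skipped),
   plus a labeled heuristic segmentation into Eysenbach's curiosity plateau,
   attrition phase, and stable participation phase.
2. **Confirm** — for each pair of sequential items (q, q′), a
   random-intercept logistic model

   logit P(y_ik = 1 | u_i) = β₀ + β₁·1[k = 2] + u_i,  u_i ~ N(0, σ_u²),

   fitted by maximum likelihood with adaptive Gauss–Hermite quadrature,
   where y_i1, y_i2 indicate that subject *i* answered items q, q′ and the
   random intercept u_i absorbs within-subject dependence.  The hypothesis
   "response proportions are equal" is β₁ = 0; estimates are transformed to
   a difference in proportions p₁ − p₂ = expit(β₀) − expit(β₀+β₁) with a
   standard error from the multivariate delta method.
3. **Explain** — chi-square / Fisher contingency tests of answers and
   subject attributes against next-item dropout and of completion against
   downstream outcomes; and whole-survey comparisons treating the dropout
   point as a discrete event time with completers censored after the final
   item: Kaplan–Meier curves, the log-rank test, and Cox proportional-hazards
   regression (Efron tie handling, Newton–Raphson) with a
   screen-then-adjust convenience workflow.

A synthetic survey generator (`surveyattrition.simulate`) with known ground
truth — discrete boundary hazards, subject frailty on the continuation
logit, sporadic skips, group hazard ratios, covariate effects, and a
completion-linked outcome — backs every stage, so all of the above is
testable without access to any particular study's data.

## Worked example

```python
from surveyattrition import (preset, simulate_survey, summarize_attrition,
                             estimate_phases, sequential_attrition_scan)

rm, covs, truth = simulate_survey(preset("paper_like", seed=42))
at = summarize_attrition(rm)
phases = estimate_phases(at)
print(phases.curiosity_end, phases.attrition_end, round(phases.stable_rate, 1))
scan = sequential_attrition_scan(rm)
print(scan[["pair", "p1", "p2", "diff", "p_value", "significant"]].head(3))
```

prints

```
2 4 47.8
             pair      p1      p2    diff  p_value  significant
0  item1 to item2  1.0000  0.9666  0.0334   0.7506        False
1  item2 to item3  0.9853  0.8352  0.1501   0.0000         True
2  item3 to item4  0.9833  0.7202  0.2631   0.0000         True
```

Reading: the heuristic puts the curiosity plateau through item 2 and the
steep attrition phase through item 4, after which participation stabilizes
near 48% of starters.  The scan's first pair is *not* significant despite a
3-point drop — item 1 was answered by everyone, a separated fit that the
model reports with an honest, very wide interval — while the item-2→3 and
3→4 cliffs are confirmed (p₁, p₂ are subject-specific proportions at
random effect 0; `scale="population"` gives population-averaged ones).

The same pipeline is scriptable from a shell:

```bash
surveyattrition report --preset paper_like --seed 42 --out results/
```

writes the attrition table, phase estimates, Table-style scan CSV, log-rank
and Cox summaries, all figures, and a manifest with input checksums.  Each
`examples/*.py` script walks one capability with commentary.

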