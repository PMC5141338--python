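"""Stage 3b — whole-survey attrition as discrete survival.

Dropout time = first item after the last answered one; completers are
censored after the final item.  The log-rank test compares cohorts, and
the screen-then-adjust workflow checks whether a gender difference in
dropout survives adjustment for the recruitment phase.
"""

from surveyattrition import (
    build_survival_data,
    cox_fit,
    logrank_test,
    preset,
    screen_then_adjust,
    simulate_survey,
)

rm, covs, _ = simulate_survey(preset("paper_like", seed=42))
sd = build_survival_data(rm, covs)

lr = logrank_test(sd, "group")
print(f"log-rank across cohorts: chi2 = {lr.statistic:.2f}, df = {lr.df}, "
      f"p = {lr.p_value:.2e}")
print("observed vs expected dropouts per cohort:")
for g in lr.observed.index:
    print(f"  {g:12s} O = {lr.observed[g]:6.0f}  E = {lr.expected[g]:8.1f}")

fit = cox_fit(sd, ["group", "gender", "age"])
print("\nCox proportional hazards (Efron ties):")
print(fit.summary.round(4).to_string())
print("proportional-hazards check (p of covariate x log(t) interaction):",
      {k: round(v, 3) for k, v in fit.ph_check.items()})

res = screen_then_adjust(sd, "gender", ["recruitment_phase", "age"])
print("\nscreen-then-adjust for exposure 'gender':")
print(res.screening.to_string(index=False))
print("retained:", res.retained, "| labels:", res.labels)
g_term = [t for t in res.final.summary.index if t.startswith("gender")][0]
print(f"adjusted gender effect: HR = "
      f"{res.final.summary.loc[g_term, 'hazard_ratio']:.3f}, "
      f"p = {res.final.summary.loc[g_term, 'p_value']:.3f}")
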