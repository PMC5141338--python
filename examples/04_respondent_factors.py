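"""Stage 3a — factor identification with contingency tables.

Asks two questions of the synthetic cohort: (1) does a subject attribute
(here gender) predict answering the next item, and (2) is survey
completion associated with obtaining the screening test afterwards?
"""

from surveyattrition import (
    completer_outcome_test,
    preset,
    response_vs_next_dropout,
    simulate_survey,
)

rm, covs, _ = simulate_survey(preset("paper_like", seed=42))

gender = covs.aligned_to(rm)["gender"]
res = response_vs_next_dropout(rm, 3, gender, 4)
print("gender vs answering item 4 (among item-3 respondents):")
print(res.to_frame().round(2))
print(f"chi-square = {res.statistic:.2f}, df = {res.df}, "
      f"p = {res.p_value:.3f}  [{res.method}]")

out = completer_outcome_test(rm, covs, "screening_obtained")
print("\ncompletion vs screening obtained:")
print(out.to_frame().round(2))
print(f"chi-square = {out.statistic:.2f}, p = {out.p_value:.4f}")
print("completers obtain the screening more often — the completion-linked")
print("outcome the generator embeds (22.37% vs 17.42% by design).")
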