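"""Stage 1 — visualize: attrition bar charts, step curve, phase heuristic.

Writes the four figure families to ``example_output/`` together with
their coordinate CSVs, and prints the heuristic three-phase segmentation
(curiosity plateau / attrition phase / stable participation).
"""

from pathlib import Path

from surveyattrition import (
    estimate_phases,
    preset,
    simulate_survey,
    summarize_attrition,
)
from surveyattrition.viz import PlotSpec, render

out = Path("example_output")
out.mkdir(exist_ok=True)

rm, covs, _ = simulate_survey(preset("paper_like", seed=42))
at = summarize_attrition(rm)
phases = estimate_phases(at, threshold=0.05)

print(f"curiosity plateau ends after item {phases.curiosity_end}")
print(f"attrition phase ends after item   {phases.attrition_end}")
print(f"stable participation rate         {phases.stable_rate:.1f}% of starters")
print("(heuristic segmentation: incremental dropout > "
      f"{phases.threshold:.0%} per item)")

for kind in ("respondents_pct", "dropouts_count", "stacked_skips"):
    render(at, PlotSpec(kind, out / f"{kind}.png"))
render(at, PlotSpec("attrition_curve", out / "attrition_curve.png",
                    phases=phases))
groups = summarize_attrition(rm, by_group=covs.aligned_to(rm)["group"])
render(groups, PlotSpec("grouped", out / "grouped_dropouts.png"))
print(f"\nfigures and coordinate CSVs written to {out}/")
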