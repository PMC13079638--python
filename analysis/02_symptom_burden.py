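"""Score symptom prevalence, severity, and burden on the simulated cohort."""
from pathlib import Path

from ohsurvey import default_codebook, load_survey, summarize_symptoms
from ohsurvey.dataset import write_results

OUT = Path(__file__).resolve().parent.parent / "results"
codebook = default_codebook()
cohort = load_survey(OUT / "survey.csv", codebook)

summary = summarize_symptoms(cohort.symptoms, codebook)
write_results(
    {"symptom_items": summary.per_item, "symptom_systems": summary.per_system},
    OUT,
)

top = summary.per_item.sort_values("prevalence", ascending=False).head(5)
print("top symptoms by prevalence:")
for row in top.itertuples():
    print(f"  {row.item}: {100 * row.prevalence:.1f}% (severity {row.severity:.2f})")
systems = summary.per_system.sort_values("prevalence", ascending=False)
print("most affected system:",
      f"{systems.iloc[0]['system']} ({100 * systems.iloc[0]['prevalence']:.1f}%)")
print(f"mean total symptom burden: {summary.per_respondent.mean():.2f}")
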