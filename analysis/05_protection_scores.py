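"""Rank protective measures by composite protective effectiveness."""
from pathlib import Path

from ohsurvey import default_codebook, load_survey, rank_measures
from ohsurvey.dataset import write_results

OUT = Path(__file__).resolve().parent.parent / "results"
codebook = default_codebook()
cohort = load_survey(OUT / "survey.csv", codebook)

table, categories = rank_measures(cohort, codebook)
write_results(
    {"protection_scores": table, "protection_categories": categories}, OUT
)

print("top 5 protective measures (CPE = 0.4 IR + 0.6 MPE/3):")
for row in table.head(5).itertuples():
    print(f"  {row.rank}. {row.item} [{row.category}]: CPE {row.cpe:.2f} "
          f"(IR {row.ir_pct:.1f}%, MPE {row.mpe:.2f})")
print("category means:")
for row in categories.itertuples():
    print(f"  {row.category}: IR {100 * row.mean_ir:.1f}%, MPE {row.mean_mpe:.2f}")
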