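"""Rank hazard exposures by the weighted composite risk score."""
from pathlib import Path

from ohsurvey import default_codebook, load_survey, rank_risk_factors
from ohsurvey.dataset import write_results

OUT = Path(__file__).resolve().parent.parent / "results"
codebook = default_codebook()
cohort = load_survey(OUT / "survey.csv", codebook)

table = rank_risk_factors(cohort, codebook, alpha=0.05)
write_results(
    {"risk_scores": table.scores, "risk_system_pvalues": table.system_pvalues},
    OUT,
)

print("top 5 risk factors by composite score (50% ES, 30% BAPS, 20% EP):")
for row in table.scores.head(5).itertuples():
    print(f"  {row.rank}. {row.item} [{row.category}]: CRS {row.crs:.3f} "
          f"(EP {100 * row.ep:.1f}%, ES {row.es:.2f}, BAPS {row.baps})")
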