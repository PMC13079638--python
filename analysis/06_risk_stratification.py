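"""Stratify the cohort: Z-score system scores, elbow-select k, K-means."""
from pathlib import Path

import pandas as pd

from ohsurvey import (
    default_codebook,
    load_survey,
    system_scores,
    total_symptom_burden,
)
from ohsurvey.dataset import write_results
from ohsurvey.stratify import stratify

OUT = Path(__file__).resolve().parent.parent / "results"
codebook = default_codebook()
cohort = load_survey(OUT / "survey.csv", codebook)

scores = system_scores(cohort.symptoms, codebook)
tsb = total_symptom_burden(cohort.symptoms)
# k fixed at 3 after inspecting the WCSS curve (the curve is still reported)
result = stratify(scores, tsb, k=3, seed=42, restarts=10)

write_results(
    {
        "wcss_curve": pd.DataFrame(
            {"k": list(result.wcss_curve), "wcss": list(result.wcss_curve.values())}
        ),
        "cluster_profiles": result.profiles,
        "cluster_labels": pd.DataFrame(
            {"respondent_id": cohort.respondent_ids, "cluster": result.labels}
        ),
    },
    OUT,
)

print("WCSS curve:", {k: round(v, 1) for k, v in result.wcss_curve.items()})
print(f"k = {result.k} clusters (0 = highest burden):")
for row in result.profiles.itertuples():
    print(f"  cluster {row.cluster}: n={row.size} ({row.share_pct:.2f}%), "
          f"mean TSB {row.mean_tsb:.2f}")
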