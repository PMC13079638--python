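"""Scale reliability per physiological system and t-test power analysis."""
from pathlib import Path

from ohsurvey import default_codebook, load_survey, reliability_report
from ohsurvey.dataset import write_results
from ohsurvey.reliability import power_report

OUT = Path(__file__).resolve().parent.parent / "results"
codebook = default_codebook()
cohort = load_survey(OUT / "survey.csv", codebook)

report = reliability_report(cohort.symptoms, codebook)
power = power_report([(31, 31), (40, 22)], d=0.5, alpha=0.05, target_power=0.80)
write_results(
    {
        "reliability": report,
        "power": power.scenarios.assign(d=0.5,
                                        required_total_n=power.required_total_n),
    },
    OUT,
)

good = report[report["alpha"].astype(float) >= 0.7]
print(f"Cronbach's alpha >= 0.70 for {len(good)} of {len(report)} systems")
for row in report.itertuples():
    print(f"  {row.system}: alpha {row.alpha} [{row.ci_low}, {row.ci_high}] "
          f"({row.band})")
print("power to detect d=0.5 (two-sided, alpha 0.05):")
for row in power.scenarios.itertuples():
    print(f"  n1={row.n1}, n2={row.n2}: power {row.power:.3f}")
print(f"required total n for 80% power at d=0.5: {power.required_total_n}")
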