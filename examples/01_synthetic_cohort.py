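"""Generate a synthetic inpatient cohort and characterise it.

Draws 10,000 admissions with correlated log-normal VTE and bleeding risks,
calibrated physician prescribing, and rank-derived Padua/IMPROVE scores,
then prints the marginal risk statistics and the prescribing rate per
VTE-risk decile — the pattern of physicians responding modestly to VTE risk
and barely to bleeding risk.
"""

from vteppx import SynthConfig, generate_cohort, quantile_prescribing_report, summarize_cohort

cohort = generate_cohort(SynthConfig(n=10_000, seed=42))
s = summarize_cohort(cohort)

print(f"n = {s.n}")
print(f"VTE risk:      mean {100 * s.p_vte_mean:.2f}%, median {100 * s.p_vte_median:.2f}%, "
      f"range {100 * s.p_vte_min:.2f}-{100 * s.p_vte_max:.1f}%")
print(f"bleeding risk: mean {100 * s.p_bleed_mean:.2f}%, median {100 * s.p_bleed_median:.2f}%, "
      f"range {100 * s.p_bleed_min:.3f}-{100 * s.p_bleed_max:.1f}%")
print(f"observed prophylaxis: {100 * s.observed_prophylaxis:.1f}% of patients\n")

report = quantile_prescribing_report(cohort, n_quantiles=10)
print("prescribing rate by VTE-risk decile (should climb ~35+ points):")
for _, row in report[report.axis == "p_vte"].iterrows():
    print(f"  decile {row['quantile']:2d}: mean risk {100 * row.mean_risk:5.2f}%  "
          f"prescribed {100 * row.prescribed_frac:5.1f}%")
print("\nprescribing rate by bleeding-risk decile (should stay nearly flat):")
for _, row in report[report.axis == "p_bleed"].iterrows():
    print(f"  decile {row['quantile']:2d}: mean risk {100 * row.mean_risk:5.2f}%  "
          f"prescribed {100 * row.prescribed_frac:5.1f}%")
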