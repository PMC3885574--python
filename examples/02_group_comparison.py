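"""Five-group cohort: trend of thermogram metrics with disease burden.

Simulates the full five-group cervical-disease cohort, computes per-group
median metrics, difference curves against the control mean thermogram and
pairwise Mann-Whitney tests, and prints the key comparisons.
"""

import numpy as np

from thermopept import (
    THERMO_GROUPS,
    compute_metrics_table,
    default_cohort_specs,
    difference_vs_control,
    group_mean_sd,
    group_thermograms,
    pairwise_metric_tests,
    process_cohort,
    simulate_cohort,
)

specs = default_cohort_specs(n_per_group=10)
manifest, records = simulate_cohort(specs, seed=2)
finals = process_cohort(records)
metrics = compute_metrics_table(finals)

med = metrics.groupby("group").median(numeric_only=True).loc[list(THERMO_GROUPS)]
print("group medians (width °C, T_FM °C, peak ratio):")
print(med[["width", "t_fm", "ratio"]].round(2).to_string())
print()
print("width and T_FM rise while the peak-amplitude ratio falls from")
print("control to advanced carcinoma: the primary ~62 °C transition is")
print("progressively stabilised and its area moves to higher temperature.")

summaries = group_mean_sd(group_thermograms(finals))
for diff in difference_vs_control(summaries):
    if diff.group == "control":
        continue
    t_neg = diff.temperatures[np.argmin(diff.values)]
    t_pos = diff.temperatures[np.argmax(diff.values)]
    print(f"  {diff.group:>10}: difference curve trough {t_neg:.1f} °C, "
          f"peak {t_pos:.1f} °C")

print()
tests = pairwise_metric_tests(metrics)
for r in tests:
    if {r.group_a, r.group_b} == {"control", "StageII_IV"}:
        print(f"control vs StageII_IV, {r.metric:>9}: "
              f"U={r.u_statistic:5.1f}  p={r.p_value:.4f}  "
              f"[{r.significance_band}]")
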