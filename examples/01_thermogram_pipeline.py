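"""Simulate a small plasma cohort and walk one scan through preprocessing.

Builds a healthy-control DSC cohort, processes the raw scan pairs
(buffer-reference subtraction, protein normalisation, linear baseline
correction, truncation to 45-90 °C) and prints the eight shape metrics of
the first sample.
"""

from thermopept import (
    compute_metrics,
    default_cohort_specs,
    process_cohort,
    simulate_cohort,
)

specs = default_cohort_specs(n_per_group=4)[:1]  # control group only
manifest, records = simulate_cohort(specs, seed=1)
finals = process_cohort(records)

sample_id = manifest["sample_id"].iloc[0]
metrics = compute_metrics(finals[sample_id])

print(f"sample {sample_id} ({len(finals)} controls simulated)")
for name, value in metrics.as_dict().items():
    print(f"  {name:>9}: {value:8.4f}")
print()
print("area is the total denaturation enthalpy per gram of plasma protein")
print("(healthy plasma sits near 4.9 cal/g); t_max is the albumin-dominated")
print("peak (~62.2 °C) and t_fm the area centroid of the whole profile")
print("(~66.4 °C); ratio compares the 60-65 °C and 68-72 °C transition")
print("amplitudes (~2.2 in controls).")
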