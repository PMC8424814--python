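"""Univariate comparisons and the study's two sample-size calculators."""

from cpinet import (
    SampleSizeSpec,
    ann_sample_heuristic,
    compare_groups,
    consolidate_dataset,
    default_config,
    generate,
    paired_mean_change_n,
)

dataset = generate(default_config(seed=1))
records = consolidate_dataset(dataset.cpis, dataset.admissions)

table = compare_groups(records)
significant = table[table.display_p != ""]
print("variables separating accepted from rejected records (p < 0.10):")
print(significant[["accepted", "rejected", "display_p"]].to_string())

# Paired mean-change design: alpha 5% two-tailed, power 80%, sd of the
# paired LOSTA change 1.05 days, difference to detect 0.125 days (3 h).
design = dict(alpha=0.05, power=0.80, sd_change=1.05, effect=0.125)
n_z = paired_mean_change_n(SampleSizeSpec(**design, statistic="z"))
n_t = paired_mean_change_n(SampleSizeSpec(**design, statistic="t"))
print(f"\nconsolidated CPI needed: {n_z} (z approximation), {n_t} (t statistic)")

# Rule of thumb for exemplar networks: inputs x 10 x second-layer neurons.
print(f"network heuristic: 19 inputs -> {ann_sample_heuristic(19, 2)}, "
      f"54 inputs -> {ann_sample_heuristic(54, 2)}")
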