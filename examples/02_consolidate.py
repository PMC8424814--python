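"""Collapse per-CPI rows into accepted/rejected records per admission.

Each admission yields at most one "accepted" and one "rejected"
consolidated record carrying ten ordinal scores in [0, 1] (averages of
the per-CPI judgments, the rejection fraction, and study-period
provider rates) plus OR-aggregated recommendation-type flags.
"""

from cpinet import (
    Status,
    compute_provider_rates,
    consolidate_dataset,
    default_config,
    generate,
)

dataset = generate(default_config(seed=1))

rates = compute_provider_rates(dataset.cpis)
print("pharmacist success rates (accepted / made):")
for pid, rate in sorted(rates.pharmacist_success.items()):
    print(f"  {pid}: {100 * rate:.0f}%")

records = consolidate_dataset(dataset.cpis, dataset.admissions)
n_acc = sum(r.status is Status.ACCEPTED for r in records)
n_rej = sum(r.status is Status.REJECTED for r in records)
print(f"\n{len(dataset.cpis)} CPI -> {len(records)} consolidated records "
      f"({n_acc} accepted, {n_rej} rejected)")

example = next(r for r in records if r.status is Status.REJECTED)
print(f"\nexample rejected record {example.admission_id}: "
      f"{example.total_cpi} CPI in the admission")
for name, value in example.scores.as_dict().items():
    print(f"  {name:>22}: {value:.3f}")

# The rejection score is the fraction of the admission's CPI the
# physicians rejected; combined CP success and physician rejection
# average the involved providers' whole-study rates.
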