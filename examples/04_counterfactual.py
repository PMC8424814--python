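"""The reassignment analysis: what if physicians accepted 100 % of CPI?

The generator plants a known effect: admissions with at least one
rejected CPI stay delta_reject = 0.4 days longer after the index
intervention (the package default mirrors the scale of effect the
method is meant to detect).  The analysis edits every record as if all
CPI were accepted, re-predicts, and compares the paired scenarios.
"""

import dataclasses

from cpinet import (
    FULL_SCHEMA,
    ReassignmentPolicy,
    SplitSpec,
    consolidate_dataset,
    default_config,
    encode_features,
    fit,
    generate,
    run_counterfactual,
    split,
)

config = dataclasses.replace(default_config(seed=1), delta_reject=0.5)
dataset = generate(config)
records = consolidate_dataset(dataset.cpis, dataset.admissions)
train, test, _ = split(records, SplitSpec(seed=1))
losta = lambda r: r.admission.outcomes.losta
fm = encode_features(train, FULL_SCHEMA, include_status=True)
fm_test = encode_features(test, FULL_SCHEMA, include_status=True, scaling=fm.scaling)
model = fit(fm, [losta(r) for r in train], bandwidth_mode="per_feature",
            groups=[f"{r.patient_id}/{r.admission_id}" for r in train],
            val_features=fm_test, val_targets=[losta(r) for r in test])

for policy in (ReassignmentPolicy.default(), ReassignmentPolicy.extended()):
    result = run_counterfactual(model, records, policy, outcome="losta")
    print(f"policy = {policy.name}")
    print("  " + result.scenario_line())
    print(f"  mean difference, all records:       "
          f"{result.mean_difference:+.3f} days")
    print(f"  mean difference, affected admissions: "
          f"{result.mean_difference_affected:+.3f} days "
          f"(generator truth: +0.500)")

# The extended policy also resets the provider-history scores to their
# 100%-acceptance values (combined CP success 1, physician rejection 0).
# It differs from the default policy only when the fitted metric kept a
# positive relevance on those inputs; when relevance pruning attributes
# the whole rejection signal to the rejection score (as for this seed),
# the two policies coincide.  Kernel smoothing attenuates the recovered
# effect by roughly 20%; see docs/methods.md for the decomposition.
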