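"""Generate a study-scale synthetic dataset and summarize its marginals.

The generator emulates an eight-month acute-care hospital study: ~542
patients, ~574 admissions, ~1700 clinical pharmacy interventions (CPI),
three pharmacists with acceptance rates 57/95/86 % (84 % overall), and
right-skewed hospital stays.
"""

import numpy as np

from cpinet import default_config, generate, summarize

config = default_config(seed=1)
dataset = generate(config)

n_patients = len({a.patient_id for a in dataset.admissions})
acceptance = np.mean([c.accepted for c in dataset.cpis])
print(f"patients:   {n_patients}")
print(f"admissions: {len(dataset.admissions)}")
print(f"CPI:        {len(dataset.cpis)}  ({100 * acceptance:.0f}% accepted)")
print()
print(summarize(dataset).to_string())

# Continuous rows print as "median (min-max)" and booleans as
# "Yes: n (p%)", the same display convention as the study's descriptive
# tables, so the calibration can be checked by eye.
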