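"""Generate a small synthetic cohort and look at its structure.

Builds 300 participants with the default study conditions (1.5% LVH
prevalence target, right-skewed iLVM, LVH-shifted covariates), prints the
realized prevalence and stratum contrasts, and writes the cohort to disk as
columnar-text ECGs plus clinical/CMR CSV tables.
"""

import numpy as np

from ecglvh import SyntheticCohortConfig, generate_cohort, write_cohort

cohort = generate_cohort(SyntheticCohortConfig(n_participants=300, seed=1))

ilvm = np.array([p.cmr.ilvm for p in cohort])
lvh = np.array([p.cmr.lvh_label for p in cohort])
sbp = np.array([p.clinical.sbp_raw for p in cohort])

print(f"participants: {len(cohort)}")
print(f"LVH prevalence: {lvh.mean():.1%}  (target 1.5%)")
print(f"iLVM mean (SD): {ilvm.mean():.1f} ({ilvm.std():.1f}) g/m^2 "
      "- right-skewed, mirroring a population imaging cohort")
if lvh.any():
    print(f"systolic BP, LVH vs normal: {sbp[lvh].mean():.0f} vs "
          f"{sbp[~lvh].mean():.0f} mmHg - the hypertensive shift in the LVH stratum")

out = write_cohort(cohort[:10], "scratch/example_cohort")
print(f"first 10 participants written under {out} (ECG text files + CSV tables)")
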