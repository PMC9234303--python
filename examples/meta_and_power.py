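"""Pool the two cohorts' MR estimates and compute the diabetic-stratum power.

The study-level IVW log-ORs (UK Biobank 1.14, FinnGen 1.08; SEs back-derived
from their 95% CIs) are combined by fixed-effect inverse-variance
meta-analysis, and the power to detect OR 1.06 in the 26,100-person diabetic
subgroup is computed from the normal approximation for binary-outcome MR.
"""

import numpy as np

from gdf15mr import MREstimate, PowerInput, meta_fixed, mr_power_binary, se_from_ci
from gdf15mr.meta_power import forest_table

studies = [
    MREstimate("ivw_random", float(np.log(1.14)), se_from_ci(1.01, 1.29), 0.028, 4),
    MREstimate("ivw_random", float(np.log(1.08)), se_from_ci(1.02, 1.14), 0.012, 4),
]
meta = meta_fixed(studies)
print(forest_table(["UK Biobank", "FinnGen"], studies, meta)
      .to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\nPooled OR {meta.or_:.2f} ({meta.ci_low:.2f}, {meta.ci_high:.2f}), "
      f"p = {meta.pvalue:.4f}: one SD higher genetically predicted GDF-15 raises "
      "gallstone odds by ~9% across both cohorts.")

power = mr_power_binary(PowerInput(n=26_100, case_fraction=2_573 / 26_100,
                                   r2=0.084, or_alt=1.06))
print(f"\nPower to detect OR 1.06 among diabetics: {100 * power:.1f}% — far too "
      "low for the null diabetic-stratum result to be informative.")
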