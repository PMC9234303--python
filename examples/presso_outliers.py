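"""MR-PRESSO outlier detection on a clean set and a contaminated one.

First runs the global/outlier tests on the embedded UK Biobank instruments
(no outliers, matching the published analysis), then plants a strongly
pleiotropic instrument in a 10-SNP synthetic set and shows it being flagged
and removed, with the distortion test quantifying how much it had shifted
the pooled estimate.
"""

import numpy as np

from gdf15mr import harmonized_reference, presso
from gdf15mr.summary_data import HarmonizedInstrument

clean = presso(harmonized_reference("ukb"), n_sim=1000, seed=1)
print(f"UK Biobank instruments: global p = {clean.global_pvalue:.3f}, "
      f"outliers = {clean.outliers} -> corrected estimate identical to raw "
      f"(OR {clean.estimate_corrected.or_:.2f})")

rng = np.random.default_rng(5)
bx = rng.uniform(0.05, 0.25, 10)
sy = np.full(10, 0.02)
by = 0.1 * bx + sy * rng.standard_normal(10)
by[4] += 10 * sy[4]  # one instrument with a large direct outcome effect
ins = [HarmonizedInstrument(snp_id=f"snp{j:02d}", status="kept",
                            beta_exposure=float(bx[j]), se_exposure=0.005,
                            beta_outcome=float(by[j]), se_outcome=float(sy[j]),
                            ratio=float(by[j] / bx[j]), ratio_se=float(sy[j] / bx[j]))
       for j in range(10)]
res = presso(ins, n_sim=1000, seed=2)
print(f"\nContaminated set: global p = {res.global_pvalue:.3f}, "
      f"outliers = {res.outliers}")
print(f"raw OR {res.estimate_raw.or_:.3f} -> corrected OR "
      f"{res.estimate_corrected.or_:.3f} (true 1.105); "
      f"distortion p = {res.distortion_pvalue}")
print("The planted SNP is removed and the corrected estimate moves back "
      "toward the generating effect.")
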