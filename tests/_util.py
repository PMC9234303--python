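"""Shared helpers for building synthetic summary-level instrument sets."""

from __future__ import annotations

import numpy as np

from gdf15mr.summary_data import HarmonizedInstrument


def make_instruments(
    rng: np.random.Generator,
    n_snps: int = 10,
    theta: float = 0.1,
    sy: float | None = None,
    displace: int | None = None,
    displace_sds: float = 10.0,
) -> list[HarmonizedInstrument]:
    """Instrument sets drawn from the two-sample MR generative model.

    Exposure betas U(0.05, 0.25); outcome betas theta*bx + N(0, sy) with
    ``sy`` either fixed or U(0.01, 0.03) per SNP.  ``displace`` shifts one
    SNP's outcome beta by ``displace_sds``·sy to create a pleiotropic
    outlier.
    """
    bx = rng.uniform(0.05, 0.25, n_snps)
    se_y = np.full(n_snps, sy) if sy is not None else rng.uniform(0.01, 0.03, n_snps)
    by = theta * bx + se_y * rng.standard_normal(n_snps)
    if displace is not None:
        by[displace] += displace_sds * se_y[displace]
    return [
        HarmonizedInstrument(
            snp_id=f"s{j:02d}",
            status="kept",
            beta_exposure=float(bx[j]),
            se_exposure=0.005,
            beta_outcome=float(by[j]),
            se_outcome=float(se_y[j]),
            eaf_exposure=0.5,
            ratio=float(by[j] / bx[j]),
            ratio_se=float(se_y[j] / bx[j]),
        )
        for j in range(n_snps)
    ]
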