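#!/usr/bin/env python
"""Compare QC reproducibility across normalization states.

Produces the two RSD report tables — per-method median RSD / IQR /
fraction below 0.3, and all pairwise paired t-tests of per-feature RSD —
plus the PCA QC-dispersion ratio per method. Key expected findings: the
SVR-vs-specific-gravity comparison is an exact zero (QCs pass through SG
normalization unchanged), and paper-literal PQN shows an artificially low
RSD because it collapses QC values toward 1.
"""

import os

import pandas as pd

from urinorm import (
    compare_rsd_paired,
    compute_rsd,
    pca_qc_dispersion,
    read_peak_table,
    summarize_rsd,
)

RESULTS = "results"

STATES = {
    "raw": "scratch/data",
    "svr_only": "scratch/corrected",
    "creatinine": "scratch/normalized/creatinine",
    "specific_gravity": "scratch/normalized/specific_gravity",
    "pqn_paper": "scratch/normalized/pqn_paper",
    "pqn_classical": "scratch/normalized/pqn_classical",
}


def main():
    tables = {
        name: read_peak_table(os.path.join(d, "intensities.csv"), os.path.join(d, "samples.csv"))
        for name, d in STATES.items()
    }
    rsd = {name: compute_rsd(t, name) for name, t in tables.items()}

    rows = []
    for name, r in rsd.items():
        s = summarize_rsd(r)
        _, ratio = pca_qc_dispersion(tables[name])
        rows.append(
            {
                "method": name,
                "median_rsd": round(s.median, 4),
                "iqr_low": round(s.iqr[0], 4),
                "iqr_high": round(s.iqr[1], 4),
                "n_rsd_below_0.3": s.n_below,
                "n_total": s.n_total,
                "pct_below_0.3": round(100 * s.fraction_below, 1),
                "pca_dispersion_ratio": round(ratio, 4),
            }
        )
    summary = pd.DataFrame(rows)

    comps = []
    names = list(rsd)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            res = compare_rsd_paired(rsd[a], rsd[b])
            comps.append(
                {
                    "method_a": a,
                    "method_b": b,
                    "rsd_mean_difference": res.mean_difference,
                    "p_value": res.p_value,
                    "n_common": res.n_common,
                    "degenerate": res.degenerate,
                }
            )
    comps = pd.DataFrame(comps)

    os.makedirs(RESULTS, exist_ok=True)
    summary.to_csv(os.path.join(RESULTS, "04_rsd_summary.csv"), index=False)
    comps.to_csv(os.path.join(RESULTS, "04_rsd_comparisons.csv"), index=False)
    print(summary.to_string(index=False))
    print()
    print(comps.to_string(index=False))


if __name__ == "__main__":
    main()
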