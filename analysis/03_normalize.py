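#!/usr/bin/env python
"""Apply the four urinary concentration normalizations to the corrected table.

Creatinine (division by the designated creatinine feature), specific
gravity ((SGref-1)/(SG-1), QCs assigned the reference), paper-literal PQN
(per-feature midpoint quotient against the QC mean) and classical PQN
(per-sample median quotient). Normalized tables go to scratch/; the
per-sample scaling factors of the three sample-rescaling methods go to
results/.
"""

import os

import pandas as pd

from urinorm import (
    SgParams,
    default_sg_ref,
    filter_all_zero_qc_features,
    find_feature,
    normalize_creatinine,
    normalize_pqn_classical,
    normalize_pqn_paper,
    normalize_specific_gravity,
    read_peak_table,
    write_peak_table,
)
from urinorm.synthetic import CREATININE_MZ, CREATININE_RT

SCRATCH_IN = "scratch/corrected"
SCRATCH_OUT = "scratch/normalized"
RESULTS = "results"


def main():
    corrected = read_peak_table(
        os.path.join(SCRATCH_IN, "intensities.csv"),
        os.path.join(SCRATCH_IN, "samples.csv"),
    )
    creatinine_id = find_feature(corrected, CREATININE_MZ, CREATININE_RT)
    sg_ref = default_sg_ref(corrected)
    pqn_input, dropped = filter_all_zero_qc_features(corrected)
    print(f"creatinine feature: {creatinine_id}; SGref = {sg_ref:.4f}; "
          f"{len(dropped)} all-zero-QC features dropped before PQN")

    results = {
        "creatinine": normalize_creatinine(corrected, creatinine_id),
        "specific_gravity": normalize_specific_gravity(corrected, SgParams(sg_ref=sg_ref)),
        "pqn_paper": normalize_pqn_paper(pqn_input),
        "pqn_classical": normalize_pqn_classical(pqn_input),
    }

    factors = {}
    for name, res in results.items():
        write_peak_table(res.table, os.path.join(SCRATCH_OUT, name))
        if res.per_sample_factor is not None:
            factors[name] = res.per_sample_factor
        print(f"{name}: {res.table.n_features} features normalized")

    os.makedirs(RESULTS, exist_ok=True)
    pd.DataFrame(factors).rename_axis("sample_id").to_csv(
        os.path.join(RESULTS, "03_sample_factors.csv")
    )
    print("per-sample factors written for:", ", ".join(factors))


if __name__ == "__main__":
    main()
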