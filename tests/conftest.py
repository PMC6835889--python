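import numpy as np
import pandas as pd
import pytest

from urinorm import PeakTable, SyntheticConfig, generate


def make_table(intensities, sample_types, feature_ids=None, mz=None, rt=None, **sample_cols):
    """Build a small PeakTable from a matrix and a list of sample types.

    Study samples are auto-assigned alternating pre/post phases and distinct
    subjects unless ``subject_id``/``phase`` columns are passed explicitly.
    """
    x = np.asarray(intensities, dtype=float)
    n_feat, n_samp = x.shape
    if feature_ids is None:
        feature_ids = [f"F{i + 1}" for i in range(n_feat)]
    features = pd.DataFrame(
        {
            "mz": mz if mz is not None else np.linspace(100, 900, n_feat),
            "rt": rt if rt is not None else np.linspace(60, 600, n_feat),
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )
    rows = []
    n_study = 0
    for j, st in enumerate(sample_types):
        row = {"sample_id": f"{st}{j + 1}", "sample_type": st, "injection_order": j + 1}
        if st == "study":
            if "subject_id" in sample_cols:
                row["subject_id"] = sample_cols["subject_id"][j]
            else:
                row["subject_id"] = f"u{n_study // 2 + 1}"
            if "phase" in sample_cols:
                row["phase"] = sample_cols["phase"][j]
            else:
                row["phase"] = "pre" if n_study % 2 == 0 else "post"
            n_study += 1
        for col in ("specific_gravity", "creatinine_pa"):
            if col in sample_cols:
                row[col] = sample_cols[col][j]
        rows.append(row)
    samples = pd.DataFrame(rows).set_index("sample_id")
    return PeakTable(
        intensities=pd.DataFrame(x, index=features.index, columns=samples.index),
        features=features,
        samples=samples,
    )


@pytest.fixture(scope="session")
def default_run():
    """One seeded synthetic run at realistic scale (shared, treat as read-only)."""
    return generate(SyntheticConfig(n_subjects=45, n_features=400, seed=11))


@pytest.fixture(scope="session")
def clean_run():
    """Noise-free, drift-free, zero-free run for exact recovery checks."""
    cfg = SyntheticConfig(
        n_subjects=45, n_features=300, seed=5,
        noise_cv=0.0, drift_amplitude=0.0, zero_rate=0.0,
    )
    return generate(cfg)
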