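"""Peak-table data model, CSV I/O, and feature filtering/lookup rules.

A peak table is the standard exchange object of untargeted LC-MS
metabolomics: a features-by-samples matrix of integrated peak areas,
where each feature is a unique (m/z, retention-time) pair, together
with per-sample run metadata (sample type, injection order, paired
subject/phase design, specific gravity, creatinine peak area).

Zeros are meaningful: a stored 0 means "peak not detected", never
"missing value". All filtering rules below are phrased on literal zeros.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FeatureNotFoundError, SchemaError, ValidationError

SAMPLE_TYPES = ("QC", "study", "blank")
PHASES = ("pre", "post")

#: columns of the sample-metadata table that may be absent
OPTIONAL_SAMPLE_COLUMNS = ("subject_id", "phase", "specific_gravity", "creatinine_pa")
REQUIRED_SAMPLE_COLUMNS = ("sample_type", "injection_order")

INTENSITY_FILENAME = "intensities.csv"
SAMPLE_META_FILENAME = "samples.csv"


@dataclass
class PeakTable:
    """Feature-by-sample peak-area matrix plus feature and sample metadata.

    Attributes
    ----------
    intensities : pd.DataFrame
        Non-negative peak areas, index = feature ids, columns = sample ids.
    features : pd.DataFrame
        Index = feature ids (same order as ``intensities``), columns
        ``mz`` (Thomson, > 0) and ``rt`` (seconds, >= 0).
    samples : pd.DataFrame
        Index = sample ids (same order as ``intensities`` columns), columns
        ``sample_type`` ({QC, study, blank}), ``injection_order`` (unique,
        1-based), and optionally ``subject_id``, ``phase`` ({pre, post}),
        ``specific_gravity``, ``creatinine_pa``.
    """

    intensities: pd.DataFrame
    features: pd.DataFrame
    samples: pd.DataFrame
    validate_on_init: bool = field(default=True, repr=False)

    def __post_init__(self):
        for col in OPTIONAL_SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                self.samples[col] = np.nan
        if self.validate_on_init:
            self.validate()

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self) -> None:
        if self.intensities.shape != (len(self.features), len(self.samples)):
            raise ValidationError(
                f"intensity matrix shape {self.intensities.shape} does not match "
                f"{len(self.features)} features x {len(self.samples)} samples"
            )
        if not self.intensities.index.equals(self.features.index):
            raise ValidationError("intensity row index does not match feature ids")
        if not self.intensities.columns.equals(self.samples.index):
            raise ValidationError("intensity column index does not match sample ids")
        if self.features.index.has_duplicates:
            dupes = self.features.index[self.features.index.duplicated()].tolist()
            raise ValidationError(f"duplicate feature ids: {dupes[:5]}")
        if self.samples.index.has_duplicates:
            dupes = self.samples.index[self.samples.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes[:5]}")

        x = self.intensities.to_numpy()
        if not np.issubdtype(x.dtype, np.number):
            raise ValidationError("intensity matrix is not numeric")
        if not np.isfinite(x).all():
            raise ValidationError("intensity matrix contains non-finite values")
        if (x < 0).any():
            i, j = np.argwhere(x < 0)[0]
            raise ValidationError(
                f"negative intensity for feature {self.intensities.index[i]!r} "
                f"in sample {self.intensities.columns[j]!r}"
            )

        if (self.features["mz"] <= 0).any():
            raise ValidationError("all m/z values must be > 0")
        if (self.features["rt"] < 0).any():
            raise ValidationError("retention times must be >= 0")

        bad_types = set(self.samples["sample_type"]) - set(SAMPLE_TYPES)
        if bad_types:
            raise ValidationError(f"unknown sample types: {sorted(bad_types)}")
        order = self.samples["injection_order"]
        if order.isna().any() or (order < 1).any() or (order != order.astype(int)).any():
            raise ValidationError("injection_order must be positive integers")
        if order.duplicated().any():
            raise ValidationError("injection_order values must be unique across the run")

        study = self.samples[self.samples["sample_type"] == "study"]
        if study["subject_id"].isna().any() or study["phase"].isna().any():
            missing = study.index[study["subject_id"].isna() | study["phase"].isna()]
            raise ValidationError(
                f"study samples missing subject_id/phase: {list(missing[:5])}"
            )
        bad_phase = set(study["phase"].dropna()) - set(PHASES)
        if bad_phase:
            raise ValidationError(f"unknown phases: {sorted(bad_phase)}")
        pairs = study[["subject_id", "phase"]].apply(tuple, axis=1)
        if pairs.duplicated().any():
            raise ValidationError("each (subject_id, phase) pair may occur at most once")

        sg = self.samples["specific_gravity"].dropna()
        if ((sg <= 1.000) | (sg >= 1.100)).any():
            raise ValidationError("specific gravity must lie in (1.000, 1.100)")

    # ------------------------------------------------------------------
    # convenience accessors
    # ------------------------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def sample_ids(self, sample_type: str | None = None) -> list[str]:
        if sample_type is None:
            return list(self.samples.index)
        return list(self.samples.index[self.samples["sample_type"] == sample_type])

    @property
    def qc_ids(self) -> list[str]:
        return self.sample_ids("QC")

    @property
    def study_ids(self) -> list[str]:
        return self.sample_ids("study")

    def qc_matrix(self) -> pd.DataFrame:
        """Peak areas restricted to QC samples, in injection order."""
        qcs = self.samples[self.samples["sample_type"] == "QC"]
        qcs = qcs.sort_values("injection_order")
        return self.intensities[qcs.index]

    def subset_features(self, feature_ids) -> "PeakTable":
        """New table restricted to ``feature_ids`` (original order kept)."""
        keep = self.features.index.isin(set(feature_ids))
        return PeakTable(
            intensities=self.intensities.loc[keep].copy(),
            features=self.features.loc[keep].copy(),
            samples=self.samples.copy(),
        )

    def with_intensities(self, values: np.ndarray | pd.DataFrame) -> "PeakTable":
        """New table with the same metadata and replaced intensity values."""
        mat = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=self.intensities.index,
            columns=self.intensities.columns,
        )
        return PeakTable(intensities=mat, features=self.features.copy(), samples=self.samples.copy())

    def copy(self) -> "PeakTable":
        return PeakTable(
            intensities=self.intensities.copy(),
            features=self.features.copy(),
            samples=self.samples.copy(),
            validate_on_init=False,
        )


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def read_peak_table(intensity_path: str, sample_meta_path: str) -> PeakTable:
    """Read a peak table from its intensity and sample-metadata CSV files.

    The intensity file holds columns ``feature_id, mz, rt`` followed by one
    column per sample; the metadata file holds one row per sample. Sample ids
    must agree exactly between the two files.
    """
    for path in (intensity_path, sample_meta_path):
        if not os.path.exists(path):
            raise SchemaError(f"no such file: {path}")

    raw = pd.read_csv(intensity_path, dtype={"feature_id": str}, float_precision="round_trip")
    for col in ("feature_id", "mz", "rt"):
        if col not in raw.columns:
            raise SchemaError(f"intensity file lacks required column {col!r}")
    meta = pd.read_csv(
        sample_meta_path, dtype={"sample_id": str, "subject_id": str},
        float_precision="round_trip",
    )
    if "sample_id" not in meta.columns:
        raise SchemaError("sample metadata file lacks required column 'sample_id'")
    for col in REQUIRED_SAMPLE_COLUMNS:
        if col not in meta.columns:
            raise SchemaError(f"sample metadata file lacks required column {col!r}")
    meta = meta.set_index("sample_id")

    header_ids = [c for c in raw.columns if c not in ("feature_id", "mz", "rt")]
    missing = [sid for sid in meta.index if sid not in header_ids]
    extra = [sid for sid in header_ids if sid not in meta.index]
    if missing:
        raise SchemaError(f"sample id(s) {missing} in metadata but absent from intensity header")
    if extra:
        raise SchemaError(f"sample id(s) {extra} in intensity header but absent from metadata")

    block = raw[list(meta.index)]
    numeric = block.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~block.isna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise SchemaError(
            f"non-numeric intensity {block.iat[i, j]!r} at row {i + 2} "
            f"(feature {raw['feature_id'].iat[i]!r}), column {block.columns[j]!r}"
        )
    if numeric.isna().to_numpy().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise SchemaError(
            f"empty intensity cell for feature {raw['feature_id'].iat[i]!r}, "
            f"sample {numeric.columns[j]!r}"
        )

    intensities = numeric.astype(float)
    intensities.index = pd.Index(raw["feature_id"], name="feature_id")
    intensities.columns = meta.index
    features = raw[["mz", "rt"]].copy()
    features.index = intensities.index
    return PeakTable(intensities=intensities, features=features, samples=meta)


def write_peak_table(table: PeakTable, out_dir: str) -> tuple[str, str]:
    """Write a peak table to ``out_dir`` as two CSV files.

    Returns the (intensity_path, sample_meta_path) pair. The files round-trip
    through :func:`read_peak_table` losslessly; optional metadata columns with
    no values at all are omitted from the output.
    """
    if table.n_features == 0:
        raise ValidationError("refusing to write a peak table with no features")
    os.makedirs(out_dir, exist_ok=True)
    if not os.access(out_dir, os.W_OK):
        raise OSError(f"output directory not writable: {out_dir}")

    intensity_path = os.path.join(out_dir, INTENSITY_FILENAME)
    meta_path = os.path.join(out_dir, SAMPLE_META_FILENAME)

    meta_block = pd.DataFrame(
        {
            "feature_id": table.features.index.to_numpy(),
            "mz": table.features["mz"].to_numpy(),
            "rt": table.features["rt"].to_numpy(),
        }
    )
    out = pd.concat([meta_block, table.intensities.reset_index(drop=True)], axis=1)
    out.to_csv(intensity_path, index=False)

    meta = table.samples.copy()
    meta.insert(0, "sample_id", meta.index)
    drop = [c for c in OPTIONAL_SAMPLE_COLUMNS if meta[c].isna().all()]
    meta = meta.drop(columns=drop)
    meta.to_csv(meta_path, index=False)
    return intensity_path, meta_path


# ----------------------------------------------------------------------
# filtering and lookup
# ----------------------------------------------------------------------

def filter_qc_zero_features(
    table: PeakTable, min_zero_qc: int = 3
) -> tuple[PeakTable, list[str]]:
    """Drop features undetected (peak area 0) in at least ``min_zero_qc`` QCs.

    This is the standard pre-processing step that removes analytically
    unreliable features before drift correction. Returns the filtered table
    and the list of removed feature ids; retained intensities are untouched
    and sample order is preserved.
    """
    if min_zero_qc < 1:
        raise ValidationError("min_zero_qc must be >= 1")
    qc = table.qc_matrix()
    if qc.shape[1] < min_zero_qc:
        raise ValidationError(
            f"table has {qc.shape[1]} QC samples, fewer than min_zero_qc={min_zero_qc}"
        )
    n_zero = (qc.to_numpy() == 0).sum(axis=1)
    removed = list(table.features.index[n_zero >= min_zero_qc])
    if len(removed) == table.n_features:
        raise ValidationError("QC-zero filter would remove every feature")
    kept = table.features.index[n_zero < min_zero_qc]
    return table.subset_features(kept), removed


def filter_all_zero_qc_features(table: PeakTable) -> tuple[PeakTable, list[str]]:
    """Drop features whose peak area is 0 in *every* QC sample.

    Required before QC-referenced quotient normalization, where a feature
    with an all-zero QC reference has no defined quotient.
    """
    n_qc = len(table.qc_ids)
    if n_qc < 1:
        raise ValidationError("table has no QC samples")
    return filter_qc_zero_features(table, min_zero_qc=n_qc)


def find_feature(
    table: PeakTable,
    mz: float,
    rt: float,
    mz_tol_ppm: float = 10.0,
    rt_tol_s: float = 15.0,
) -> str:
    """Locate a feature by (m/z, retention time) within tolerance windows.

    Among features within ``mz_tol_ppm`` parts-per-million in m/z and
    ``rt_tol_s`` seconds in retention time, returns the one with the smallest
    ppm deviation, breaking residual ties by the smallest rt deviation.
    """
    if mz_tol_ppm <= 0 or rt_tol_s <= 0:
        raise ValidationError("tolerances must be positive")
    ppm_dev = np.abs(table.features["mz"].to_numpy() - mz) / table.features["mz"].to_numpy() * 1e6
    rt_dev = np.abs(table.features["rt"].to_numpy() - rt)
    in_window = (ppm_dev <= mz_tol_ppm) & (rt_dev <= rt_tol_s)
    if not in_window.any():
        closest = int(np.argmin(ppm_dev + rt_dev / 1e6))
        fid = table.features.index[closest]
        raise FeatureNotFoundError(
            f"no feature within {mz_tol_ppm} ppm / {rt_tol_s} s of "
            f"(m/z {mz}, rt {rt}); closest is {fid!r} at "
            f"(m/z {table.features['mz'].iloc[closest]}, rt {table.features['rt'].iloc[closest]})",
            closest=fid,
        )
    candidates = np.flatnonzero(in_window)
    best = candidates[np.lexsort((rt_dev[candidates], ppm_dev[candidates]))[0]]
    return table.features.index[best]
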