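"""Reproducibility metrics based on pooled QC samples.

Pooled QCs are identical in composition, so any spread in a feature's QC
peak areas is analytical error. The per-feature relative standard deviation
(RSD = sd / mean over QC injections) is the field's standard reproducibility
score, with RSD < 0.3 the conventional acceptability criterion. The module
also provides the paired t-test used to compare RSD distributions between
normalization states, and a quantitative PCA score for how tightly the QCs
cluster relative to the study samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .errors import ValidationError
from .peaktable import PeakTable

RSD_THRESHOLD = 0.3


@dataclass
class RsdTable:
    """Per-feature QC relative standard deviations for one normalization state."""

    rsd: pd.Series              # defined features only
    excluded: pd.Series         # feature id -> reason, for undefined features
    label: str = ""


@dataclass
class RsdSummary:
    median: float
    iqr: tuple[float, float]    # (25th, 75th percentile)
    n_below: int
    n_total: int
    fraction_below: float
    threshold: float


@dataclass
class RsdComparison:
    mean_difference: float      # mean of (a - b) over common features
    t_statistic: float
    p_value: float
    n_common: int
    degenerate: bool            # True when all differences are identical


def compute_rsd(table: PeakTable, label: str = "") -> RsdTable:
    """Per-feature QC RSD: sample sd (n-1 denominator) over QC areas / mean.

    Features whose QC mean is 0 have no defined RSD and are recorded as
    excluded rather than assigned an infinite value.
    """
    qc = table.qc_matrix().to_numpy()
    if qc.shape[1] < 3:
        raise ValidationError(f"RSD needs >= 3 QC samples, found {qc.shape[1]}")
    mean = qc.mean(axis=1)
    sd = qc.std(axis=1, ddof=1)
    defined = mean > 0
    rsd = pd.Series(sd[defined] / mean[defined], index=table.features.index[defined], name="rsd")
    excluded = pd.Series(
        "zero QC mean", index=table.features.index[~defined], name="reason", dtype=object
    )
    return RsdTable(rsd=rsd, excluded=excluded, label=label)


def summarize_rsd(rsd: RsdTable, threshold: float = RSD_THRESHOLD) -> RsdSummary:
    """Median, interquartile range, and count strictly below ``threshold``."""
    values = rsd.rsd.to_numpy()
    if values.size == 0:
        raise ValidationError("RSD table is empty")
    n_below = int((values < threshold).sum())
    return RsdSummary(
        median=float(np.median(values)),
        iqr=(float(np.percentile(values, 25)), float(np.percentile(values, 75))),
        n_below=n_below,
        n_total=values.size,
        fraction_below=n_below / values.size,
        threshold=threshold,
    )


def compare_rsd_paired(a: RsdTable, b: RsdTable) -> RsdComparison:
    """Paired t-test of per-feature RSD between two normalization states.

    Differences are computed as a - b over the features defined in both
    tables; a positive mean difference means state ``a`` is less
    reproducible. When every difference is identical the t statistic is
    undefined and the comparison is flagged degenerate (the exact-zero case
    arises whenever a normalization leaves QC areas untouched).
    """
    common = a.rsd.index.intersection(b.rsd.index)
    if len(common) < 2:
        raise ValidationError(f"only {len(common)} features defined in both RSD tables")
    diff = a.rsd[common].to_numpy() - b.rsd[common].to_numpy()
    mean_diff = float(diff.mean())
    if np.ptp(diff) == 0.0:
        return RsdComparison(
            mean_difference=mean_diff,
            t_statistic=float("nan"),
            p_value=float("nan"),
            n_common=len(common),
            degenerate=True,
        )
    t, p = stats.ttest_rel(a.rsd[common].to_numpy(), b.rsd[common].to_numpy())
    return RsdComparison(
        mean_difference=mean_diff,
        t_statistic=float(t),
        p_value=float(p),
        n_common=len(common),
        degenerate=False,
    )


def pca_qc_dispersion(
    table: PeakTable, n_components: int = 2, scaling: str = "uv"
) -> tuple[pd.DataFrame, float]:
    """Quantify QC clustering in PCA score space.

    Runs PCA on QC + study samples (features centered; ``scaling`` one of
    "uv" for unit variance, "pareto", or "none"; constant features dropped)
    and returns the score matrix together with the dispersion ratio:

        mean ||QC score - QC centroid|| / mean ||study score - study centroid||

    over the first ``n_components`` components. Lower means tighter QC
    clustering; ~1 means QCs scatter like study samples.
    """
    if scaling not in ("uv", "pareto", "none"):
        raise ValidationError(f"unknown scaling {scaling!r}")
    keep = table.samples["sample_type"].isin(["QC", "study"])
    ids = table.samples.index[keep]
    types = table.samples.loc[ids, "sample_type"]
    if (types == "QC").sum() < 3 or (types == "study").sum() < 3:
        raise ValidationError("PCA dispersion needs >= 3 QCs and >= 3 study samples")

    x = table.intensities[ids].to_numpy().T  # samples x features
    sd = x.std(axis=0, ddof=1)
    varying = sd > 0
    if not varying.any():
        raise ValidationError("all features are constant; PCA undefined")
    x = x[:, varying]
    sd = sd[varying]
    x = x - x.mean(axis=0)
    if scaling == "uv":
        x = x / sd
    elif scaling == "pareto":
        x = x / np.sqrt(sd)

    n_components = min(n_components, min(x.shape) - 1)
    scores = PCA(n_components=n_components, svd_solver="full").fit_transform(x)
    score_df = pd.DataFrame(
        scores, index=ids, columns=[f"PC{k + 1}" for k in range(n_components)]
    )
    qc_scores = scores[(types == "QC").to_numpy()]
    study_scores = scores[(types == "study").to_numpy()]
    qc_spread = np.linalg.norm(qc_scores - qc_scores.mean(axis=0), axis=1).mean()
    study_spread = np.linalg.norm(study_scores - study_scores.mean(axis=0), axis=1).mean()
    if study_spread == 0:
        raise ValidationError("study samples have zero PCA spread; ratio undefined")
    return score_df, float(qc_spread / study_spread)
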