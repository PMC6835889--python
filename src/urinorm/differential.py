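"""Paired pre/post differential testing with FDR control.

Each subject contributes one pre- and one post-phase sample, so per-feature
change is tested with the Wilcoxon paired signed-rank test on post - pre
differences (nonparametric, hence invariant to any monotone per-feature
transform of the normalized areas). P-values are adjusted per run with the
Benjamini-Hochberg step-up procedure, and candidate biomarkers are the
features passing the conventional conjunction VIP > 1 and q < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .peaktable import PeakTable

#: above this many nonzero pairs the normal approximation is used
EXACT_LIMIT = 25
MIN_PAIRS = 5


@dataclass
class WilcoxonResult:
    statistic: float
    p_value: float
    n_pairs: int            # nonzero-difference pairs used
    degenerate: bool        # all differences zero
    median_diff_sign: int   # sign of the median paired difference


@dataclass
class DifferentialTable:
    """Per-feature test results for one normalization state."""

    table: pd.DataFrame     # statistic, p_value, q_value, sign, vip, selected
    skipped: pd.Series      # feature id -> reason
    label: str = ""


def _paired_matrix(table: PeakTable) -> pd.DataFrame:
    """Features x subjects matrix of post - pre differences."""
    study = table.samples[table.samples["sample_type"] == "study"]
    if study.empty:
        raise ValidationError("table has no study samples")
    by_phase = {}
    for phase in ("pre", "post"):
        sel = study[study["phase"] == phase]
        block = table.intensities[sel.index]
        block.columns = sel["subject_id"].to_numpy()
        by_phase[phase] = block
    subjects = by_phase["pre"].columns.intersection(by_phase["post"].columns)
    if len(subjects) == 0:
        raise ValidationError("no subject has both pre and post samples")
    return by_phase["post"][subjects] - by_phase["pre"][subjects]


def paired_differences(table: PeakTable, feature_id: str) -> np.ndarray:
    """post - pre peak-area differences across subjects with both phases."""
    if feature_id not in table.features.index:
        raise ValidationError(f"unknown feature {feature_id!r}")
    return _paired_matrix(table).loc[feature_id].to_numpy()


def _test_differences(diff: np.ndarray, feature_id: str = "") -> WilcoxonResult:
    nonzero = diff[diff != 0]
    if nonzero.size == 0:
        return WilcoxonResult(
            statistic=0.0, p_value=1.0, n_pairs=0, degenerate=True, median_diff_sign=0
        )
    if nonzero.size < MIN_PAIRS:
        raise ValidationError(
            f"feature {feature_id!r}: only {nonzero.size} nonzero paired "
            f"differences (< {MIN_PAIRS})"
        )
    ranks_tied = len(np.unique(np.abs(nonzero))) < nonzero.size
    method = "exact" if (nonzero.size <= EXACT_LIMIT and not ranks_tied) else "approx"
    res = stats.wilcoxon(
        nonzero, alternative="two-sided", zero_method="wilcox",
        correction=(method == "approx"), method=method,
    )
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_pairs=int(nonzero.size),
        degenerate=False,
        median_diff_sign=int(np.sign(np.median(diff))),
    )


def wilcoxon_paired(table: PeakTable, feature_id: str) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on post - pre for one feature.

    Zero differences are dropped before ranking; ties are mid-ranked. The
    exact null distribution is used for <= 25 nonzero untied pairs, the
    normal approximation with continuity correction otherwise. All-zero
    differences give p = 1 with a degenerate flag; fewer than 5 usable
    pairs raises.
    """
    return _test_differences(paired_differences(table, feature_id), feature_id)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_test(
    table: PeakTable, vip: pd.Series | None = None, q_threshold: float = 0.05,
    vip_threshold: float = 1.0, label: str = "",
) -> DifferentialTable:
    """Wilcoxon test for every feature, BH adjustment, and biomarker flags.

    Features without enough usable pairs are skipped with a reason; FDR is
    computed over the tested features of this run only. When VIP scores are
    supplied, ``selected`` marks VIP > vip_threshold and q < q_threshold.
    """
    diffs = _paired_matrix(table)
    rows = {}
    skipped = {}
    for fid in table.features.index:
        try:
            rows[fid] = _test_differences(diffs.loc[fid].to_numpy(), fid)
        except ValidationError as exc:
            skipped[fid] = str(exc)
    if not rows:
        raise ValidationError("no feature had enough paired observations to test")
    out = pd.DataFrame(
        {
            "statistic": {f: r.statistic for f, r in rows.items()},
            "p_value": {f: r.p_value for f, r in rows.items()},
            "sign": {f: r.median_diff_sign for f, r in rows.items()},
            "degenerate": {f: r.degenerate for f, r in rows.items()},
        }
    )
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    if vip is not None:
        out["vip"] = vip.reindex(out.index)
        out["selected"] = (out["vip"] > vip_threshold) & (out["q_value"] < q_threshold)
    return DifferentialTable(
        table=out,
        skipped=pd.Series(skipped, name="reason", dtype=object),
        label=label,
    )


def select_features(
    diff: DifferentialTable, vip: pd.Series,
    vip_threshold: float = 1.0, q_threshold: float = 0.05,
) -> tuple[list[str], int]:
    """Features with VIP strictly above and q strictly below the thresholds."""
    common = diff.table.index.intersection(vip.index)
    if len(common) == 0:
        raise ValidationError("differential table and VIP scores share no features")
    q = diff.table.loc[common, "q_value"]
    v = vip[common]
    selected = list(common[(v > vip_threshold) & (q < q_threshold)])
    return selected, len(selected)
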