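"""End-to-end comparison of normalization methods on one peak table.

Orchestrates the full benchmarking workflow: QC-zero feature filtering,
SVR drift correction, each requested concentration normalization, and the
evaluation suite (QC RSD summaries and pairwise paired t-tests, PCA QC
dispersion, OPLS-DA with VIP and optional permutation validation, paired
Wilcoxon differential testing with the VIP > 1 & q < 0.05 selection rule).
The report mirrors the three standard summary tables of a normalization
comparison: per-method RSD, pairwise RSD differences, and per-method
class-separation results.

Everything is deterministic given the configuration and its master seed:
the seed deterministically spawns one sub-seed per stochastic stage.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ValidationError
from .peaktable import (
    PeakTable,
    filter_all_zero_qc_features,
    filter_qc_zero_features,
    find_feature,
    read_peak_table,
    write_peak_table,
)
from .synthetic import (
    CREATININE_MZ,
    CREATININE_RT,
    SyntheticConfig,
    SyntheticTruth,
    config_to_dict,
    generate,
)
from .drift import correct_drift, drift_diagnostics, fit_drift
from .normalize import (
    SgParams,
    default_sg_ref,
    normalize_creatinine,
    normalize_pqn_classical,
    normalize_pqn_paper,
    normalize_specific_gravity,
)
from .qc import RsdSummary, RsdTable, compare_rsd_paired, compute_rsd, pca_qc_dispersion, summarize_rsd
from .opls import opls_fit, opls_q2, permutation_test, rsd_filtered_features, vip_scores
from .differential import differential_test

logger = logging.getLogger("urinorm")

#: canonical ordering of report rows, independent of config listing order
METHOD_ORDER = ("raw", "svr_only", "creatinine", "specific_gravity", "pqn_paper", "pqn_classical")


@dataclass
class PipelineConfig:
    """Configuration of one comparison run."""

    methods: tuple[str, ...] = METHOD_ORDER
    intensity_path: str | None = None
    sample_meta_path: str | None = None
    synthetic: SyntheticConfig | None = None
    min_zero_qc: int = 3
    drift_min_qc: int = 5
    drift_fit_log: bool = False
    sg_ref: float | None = None          # None: median study SG
    creatinine_source: str = "auto"      # "auto" | metadata column | feature id
    rsd_threshold: float = 0.3
    n_ortho: int = 1
    n_folds: int = 7
    n_permutations: int = 0              # 0 disables permutation validation
    scaling: str = "uv"
    seed: int = 0

    def validate(self) -> None:
        if not self.methods:
            raise ValidationError("at least one method must be requested")
        unknown = set(self.methods) - set(METHOD_ORDER)
        if unknown:
            raise ValidationError(f"unknown method(s): {sorted(unknown)}")
        has_files = self.intensity_path is not None and self.sample_meta_path is not None
        if has_files == (self.synthetic is not None):
            raise ValidationError(
                "provide either input file paths or a synthetic config (exactly one)"
            )

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["methods"] = list(self.methods)
        return d


@dataclass
class ComparisonReport:
    """All evaluation results of one comparison run."""

    methods: tuple[str, ...]
    n_features_input: int
    n_features_filtered: int
    qc_zero_removed: list[str]
    rsd_tables: dict[str, RsdTable]
    rsd_summaries: dict[str, RsdSummary]
    rsd_comparisons: pd.DataFrame
    pca_dispersion: dict[str, float]
    opls_summary: pd.DataFrame
    differential: dict = field(default_factory=dict)
    permutation: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


def _stage_seeds(seed: int, n: int) -> list[int]:
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def _normalized_tables(table: PeakTable, config: PipelineConfig) -> dict[str, PeakTable]:
    """Filtered/raw, drift-corrected, and per-method normalized tables."""
    filtered, removed = filter_qc_zero_features(table, config.min_zero_qc)
    logger.info("filter_qc_zero: %d features in, %d removed", table.n_features, len(removed))

    model = fit_drift(filtered, min_qc=config.drift_min_qc, fit_log=config.drift_fit_log)
    corrected = correct_drift(filtered, model)
    logger.info("drift: %d fallback features", int(model.fallback.sum()))

    tables: dict[str, PeakTable] = {}
    for method in METHOD_ORDER:
        if method not in config.methods:
            continue
        if method == "raw":
            tables[method] = filtered
        elif method == "svr_only":
            tables[method] = corrected
        elif method == "creatinine":
            source = config.creatinine_source
            if source == "auto":
                try:
                    source = find_feature(corrected, CREATININE_MZ, CREATININE_RT)
                except Exception:
                    source = "creatinine_pa"
            tables[method] = normalize_creatinine(corrected, source).table
        elif method == "specific_gravity":
            sg_ref = config.sg_ref if config.sg_ref is not None else default_sg_ref(corrected)
            tables[method] = normalize_specific_gravity(corrected, SgParams(sg_ref=sg_ref)).table
        elif method in ("pqn_paper", "pqn_classical"):
            pqn_input, dropped = filter_all_zero_qc_features(corrected)
            if dropped:
                logger.info("%s: %d all-zero-QC features removed", method, len(dropped))
            norm = normalize_pqn_paper(pqn_input) if method == "pqn_paper" else normalize_pqn_classical(pqn_input)
            tables[method] = norm.table
        logger.info("method %s: %d features", method, tables[method].n_features)

    # stash for reporting
    tables["__meta__"] = (table.n_features, filtered.n_features, removed, model, filtered, corrected)
    return tables


def run_comparison(config: PipelineConfig) -> ComparisonReport:
    """Execute the full comparison described by ``config``."""
    config.validate()
    q2_seed, perm_seed = _stage_seeds(config.seed, 2)

    if config.synthetic is not None:
        table, _truth = generate(config.synthetic)
        logger.info("synthetic run: %d features x %d samples", table.n_features, table.n_samples)
    else:
        table = read_peak_table(config.intensity_path, config.sample_meta_path)
        logger.info("loaded run: %d features x %d samples", table.n_features, table.n_samples)

    tables = _normalized_tables(table, config)
    n_in, n_filt, removed, _model, _filtered, _corrected = tables.pop("__meta__")
    methods = tuple(m for m in METHOD_ORDER if m in tables)

    rsd_tables = {m: compute_rsd(tables[m], label=m) for m in methods}
    rsd_summaries = {m: summarize_rsd(rsd_tables[m], config.rsd_threshold) for m in methods}

    comparisons = []
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            cmp_res = compare_rsd_paired(rsd_tables[a], rsd_tables[b])
            comparisons.append(
                {
                    "method_a": a, "method_b": b,
                    "rsd_mean_difference": cmp_res.mean_difference,
                    "t_statistic": cmp_res.t_statistic,
                    "p_value": cmp_res.p_value,
                    "n_common_features": cmp_res.n_common,
                    "degenerate": cmp_res.degenerate,
                }
            )
    comparisons = pd.DataFrame(comparisons)

    dispersion = {m: pca_qc_dispersion(tables[m])[1] for m in methods}

    opls_rows = []
    differential = {}
    permutation = {}
    for m in methods:
        feats = rsd_filtered_features(rsd_tables[m], config.rsd_threshold)
        feats = tables[m].features.index.intersection(feats)
        row = {"method": m, "features_n": len(feats)}
        try:
            model = opls_fit(
                tables[m], rsd_tables[m], config.rsd_threshold,
                n_ortho=config.n_ortho, scaling=config.scaling,
            )
            vip = vip_scores(model)
            q2 = opls_q2(
                tables[m], model.feature_ids, n_ortho=config.n_ortho,
                n_folds=config.n_folds, seed=q2_seed, scaling=config.scaling,
            )
            diff = differential_test(tables[m].subset_features(model.feature_ids), vip=vip, label=m)
            differential[m] = diff
            row.update(
                r2x=model.r2x, r2y=model.r2y, q2=q2,
                n_selected=int(diff.table.get("selected", pd.Series(dtype=bool)).sum()),
            )
            if config.n_permutations:
                perm = permutation_test(
                    tables[m], model.feature_ids, n_permutations=config.n_permutations,
                    seed=perm_seed, n_ortho=config.n_ortho, n_folds=config.n_folds,
                    scaling=config.scaling,
                )
                permutation[m] = perm
                row.update(r2_intercept=perm.r2_intercept, q2_intercept=perm.q2_intercept)
        except ValidationError as exc:
            logger.warning("OPLS/differential stage failed for %s: %s", m, exc)
            row.update(error=str(exc))
        opls_rows.append(row)
        logger.info("evaluated %s", m)

    report = ComparisonReport(
        methods=methods,
        n_features_input=n_in,
        n_features_filtered=n_filt,
        qc_zero_removed=removed,
        rsd_tables=rsd_tables,
        rsd_summaries=rsd_summaries,
        rsd_comparisons=comparisons,
        pca_dispersion=dispersion,
        opls_summary=pd.DataFrame(opls_rows).set_index("method"),
        differential=differential,
        permutation=permutation,
        provenance={
            "config": config.to_dict(),
            "seed": config.seed,
            "stage_seeds": {"q2": q2_seed, "permutation": perm_seed},
            "urinorm_version": __version__,
        },
    )
    return report


def write_report(report: ComparisonReport, out_dir: str, include_differential: bool = True) -> None:
    """Write the report as CSV tables plus a JSON run manifest."""
    os.makedirs(out_dir, exist_ok=True)

    rows = []
    for m, s in report.rsd_summaries.items():
        rows.append(
            {
                "method": m, "median_rsd": s.median,
                "iqr_low": s.iqr[0], "iqr_high": s.iqr[1],
                "n_below_threshold": s.n_below, "n_total": s.n_total,
                "fraction_below": s.fraction_below, "threshold": s.threshold,
            }
        )
    pd.DataFrame(rows).to_csv(os.path.join(out_dir, "rsd_summary.csv"), index=False)
    report.rsd_comparisons.to_csv(os.path.join(out_dir, "rsd_comparisons.csv"), index=False)
    pd.Series(report.pca_dispersion, name="dispersion_ratio").rename_axis("method").to_csv(
        os.path.join(out_dir, "pca_dispersion.csv")
    )
    report.opls_summary.to_csv(os.path.join(out_dir, "opls_summary.csv"))
    if include_differential:
        for m, diff in report.differential.items():
            diff.table.rename_axis("feature_id").to_csv(
                os.path.join(out_dir, f"differential_{m}.csv")
            )
    manifest = dict(report.provenance)
    manifest.update(
        n_features_input=report.n_features_input,
        n_features_filtered=report.n_features_filtered,
        n_qc_zero_removed=len(report.qc_zero_removed),
    )
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def make_synthetic(config: SyntheticConfig, out_dir: str) -> tuple[str, str, str]:
    """Generate a synthetic run and write its peak table and ground truth.

    Returns (intensity_path, sample_meta_path, truth_path). The truth file
    records the dilution factors, effect features, creatinine feature and
    generator configuration as JSON; drift curves are regenerable from the
    configuration and are not serialized.
    """
    table, truth = generate(config)
    intensity_path, meta_path = write_peak_table(table, out_dir)
    truth_path = os.path.join(out_dir, "truth.json")
    payload = {
        "config": config_to_dict(config),
        "creatinine_feature_id": truth.creatinine_feature_id,
        "dilution": {k: float(v) for k, v in truth.dilution.items()},
        "effect_features": {k: float(v) for k, v in truth.effect_features.items()},
    }
    with open(truth_path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
    return intensity_path, meta_path, truth_path
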