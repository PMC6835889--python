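"""Synthetic paired-urine metabolomics cohorts with known ground truth.

The generator emulates the statistical structure of an untargeted LC-MS
run on paired urine samples: a cohort of subjects sampled in two biological
states (``pre`` and ``post``), pooled QC injections at the run start and at
a fixed cadence, per-sample multiplicative urinary dilution tied to measured
specific gravity, smooth injection-order signal drift, multiplicative
measurement noise, occasional non-detects recorded as zeros, a minority of
features with genuine phase effects, and a designated creatinine feature
whose excretion shifts with phase (the confounding scenario in which
creatinine normalization fails).

Every stochastic element derives from one seed, so a configuration is a
complete, bit-reproducible description of a run. The ground truth
(:class:`SyntheticTruth`) exposes the dilution factors, drift curves and
effect features so downstream corrections can be tested as parameter
recovery problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ValidationError
from .peaktable import PeakTable

#: creatinine [M-H]- coordinates used for the designated creatinine feature
CREATININE_MZ = 112.05132
CREATININE_RT = 277.282


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of a synthetic run.

    Defaults follow the paired-cohort design the package targets:
    45 subjects x 2 phases (90 study injections) with pooled QCs every
    6 injections after 3 lead-in QCs, ~2000 features, log-normal dilution
    with geometric mean 1, and a creatinine feature that falls by a factor
    of 2^-0.5 from pre to post phase.
    """

    n_subjects: int = 45
    n_features: int = 2000
    qc_every: int = 6
    n_lead_qcs: int = 3
    dilution_sigma: float = 0.4     # std of log dilution factor
    drift_amplitude: float = 0.3    # fractional peak-area change across the run
    effect_fraction: float = 0.1    # fraction of features with a phase effect
    effect_log2fc: float = 1.0      # |log2 fold change| of effect features
    noise_cv: float = 0.1           # per-measurement multiplicative noise CV
    creatinine_phase_log2fc: float = -0.5
    sg_solute_coeff: float = 0.020  # maps relative solute load to SG - 1
    zero_rate: float = 0.01         # fraction of low signals recorded as 0
    solute_load_sigma: float = 0.0  # std of log per-subject solute load
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValidationError("n_subjects must be >= 2")
        if self.n_features < 2:
            raise ValidationError("n_features must be >= 2")
        if self.qc_every < 2:
            raise ValidationError("qc_every must be >= 2")
        if self.n_lead_qcs < 0:
            raise ValidationError("n_lead_qcs must be >= 0")
        for name in ("dilution_sigma", "drift_amplitude", "noise_cv", "solute_load_sigma"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("effect_fraction", "zero_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.sg_solute_coeff <= 0:
            raise ValidationError("sg_solute_coeff must be > 0")


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated peak table."""

    dilution: pd.Series                 # per study sample, geometric mean 1
    drift_curves: pd.DataFrame          # features x injection orders
    effect_features: dict[str, float]   # feature id -> signed log2 fold change
    base_profile: pd.Series             # per-feature pre-phase concentration
    pooled_profile: pd.Series           # per-feature pooled (QC) concentration
    creatinine_feature_id: str
    sample_phase: dict[str, str]        # sample id -> "QC" | "pre" | "post"
    config: SyntheticConfig = field(repr=False)


def _injection_layout(config: SyntheticConfig) -> list[str]:
    """Sequence of slot kinds ("QC" or "study") over the whole run."""
    slots = ["QC"] * config.n_lead_qcs
    n_study = 2 * config.n_subjects
    placed = 0
    while placed < n_study:
        block = min(config.qc_every, n_study - placed)
        slots.extend(["study"] * block)
        placed += block
        if block == config.qc_every:
            slots.append("QC")
    return slots


def generate(config: SyntheticConfig) -> tuple[PeakTable, SyntheticTruth]:
    """Generate one synthetic run.

    Study peak area for feature ``f`` in sample ``i`` is

        base_f * phase_effect_f(i) * d_i * drift_f(order_i) * noise,

    QC peak area is ``pooled_f * drift_f(order) * noise`` (dilution factor 1,
    pooled profile = mean study concentration), and measured specific gravity
    is ``1 + sg_solute_coeff * d_i * load_subject / mean(load)``. Values in
    the lowest ``zero_rate`` quantile of the run are recorded as 0
    (non-detects).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_study = 2 * config.n_subjects
    slots = _injection_layout(config)
    n_inj = len(slots)

    # --- features -----------------------------------------------------
    feature_ids = [f"F{i + 1:05d}" for i in range(config.n_features)]
    mz = rng.uniform(70.0, 1000.0, config.n_features)
    rt = rng.uniform(30.0, 1080.0, config.n_features)
    log_base = rng.normal(np.log(1.0e4), 1.2, config.n_features)
    base = np.exp(log_base)

    # designated creatinine feature: high-abundance, at its known coordinates
    creat_idx = int(rng.integers(config.n_features))
    mz[creat_idx] = CREATININE_MZ
    rt[creat_idx] = CREATININE_RT
    base[creat_idx] = np.quantile(base, 0.98) * 2.0
    creat_id = feature_ids[creat_idx]

    # --- phase effects ------------------------------------------------
    n_effect = int(round(config.effect_fraction * config.n_features))
    candidates = np.setdiff1d(np.arange(config.n_features), [creat_idx])
    effect_idx = rng.choice(candidates, size=min(n_effect, len(candidates)), replace=False)
    effect_sign = rng.choice([-1.0, 1.0], size=len(effect_idx))
    log2fc = np.zeros(config.n_features)
    log2fc[effect_idx] = effect_sign * config.effect_log2fc
    log2fc[creat_idx] = config.creatinine_phase_log2fc

    # --- subjects, dilution, specific gravity -------------------------
    subjects = [f"subj{j + 1:03d}" for j in range(config.n_subjects)]
    d = np.exp(rng.normal(0.0, config.dilution_sigma, n_study))
    d /= np.exp(np.mean(np.log(d)))  # geometric mean exactly 1
    load = np.exp(rng.normal(0.0, config.solute_load_sigma, config.n_subjects))
    load /= load.mean()

    # study injection order randomized across (subject, phase) pairs
    pairs = [(s, p) for s in subjects for p in ("pre", "post")]
    order_perm = rng.permutation(n_study)
    pairs = [pairs[k] for k in order_perm]

    # --- drift curves -------------------------------------------------
    x = np.linspace(0.0, 1.0, n_inj) if n_inj > 1 else np.zeros(1)
    amp = config.drift_amplitude * rng.uniform(0.5, 1.0, config.n_features)
    sign = rng.choice([-1.0, 1.0], size=config.n_features)
    curvature = rng.uniform(0.0, 1.0, config.n_features)
    shapes = (1.0 - curvature)[:, None] * x[None, :] + curvature[:, None] * x[None, :] ** 2
    drift = 1.0 + (sign * amp)[:, None] * shapes
    drift = np.maximum(drift, 0.05)

    # --- concentrations -----------------------------------------------
    phase_mult = np.where(
        np.array([p for (_, p) in pairs]) == "post", 2.0 ** log2fc[:, None], 1.0
    )  # features x study samples
    conc_study = base[:, None] * phase_mult
    pooled = conc_study.mean(axis=1)

    # --- assemble run in injection order -------------------------------
    sigma_ln = np.sqrt(np.log1p(config.noise_cv**2))

    sample_ids: list[str] = []
    sample_rows: list[dict] = []
    cols: list[np.ndarray] = []
    study_ids: list[str] = []
    qc_count = 0
    study_count = 0
    for order, kind in enumerate(slots, start=1):
        noise = (
            np.exp(rng.normal(-0.5 * sigma_ln**2, sigma_ln, config.n_features))
            if config.noise_cv > 0
            else np.ones(config.n_features)
        )
        if kind == "QC":
            qc_count += 1
            sid = f"QC{qc_count:02d}"
            col = pooled * drift[:, order - 1] * noise
            row = {"sample_id": sid, "sample_type": "QC", "injection_order": order}
        else:
            subj, phase = pairs[study_count]
            sid = f"{subj}_{phase}"
            d_i = d[study_count]
            load_i = load[subjects.index(subj)]
            sg = 1.0 + config.sg_solute_coeff * d_i * load_i
            sg = min(sg, 1.0999)
            col = conc_study[:, study_count] * d_i * drift[:, order - 1] * noise
            row = {
                "sample_id": sid,
                "sample_type": "study",
                "injection_order": order,
                "subject_id": subj,
                "phase": phase,
                "specific_gravity": sg,
            }
            study_ids.append(sid)
            study_count += 1
        sample_ids.append(sid)
        sample_rows.append(row)
        cols.append(col)

    intensities = np.column_stack(cols)

    # --- non-detects ---------------------------------------------------
    if config.zero_rate > 0:
        threshold = np.quantile(intensities, config.zero_rate)
        intensities = np.where(intensities < threshold, 0.0, intensities)

    samples = pd.DataFrame(sample_rows).set_index("sample_id")
    samples["creatinine_pa"] = intensities[creat_idx, :]

    features = pd.DataFrame({"mz": mz, "rt": rt}, index=pd.Index(feature_ids, name="feature_id"))
    table = PeakTable(
        intensities=pd.DataFrame(intensities, index=features.index, columns=samples.index),
        features=features,
        samples=samples,
    )

    phase_map = {sid: "QC" for sid in sample_ids if sid.startswith("QC")}
    phase_map.update({f"{s}_{p}": p for (s, p) in pairs})
    truth = SyntheticTruth(
        dilution=pd.Series(d, index=pd.Index(study_ids, name="sample_id")),
        drift_curves=pd.DataFrame(
            drift, index=features.index, columns=pd.RangeIndex(1, n_inj + 1, name="injection_order")
        ),
        effect_features={feature_ids[i]: log2fc[i] for i in effect_idx},
        base_profile=pd.Series(base, index=features.index),
        pooled_profile=pd.Series(pooled, index=features.index),
        creatinine_feature_id=creat_id,
        sample_phase=phase_map,
        config=config,
    )
    return table, truth


def truth_concentrations(truth: SyntheticTruth, sample_id: str) -> pd.Series:
    """Drift-free, dilution-free expected concentration vector for a sample.

    QC samples map to the pooled mean profile; pre-phase study samples to the
    base profile; post-phase samples to the base profile with each effect
    feature (and creatinine) multiplied by its 2**log2fc.
    """
    phase = truth.sample_phase.get(sample_id)
    if phase is None:
        raise ValidationError(f"unknown sample id {sample_id!r}")
    if phase == "QC":
        return truth.pooled_profile.copy()
    conc = truth.base_profile.copy()
    if phase == "post":
        cfg = truth.config
        for fid, fc in truth.effect_features.items():
            conc[fid] *= 2.0**fc
        conc[truth.creatinine_feature_id] *= 2.0**cfg.creatinine_phase_log2fc
    return conc


def config_to_dict(config: SyntheticConfig) -> dict:
    return asdict(config)
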