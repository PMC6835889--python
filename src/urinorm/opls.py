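"""Orthogonal partial least-squares discriminant analysis (OPLS-DA).

Two-class OPLS-DA splits predictor variance into one class-predictive
component and ``n_ortho`` orthogonal components that vary independently of
class. For a single response the orthogonal filter is deterministic (no
NIPALS iteration is needed): at each step the predictive weight vector is
w ∝ X'y, the loading p = X't/(t't) is computed for t = Xw, and the part of
p orthogonal to w defines an orthogonal component that is deflated from X.
The final predictive component is a one-component PLS fit on the filtered
matrix, so with ``n_ortho = 0`` the model reduces exactly to PLS1-DA.

Model quality is summarized by R²X (predictor variance captured by all
fitted components), R²Y (class variance explained in training), and Q²
(cross-validated 1 - PRESS/TSS over stratified folds with preprocessing
refit inside each training fold). Feature influence is scored by VIP,
normalized so that the squared scores average 1; validity is checked by
refitting under random label permutations and extrapolating R²Y/Q² to zero
label correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .errors import ValidationError
from .peaktable import PeakTable
from .qc import RsdTable

CLASS_ENCODING = {"pre": -1.0, "post": 1.0}


# ----------------------------------------------------------------------
# matrix-level core (reused by cross-validation and permutations)
# ----------------------------------------------------------------------

def _preprocess(X: np.ndarray, scaling: str):
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if scaling == "uv":
        scale = np.where(sd > 0, sd, 1.0)
    elif scaling == "pareto":
        scale = np.where(sd > 0, np.sqrt(sd), 1.0)
    elif scaling == "none":
        scale = np.ones_like(sd)
    else:
        raise ValidationError(f"unknown scaling {scaling!r}")
    return (X - mean) / scale, mean, scale


def _fit_core(Xs: np.ndarray, y: np.ndarray, n_ortho: int) -> dict:
    """Fit OPLS on preprocessed X and centered y; returns component record."""
    X = Xs.copy()
    yc = y - y.mean()
    ss_x0 = float((Xs**2).sum())
    ss_y = float((yc**2).sum())
    if ss_y == 0:
        raise ValidationError("response has zero variance (single class?)")

    w_ortho, p_ortho, t_ortho = [], [], []
    for _ in range(n_ortho):
        w = X.T @ yc
        norm_w = np.linalg.norm(w)
        if norm_w == 0:
            break
        w /= norm_w
        t = X @ w
        p = X.T @ t / (t @ t)
        wo = p - (w @ p) * w
        norm_wo = np.linalg.norm(wo)
        if norm_wo < 1e-12:
            break
        wo /= norm_wo
        to = X @ wo
        po = X.T @ to / (to @ to)
        X = X - np.outer(to, po)
        w_ortho.append(wo)
        p_ortho.append(po)
        t_ortho.append(to)

    w = X.T @ yc
    norm_w = np.linalg.norm(w)
    if norm_w == 0:
        raise ValidationError("predictors are uncorrelated with the response")
    w /= norm_w
    t = X @ w
    tt = float(t @ t)
    p = X.T @ t / tt
    q = float(yc @ t / tt)

    resid = yc - t * q
    r2y = 1.0 - float((resid**2).sum()) / ss_y
    ss_pred = tt * float(p @ p)
    ss_orth = sum(float(to @ to) * float(po @ po) for to, po in zip(t_ortho, p_ortho))
    r2x = (ss_pred + ss_orth) / ss_x0 if ss_x0 > 0 else 0.0

    return {
        "w": w, "t": t, "p": p, "q": q,
        "w_ortho": w_ortho, "p_ortho": p_ortho, "t_ortho": t_ortho,
        "y_mean": float(y.mean()), "r2x": r2x, "r2y": r2y,
        "ss_pred_x": ss_pred, "ss_x0": ss_x0,
    }


def _predict_core(core: dict, Xs: np.ndarray) -> np.ndarray:
    """Predict the response for preprocessed new samples."""
    X = Xs.copy()
    for wo, po in zip(core["w_ortho"], core["p_ortho"]):
        to = X @ wo
        X = X - np.outer(to, po)
    t = X @ core["w"]
    return t * core["q"] + core["y_mean"]


def _q2_core(
    X: np.ndarray, y: np.ndarray, n_ortho: int, n_folds: int, seed: int, scaling: str
) -> float:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValidationError("Q2 requires exactly two classes")
    if counts.min() < n_folds:
        raise ValidationError(
            f"cannot form {n_folds} stratified folds with only {counts.min()} "
            "samples in the smaller class"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    press = 0.0
    tss = 0.0
    for train, test in skf.split(X, y):
        Xs_train, mean, scale = _preprocess(X[train], scaling)
        core = _fit_core(Xs_train, y[train], n_ortho)
        Xs_test = (X[test] - mean) / scale
        y_hat = _predict_core(core, Xs_test)
        press += float(((y[test] - y_hat) ** 2).sum())
        tss += float(((y[test] - y[train].mean()) ** 2).sum())
    return 1.0 - press / tss


# ----------------------------------------------------------------------
# table-level interface
# ----------------------------------------------------------------------

@dataclass
class OplsModel:
    """A fitted two-class OPLS-DA model."""

    feature_ids: pd.Index
    weights: np.ndarray             # predictive weights, unit norm
    loadings: np.ndarray            # predictive X loadings
    scores: np.ndarray              # predictive scores (training samples)
    q: float                        # response loading
    ortho_weights: list[np.ndarray]
    ortho_loadings: list[np.ndarray]
    ortho_scores: list[np.ndarray]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    class_encoding: dict[str, float]
    scaling: str
    r2x: float
    r2y: float
    sample_ids: pd.Index = field(default=None)

    @property
    def n_ortho(self) -> int:
        return len(self.ortho_weights)

    def predict(self, table: PeakTable) -> pd.Series:
        x = table.intensities.loc[self.feature_ids].to_numpy().T
        xs = (x - self.x_mean) / self.x_scale
        core = {
            "w_ortho": self.ortho_weights, "p_ortho": self.ortho_loadings,
            "w": self.weights, "q": self.q, "y_mean": self.y_mean,
        }
        return pd.Series(_predict_core(core, xs), index=table.samples.index)


@dataclass
class PermutationResult:
    """Label-permutation validation record for one fitted pipeline."""

    n_permutations: int
    r2y_permuted: np.ndarray
    q2_permuted: np.ndarray
    label_correlation: np.ndarray   # |corr(permuted, original labels)|
    r2y_original: float
    q2_original: float
    r2_intercept: float
    q2_intercept: float
    seed: int


def _study_design(table: PeakTable, feature_ids) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    study = table.samples[table.samples["sample_type"] == "study"]
    if study["phase"].isna().any():
        raise ValidationError("study samples without phase labels")
    y = study["phase"].map(CLASS_ENCODING).to_numpy(dtype=float)
    for phase, code in CLASS_ENCODING.items():
        if (y == code).sum() < 4:
            raise ValidationError(f"fewer than 4 samples in class {phase!r}")
    fid = pd.Index(feature_ids)
    X = table.intensities.loc[fid, study.index].to_numpy().T
    return X, y, fid


def rsd_filtered_features(rsd_filter: RsdTable, rsd_threshold: float = 0.3) -> pd.Index:
    """Feature ids passing the QC reproducibility criterion (RSD strictly below)."""
    return rsd_filter.rsd.index[rsd_filter.rsd < rsd_threshold]


def opls_fit(
    table: PeakTable,
    rsd_filter: RsdTable | None = None,
    rsd_threshold: float = 0.3,
    n_ortho: int = 1,
    scaling: str = "uv",
) -> OplsModel:
    """Fit OPLS-DA of phase (pre vs post) on the study samples.

    Features are restricted to those with QC RSD strictly below
    ``rsd_threshold`` when an RSD table is supplied. Predictors are centered
    and scaled (``uv``, ``pareto`` or ``none``); the class is encoded
    pre = -1, post = +1.
    """
    if rsd_filter is not None:
        feature_ids = rsd_filtered_features(rsd_filter, rsd_threshold)
        feature_ids = table.features.index.intersection(feature_ids)
        if len(feature_ids) < 2:
            raise ValidationError(
                f"only {len(feature_ids)} features pass the RSD filter; need >= 2"
            )
    else:
        feature_ids = table.features.index
    if len(feature_ids) < 1:
        raise ValidationError("no features to fit")
    X, y, fid = _study_design(table, feature_ids)
    Xs, mean, scale = _preprocess(X, scaling)
    core = _fit_core(Xs, y, n_ortho)
    study_ids = table.samples.index[table.samples["sample_type"] == "study"]
    return OplsModel(
        feature_ids=fid,
        weights=core["w"],
        loadings=core["p"],
        scores=core["t"],
        q=core["q"],
        ortho_weights=core["w_ortho"],
        ortho_loadings=core["p_ortho"],
        ortho_scores=core["t_ortho"],
        x_mean=mean,
        x_scale=scale,
        y_mean=core["y_mean"],
        class_encoding=dict(CLASS_ENCODING),
        scaling=scaling,
        r2x=core["r2x"],
        r2y=core["r2y"],
        sample_ids=study_ids,
    )


def vip_scores(model: OplsModel) -> pd.Series:
    """Variable importance in projection for the predictive component.

    With a single predictive component the VIP of feature j reduces to
    sqrt(p) * |w_j| for the unit-norm weight vector, so the squared scores
    sum to the number of features (mean-square 1).
    """
    if model.weights is None:
        raise ValidationError("model is not fitted")
    p = len(model.feature_ids)
    return pd.Series(np.sqrt(p) * np.abs(model.weights), index=model.feature_ids, name="vip")


def opls_q2(
    table: PeakTable,
    feature_ids,
    n_ortho: int = 1,
    n_folds: int = 7,
    seed: int = 0,
    scaling: str = "uv",
) -> float:
    """Cross-validated Q² = 1 - PRESS/TSS over stratified folds.

    Preprocessing (centering/scaling) is refit inside each training fold;
    the fold split is deterministic given ``seed``.
    """
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    X, y, _ = _study_design(table, feature_ids)
    return _q2_core(X, y, n_ortho, n_folds, seed, scaling)


def permutation_test(
    table: PeakTable,
    feature_ids,
    n_permutations: int = 200,
    seed: int = 0,
    n_ortho: int = 1,
    n_folds: int = 7,
    scaling: str = "uv",
) -> PermutationResult:
    """Validate the model by refitting under random label permutations.

    For each permutation, phase labels are shuffled uniformly, the full
    pipeline (scaling, OPLS fit, cross-validated Q²) is refit, and R²Y/Q²
    are recorded against the absolute correlation between permuted and
    original labels. Straight lines through these points — anchored by the
    original model at correlation 1 — give the R² and Q² intercepts at
    correlation 0; a sound model has intercepts near or below 0 for Q².
    """
    if n_permutations < 20:
        raise ValidationError("need >= 20 permutations for a stable intercept")
    X, y, _ = _study_design(table, feature_ids)
    rng = np.random.default_rng(seed)

    Xs, _, _ = _preprocess(X, scaling)
    core = _fit_core(Xs, y, n_ortho)
    r2y_orig = core["r2y"]
    q2_orig = _q2_core(X, y, n_ortho, n_folds, seed, scaling)

    r2y_perm = np.empty(n_permutations)
    q2_perm = np.empty(n_permutations)
    corr = np.empty(n_permutations)
    for k in range(n_permutations):
        y_perm = rng.permutation(y)
        corr[k] = abs(stats.pearsonr(y_perm, y)[0])
        core_k = _fit_core(Xs, y_perm, n_ortho)
        r2y_perm[k] = core_k["r2y"]
        q2_perm[k] = _q2_core(X, y_perm, n_ortho, n_folds, seed + k + 1, scaling)

    xs = np.concatenate([corr, [1.0]])
    r2_line = np.polyfit(xs, np.concatenate([r2y_perm, [r2y_orig]]), 1)
    q2_line = np.polyfit(xs, np.concatenate([q2_perm, [q2_orig]]), 1)
    return PermutationResult(
        n_permutations=n_permutations,
        r2y_permuted=r2y_perm,
        q2_permuted=q2_perm,
        label_correlation=corr,
        r2y_original=r2y_orig,
        q2_original=q2_orig,
        r2_intercept=float(r2_line[1]),
        q2_intercept=float(q2_line[1]),
        seed=seed,
    )
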