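"""QC-anchored correction of injection-order signal drift.

Instrument sensitivity changes smoothly over an LC-MS run, so the pooled QC
samples — identical in composition by construction — trace out each feature's
drift as a function of injection order. Following the QC-RSC family of
methods, each feature's QC peak areas are regressed on injection order with
an epsilon-insensitive support-vector machine (RBF kernel), and every sample
is rescaled by reference/fitted at its own injection position.

Fitting is done on areas relative to the feature's QC median, which makes
the regularization constant and the tube width scale-free: the default tube
of 0.05 corresponds to 5% of the QC median. A wider tube leaves a boundary
bias of up to the tube width where the drift is steep at the run edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVR

from .errors import ValidationError
from .peaktable import PeakTable

#: fitted curves are floored at this fraction of the reference level,
#: preventing division blow-ups where the SVR extrapolates toward zero
CURVE_FLOOR = 0.01


@dataclass
class DriftModel:
    """Per-feature fitted drift curves over the run's injection orders.

    ``curves`` holds fitted peak areas (absolute scale) per feature at every
    injection order present in the run; ``reference`` is each feature's QC
    median; ``fallback`` flags features where no curve was fit (too few
    nonzero QCs) and the constant reference is used instead.
    """

    curves: pd.DataFrame        # features x injection orders
    reference: pd.Series        # per-feature QC median (nonzero QCs)
    fallback: pd.Series         # per-feature bool
    hyperparameters: dict

    def fitted_at(self, orders: np.ndarray) -> np.ndarray:
        """Fitted values (features x len(orders)) at the given orders."""
        return self.curves[list(orders)].to_numpy()


def _median_heuristic_gamma(orders: np.ndarray) -> float:
    diffs = np.abs(orders[:, None] - orders[None, :])
    pos = diffs[diffs > 0]
    h = np.median(pos) if pos.size else 1.0
    return 1.0 / (2.0 * h * h)


def fit_drift(
    table: PeakTable,
    min_qc: int = 5,
    C: float = 1.0,
    epsilon: float = 0.05,
    gamma: float | None = None,
    fit_log: bool = False,
) -> DriftModel:
    """Fit per-feature QC drift curves against injection order.

    Features with at least ``min_qc`` nonzero QC areas get an RBF-SVR curve
    (fit on areas relative to the feature's nonzero-QC median; ``epsilon``
    is therefore a fraction of that median). Features with fewer usable QCs
    fall back to a constant curve at the reference level. The kernel scale
    defaults to the median heuristic on QC injection-order distances.

    Set ``fit_log`` to regress log relative areas instead; the returned
    curves are always on the linear scale.
    """
    qc = table.qc_matrix()
    if qc.shape[1] < 3:
        raise ValidationError(f"drift fitting needs >= 3 QC samples, found {qc.shape[1]}")
    if not np.isfinite(qc.to_numpy()).all():
        raise ValidationError("QC intensities contain non-finite values")

    qc_orders = table.samples.loc[qc.columns, "injection_order"].to_numpy(dtype=float)
    all_orders = np.sort(table.samples["injection_order"].to_numpy(dtype=int))
    if gamma is None:
        gamma = _median_heuristic_gamma(qc_orders)

    n_feat = table.n_features
    curves = np.ones((n_feat, len(all_orders)))
    reference = np.zeros(n_feat)
    fallback = np.zeros(n_feat, dtype=bool)

    qc_mat = qc.to_numpy()
    grid = all_orders.astype(float)[:, None]
    for i in range(n_feat):
        y = qc_mat[i]
        nonzero = y > 0
        ref = float(np.median(y[nonzero])) if nonzero.any() else 0.0
        reference[i] = ref
        if nonzero.sum() < min_qc or ref <= 0:
            fallback[i] = True
            continue
        y_rel = y[nonzero] / ref
        target = np.log(y_rel) if fit_log else y_rel
        svr = SVR(kernel="rbf", C=C, epsilon=epsilon, gamma=gamma)
        svr.fit(qc_orders[nonzero, None], target)
        pred = svr.predict(grid)
        if fit_log:
            pred = np.exp(pred)
        curves[i] = np.maximum(pred, CURVE_FLOOR)

    curve_df = pd.DataFrame(
        curves * np.where(reference > 0, reference, 1.0)[:, None],
        index=table.features.index,
        columns=pd.Index(all_orders, name="injection_order"),
    )
    # fallback features keep a flat curve at the reference (or 1 if ref == 0)
    return DriftModel(
        curves=curve_df,
        reference=pd.Series(np.where(reference > 0, reference, 1.0), index=table.features.index),
        fallback=pd.Series(fallback, index=table.features.index),
        hyperparameters={
            "kernel": "rbf",
            "C": C,
            "epsilon": epsilon,
            "gamma": gamma,
            "min_qc": min_qc,
            "fit_log": fit_log,
        },
    )


def correct_drift(table: PeakTable, model: DriftModel) -> PeakTable:
    """Rescale every sample by reference/fitted at its injection order.

    Corrected area = raw area * reference_f / fitted_f(order_i), applied to
    QC and study samples alike; zeros stay zero. Blank samples are carried
    through unchanged.
    """
    if not table.features.index.equals(model.curves.index):
        raise ValidationError("drift model features do not match the table")
    orders = table.samples["injection_order"].to_numpy(dtype=int)
    missing = set(orders) - set(model.curves.columns)
    if missing:
        raise ValidationError(f"injection orders {sorted(missing)} absent from drift model")

    fitted = model.fitted_at(orders)
    factor = model.reference.to_numpy()[:, None] / fitted
    corrected = table.intensities.to_numpy() * factor
    blank = (table.samples["sample_type"] == "blank").to_numpy()
    if blank.any():
        corrected[:, blank] = table.intensities.to_numpy()[:, blank]
    return table.with_intensities(corrected)


def drift_diagnostics(model: DriftModel, before: PeakTable, after: PeakTable) -> pd.DataFrame:
    """Per-feature table of fallback status and QC RSD before/after correction."""
    from .qc import compute_rsd

    rsd_before = compute_rsd(before).rsd
    rsd_after = compute_rsd(after).rsd
    return pd.DataFrame(
        {
            "fallback": model.fallback,
            "reference": model.reference,
            "qc_rsd_before": rsd_before.reindex(model.fallback.index),
            "qc_rsd_after": rsd_after.reindex(model.fallback.index),
        }
    )
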