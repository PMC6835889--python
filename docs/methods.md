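# Methods

This note documents the models and procedures implemented in `urinorm`,
the parameters that matter, what the synthetic cohort does and does not
emulate, and the numerical choices made where the design was open.

## Data model

A run is a features × samples matrix of non-negative peak areas plus
feature coordinates (m/z in Thomson, retention time in seconds) and
per-sample metadata: sample type (pooled QC, study, blank), 1-based
injection order (unique across the run), and for study samples a subject
id, a phase label (pre/post), the measured specific gravity (dimensionless,
constrained to (1.000, 1.100)) and optionally a creatinine peak area.
A stored 0 means "peak not detected", never "missing"; all filtering rules
are phrased on literal zeros. Two filters are provided: removal of features
with peak area 0 in ≥ 3 QC samples (run before drift correction), and
removal of features with all-zero QCs (mandatory before quotient
normalization, where the QC reference would be undefined).

## Signal-drift correction

Pooled QCs are identical in composition, so a feature's QC trajectory over
injection order traces its analytical drift. For each feature with at least
`min_qc = 5` nonzero QC areas we fit an ε-insensitive support-vector
regression (RBF kernel) of QC peak area against injection order, on areas
divided by the feature's nonzero-QC median so that the hyperparameters are
scale-free. Defaults: C = 1.0, ε = 0.05 (a tube of 5% of the QC median),
kernel scale from the median heuristic on pairwise QC injection-order
distances. The ε-insensitive loss is exactly zero anywhere inside the tube,
so the fitted curve can sit a full tube-width away from the truth where the
drift is steep (typically at the run edges); halving the conventional 10%
tube to 5% halves that boundary bias while remaining near the per-point QC
noise level (default noise CV 0.1), and on a noise-free linear 2:1 decay
the end-of-run fit lands within ~7% of the truth. Features with too few
usable QCs fall back to a constant curve at the QC median and are flagged.
Fitted curves are floored at 1% of the reference to prevent division
blow-ups; corrected area = raw × reference / fitted(order), applied to QC
and study samples alike (zeros stay zero, blanks pass through). Fitting on
log areas is available (`fit_log`) but defaults off; on multiplicative
drift of the magnitudes simulated here the two differ negligibly.

## Dilution normalization

All three corrections run after drift correction, so the QC-derived
references are themselves drift-free.

* **Creatinine**: divide every peak area by the sample's creatinine peak
  area, taken either from a designated feature (located by m/z 112.05132,
  rt 277.282 s with configurable windows of 10 ppm / ±15 s; ties resolved
  by smallest ppm, then smallest rt deviation) or from a metadata column
  (the manual-integration route). Creatinine must be positive everywhere.
* **Specific gravity**: PA_corr = PA × (SG_ref − 1)/(SG − 1). SG − 1
  approximates total dissolved solids, so dilute samples (SG < SG_ref) are
  scaled up and concentrated ones down. SG_ref defaults to the median SG
  of the study samples (≈ 1.020 for urine). Pooled QCs are normally not
  refractometered; under the default `assign_reference` policy they take
  SG = SG_ref and pass through bit-identical — which is why the QC RSD
  comparison between drift-corrected and SG-normalized states is an exact
  analytic zero.
* **Classical PQN**: per sample, the dilution estimate is the median of
  feature-wise quotients PA_f / ref_f over features detected in both the
  sample and the reference (mean QC spectrum); the sample is divided by it.
  At least 10 valid quotients are required per sample.
* **Midpoint-quotient PQN** (`pqn_paper`): per feature and sample,
  normalized = PA / ((PA + ref)/2), the two-element median read as the
  arithmetic mean of the pair. This maps all values into [0, 2), is not a
  per-sample common rescaling, and drives QC values toward 1 — so its QC
  RSD is artificially small. It is retained precisely because the
  evaluation suite must be able to expose this artifact; no per-sample
  factor is reported for it.

Creatinine, SG and classical PQN are common per-sample rescalings and
preserve within-sample feature ratios exactly; on noise-free data they
recover the true concentration profiles up to one global constant each
(classical PQN recovers the planted dilution factors exactly).

## Evaluation suite

**RSD.** Per feature, sample standard deviation (n − 1) of QC areas over
their mean; features with zero QC mean are excluded with a recorded reason
rather than given infinite RSD. Summaries report median, IQR and the count
strictly below the threshold (default 0.3, the field's reproducibility
convention; strict inequality). Method pairs are compared by a paired
t-test on per-feature RSD over the features defined in both states; when
all differences are identical (variance zero — e.g. the exact SVR-vs-SG
tie) the mean difference is reported and the t-test is flagged degenerate
instead of emitting an undefined statistic.

**PCA dispersion.** PCA on QC + study samples (centered; unit-variance
scaling by default, Pareto and none available; constant features dropped).
The dispersion ratio is mean QC distance to the QC centroid over mean study
distance to the study centroid in the first 2 components — a quantitative
stand-in for the visual "tight QC cluster" criterion; ~1 means QCs scatter
like study samples, smaller is better.

**OPLS-DA.** Class encoded pre = −1, post = +1; predictors centered and
unit-variance scaled by default. For a single response the orthogonal
filter is deterministic: w ∝ X'y; p = X't/(t't) for t = Xw; the component
of p orthogonal to w is normalized, its scores and loadings deflated from
X; repeated `n_ortho` times (default 1). The predictive component is a
one-component PLS fit on the filtered matrix, so `n_ortho = 0` reduces
exactly to PLS1-DA (verified against scikit-learn's PLSRegression).
Orthogonal scores are exactly uncorrelated with the encoded class. R²X
counts all fitted components; VIP uses the predictive component only
(selection targets class-discriminating features), reducing to
√p · |w_j| with Σ VIP² = p. Q² = 1 − PRESS/TSS over 7 stratified folds,
preprocessing refit inside each training fold, deterministic given a seed.
The permutation test refits the full pipeline under uniformly shuffled
labels (default 200 iterations) and records R²Y/Q² against |corr(permuted,
original labels)|; R² and Q² intercepts come from straight-line fits
anchored by the unpermuted model at correlation 1. Note that the null Q²
level depends on the data shape: in p ≫ n regimes an overfit predictive
component makes confidently wrong CV predictions and the null Q² (hence
the intercept) is strongly negative, while in well-determined regimes
(n ≫ p) it concentrates near 0. Intercepts should be compared against a
matched null, not against a universal band.

**Differential testing.** Per feature, a two-sided Wilcoxon signed-rank
test on post − pre differences across subjects. Zero differences are
dropped before ranking (signed-rank convention); ties are mid-ranked; the
exact null distribution is used for ≤ 25 untied nonzero pairs and the
normal approximation with continuity correction above; features with < 5
usable pairs are skipped with a reason, and all-zero features return p = 1
flagged degenerate. Tests run on normalized areas without log transform —
the test is invariant to monotone per-feature transforms, so this is
inconsequential. Benjamini–Hochberg adjustment is computed within each
normalization state separately; candidate biomarkers satisfy the strict
conjunction VIP > 1 and q < 0.05.

## Synthetic cohort

The generator emulates the paired periconceptional design: `n_subjects`
(default 45) × 2 phases = 90 study injections in randomized order, 3
lead-in pooled QCs and one QC after every 6 study injections (18 QCs
total). Study peak area for feature f in sample i is

    base_f × phase_effect_f(i) × d_i × drift_f(order_i) × noise,

with log-normal base abundances (median 10⁴, log-sd 1.2), log-normal
dilution d_i (log-sd `dilution_sigma` = 0.4, geometric mean exactly 1),
per-feature smooth linear-to-quadratic drift with random sign and
amplitude up to `drift_amplitude` = 0.3 of the run, and multiplicative
log-normal noise with CV `noise_cv` = 0.1. QCs are the dilution-free mean
study concentration profile times drift and noise. A fraction
`effect_fraction` = 0.1 of features receive a ±`effect_log2fc` = 1 log2
fold change in the post phase; the designated creatinine feature (placed
at its known HILIC coordinates, high abundance) shifts by
`creatinine_phase_log2fc` = −0.5, reproducing the falling creatinine
excretion of early pregnancy. Measured specific gravity is
1 + 0.020 × d_i × (subject solute load / mean load); per-subject solute
load is uniform by default (`solute_load_sigma` = 0), anchoring the median
SG at 1.020 and making SG an exact readout of dilution. The lowest
`zero_rate` = 0.01 quantile of intensities is recorded as 0 (non-detects).
Everything derives from one seed; generation is bit-reproducible.

What the generator does **not** emulate: chromatographic peak shapes,
adducts/isotopes, batch effects across plates, retention-time drift,
heteroscedastic detector noise, correlated metabolite modules, or
subject-level covariates (age, BMI, diet) that drive real creatinine
variability. Passing tests therefore demonstrate correctness of the
algorithms under the stated multiplicative model, not performance on any
particular real cohort; in particular the SG–dilution link is exact here
by construction, whereas in real urine SG is a noisy, load-confounded
proxy.

## Problem sizes and determinism

The analysis drivers use the full default cohort (2000 features, 108
injections, 50 permutation iterations in the validation scatter); the test
suite uses 200–600-feature cohorts and 20-seed Monte-Carlo loops, sizes at
which every distributional claim tested is already stable. The pipeline
spawns per-stage seeds from one master seed via `numpy.random.SeedSequence`,
so reports are byte-identical across runs and invariant to the order
methods are listed in the configuration.

## Known limitations

* Drift correction assumes drift is smooth in injection order and shared
  between QC and study samples; step changes (e.g. a source clean mid-run)
  are not modeled and will be smoothed over.
* The SVR tube leaves a residual bias of up to ε × reference where drift
  is steep at the run boundaries.
* OPLS-DA is two-class only, with a fixed component structure (1
  predictive + `n_ortho` orthogonal); no automatic component selection.
* Creatinine lookup windows (10 ppm, ±15 s) are sensible defaults for
  QToF data, not instrument-calibrated values.
* The midpoint-quotient PQN variant is intentionally reported without a
  per-sample factor; treating its RSD as comparable to other methods'
  is exactly the evaluation artifact the suite is designed to expose.
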