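import numpy as np
import pandas as pd
import pytest
from sklearn.cross_decomposition import PLSRegression

from urinorm import (
    ValidationError,
    opls_fit,
    opls_q2,
    permutation_test,
    vip_scores,
)
from urinorm.opls import _fit_core, _predict_core, _preprocess

from conftest import make_table


def class_table(X, labels, seed=0):
    """Wrap a samples-x-features matrix and ±1 labels as a study-only PeakTable."""
    phases = ["post" if y > 0 else "pre" for y in labels]
    subjects = [f"u{i}" for i in range(len(labels))]
    return make_table(
        np.abs(X).T + 1.0 if (X < 0).any() else X.T,
        ["study"] * len(labels),
        subject_id=subjects,
        phase=phases,
    )


def gaussian_classes(n_per_class=20, p=50, n_informative=10, delta=5.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n_per_class, p))
    X[:n_per_class, :n_informative] += delta
    y = np.r_[np.ones(n_per_class), -np.ones(n_per_class)]
    return X, y


class TestFit:
    def test_single_feature_vip_is_one(self):
        X, y = gaussian_classes(n_per_class=6, p=1, n_informative=1, delta=3.0)
        t = class_table(X, y)
        model = opls_fit(t, rsd_filter=None, n_ortho=0)
        assert vip_scores(model)["F1"] == pytest.approx(1.0)

    def test_separated_classes_high_r2y(self):
        X, y = gaussian_classes(seed=1)
        model = opls_fit(class_table(X, y), n_ortho=1)
        assert model.r2y >= 0.9
        # the plain one-component PLS fit bounds OPLS R2Y from below
        Xs, _, _ = _preprocess(np.abs(X) + 1.0, "uv")
        pls_core = _fit_core(Xs, y, 0)
        assert model.r2y >= pls_core["r2y"] - 1e-9

    def test_null_labels_low_predictive_share(self):
        """Pure-noise labels: the predictive component captures little X variance."""
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = rng.normal(size=(40, 100))
            y = np.r_[np.ones(20), -np.ones(20)]
            model = opls_fit(class_table(X, y, seed), n_ortho=1)
            Xs, _, _ = _preprocess(np.abs(X) + 1.0, "uv")
            core = _fit_core(Xs, y, 1)
            fracs.append(core["ss_pred_x"] / core["ss_x0"] / max(core["r2x"], 1e-12))
        assert np.mean(fracs) < 0.75  # predictive part is a minor share of fitted variance

    def test_single_class_errors(self):
        X, _ = gaussian_classes(n_per_class=5, p=10)
        t = class_table(X, np.ones(10))
        with pytest.raises(ValidationError, match="class|fewer than 4"):
            opls_fit(t)

    def test_vip_normalization_every_fit(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(12, 17))
            y = np.r_[np.ones(6), -np.ones(6)]
            for n_ortho in (0, 1, 2):
                model = opls_fit(class_table(X, y, seed), n_ortho=n_ortho)
                vip = vip_scores(model).to_numpy()
                assert abs((vip**2).sum() - 17) < 1e-8

    def test_orthogonal_scores_uncorrelated_with_class(self):
        X, y = gaussian_classes(seed=3)
        model = opls_fit(class_table(X, y), n_ortho=2)
        for t_o in model.ortho_scores:
            assert abs(np.corrcoef(t_o, y)[0, 1]) < 1e-8

    def test_r2x_nondecreasing_in_components(self):
        X, y = gaussian_classes(seed=4)
        t = class_table(X, y)
        r2x = [opls_fit(t, n_ortho=k).r2x for k in range(4)]
        assert all(b >= a - 1e-12 for a, b in zip(r2x, r2x[1:]))

    def test_informative_features_get_high_vip(self):
        X, y = gaussian_classes(n_per_class=20, p=50, n_informative=10, delta=2.0, seed=5)
        model = opls_fit(class_table(X, y), n_ortho=1)
        vip = vip_scores(model)
        informative = vip.iloc[:10].mean()
        noise = vip.iloc[10:].mean()
        assert informative > 1.0 > noise


class TestPlsEquivalence:
    def test_n_ortho_zero_equals_one_component_pls(self):
        """Oracle: with no orthogonal filtering the fit is plain PLS1-DA."""
        rng = np.random.default_rng(0)
        for rep in range(20):
            X = rng.normal(size=(10, 30))
            y = rng.permutation(np.r_[np.ones(5), -np.ones(5)])
            Xs, _, _ = _preprocess(X, "uv")
            core = _fit_core(Xs, y, 0)
            ours = _predict_core(core, Xs)
            oracle = PLSRegression(n_components=1, scale=True).fit(X, y).predict(X).ravel()
            assert np.allclose(ours, oracle, atol=1e-8)


class TestQ2:
    def test_separable_classes_high_q2(self):
        X, y = gaussian_classes(seed=6)
        t = class_table(X, y)
        q2 = opls_q2(t, t.features.index, seed=0)
        assert q2 >= 0.8

    def test_permuted_labels_low_q2(self):
        """Null Q2 stays at or below ~0 across seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            X = rng.normal(size=(40, 100))
            y = np.r_[np.ones(20), -np.ones(20)]
            t = class_table(X, y, seed)
            q2 = opls_q2(t, t.features.index, seed=seed)
            hits += q2 <= 0.1
        assert hits >= 18

    def test_duplicating_samples_keeps_q2_sign(self):
        X, y = gaussian_classes(n_per_class=10, p=20, seed=7)
        t1 = class_table(X, y)
        q2_single = opls_q2(t1, t1.features.index, seed=1)
        X2 = np.vstack([X, X])
        y2 = np.r_[y, y]
        t2 = make_table(
            np.abs(X2).T + 1.0, ["study"] * 40,
            subject_id=[f"u{i}" for i in range(40)],
            phase=["post" if v > 0 else "pre" for v in y2],
        )
        q2_double = opls_q2(t2, t2.features.index, seed=1)
        assert np.sign(q2_single) == np.sign(q2_double)

    def test_deterministic_given_seed(self):
        X, y = gaussian_classes(seed=8)
        t = class_table(X, y)
        assert opls_q2(t, t.features.index, seed=3) == opls_q2(t, t.features.index, seed=3)

    def test_fold_without_both_classes_errors(self):
        X, y = gaussian_classes(n_per_class=5, p=10, seed=9)
        t = class_table(X, y)
        with pytest.raises(ValidationError, match="folds"):
            opls_q2(t, t.features.index, n_folds=7)  # only 5 per class


class TestPermutation:
    def test_identity_anchor_and_strong_effect(self):
        X, y = gaussian_classes(n_per_class=12, p=30, delta=4.0, seed=10)
        t = class_table(X, y)
        res = permutation_test(t, t.features.index, n_permutations=30, seed=0)
        # anchored by the original model at correlation 1
        assert res.q2_original == opls_q2(t, t.features.index, seed=res.seed)
        low_corr = res.label_correlation < 0.3
        assert res.q2_original > res.q2_permuted[low_corr].max()

    def test_null_data_q2_intercept_near_zero(self):
        # well-determined regime (n >> p): null Q2 concentrates near 0,
        # so the extrapolated intercept stays in a narrow band around it
        rng = np.random.default_rng(11)
        X = rng.normal(size=(80, 8))
        y = np.r_[np.ones(40), -np.ones(40)]
        t = class_table(X, y, 11)
        res = permutation_test(t, t.features.index, n_permutations=40, seed=2)
        assert -0.2 <= res.q2_intercept <= 0.2

    def test_too_few_permutations_errors(self):
        X, y = gaussian_classes(n_per_class=6, p=10)
        t = class_table(X, y)
        with pytest.raises(ValidationError, match="20"):
            permutation_test(t, t.features.index, n_permutations=5)
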