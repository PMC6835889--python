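import numpy as np
import pandas as pd
import pytest

from urinorm import (
    SgParams,
    SyntheticConfig,
    ValidationError,
    default_sg_ref,
    generate,
    normalize_creatinine,
    normalize_pqn_classical,
    normalize_pqn_paper,
    normalize_specific_gravity,
    truth_concentrations,
)

from conftest import make_table


class TestCreatinine:
    def test_division_by_sample_creatinine(self):
        t = make_table(
            [[500.0, 300.0], [250.0, 100.0]],
            ["QC", "QC"],
            creatinine_pa=[250.0, 100.0],
        )
        res = normalize_creatinine(t, "creatinine_pa")
        assert res.table.intensities.loc["F1", "QC1"] == pytest.approx(2.0)
        assert res.table.intensities.loc["F2"].tolist() == [1.0, 1.0]

    def test_feature_source_maps_creatinine_to_one(self):
        t = make_table([[500.0, 300.0], [250.0, 100.0]], ["QC", "QC"])
        res = normalize_creatinine(t, "F2")
        assert (res.table.intensities.loc["F2"] == 1.0).all()
        assert res.provenance["source_kind"] == "feature"

    def test_common_creatinine_is_global_rescale(self):
        t = make_table([[5.0, 7.0], [1.0, 3.0]], ["QC", "QC"], creatinine_pa=[4.0, 4.0])
        res = normalize_creatinine(t)
        assert np.allclose(res.table.intensities.to_numpy(), t.intensities.to_numpy() / 4.0)

    def test_zero_or_missing_creatinine_lists_samples(self):
        t = make_table([[1.0, 1.0]], ["QC", "QC"], creatinine_pa=[0.0, 5.0])
        with pytest.raises(ValidationError, match="QC1"):
            normalize_creatinine(t)

    def test_phase_shifted_creatinine_confounds_normalization(self):
        """A pre->post fall in creatinine inflates post-phase normalized areas."""
        cfg = SyntheticConfig(
            n_subjects=20, n_features=60, seed=8, effect_fraction=0.0,
            creatinine_phase_log2fc=-0.5, noise_cv=0.0, drift_amplitude=0.0,
            zero_rate=0.0,
        )
        table, truth = generate(cfg)
        res = normalize_creatinine(table, truth.creatinine_feature_id)
        study = table.samples[table.samples["sample_type"] == "study"]
        pre = study.index[study["phase"] == "pre"]
        post = study.index[study["phase"] == "post"]
        other = table.features.index.drop(truth.creatinine_feature_id)
        shift = np.log2(
            res.table.intensities.loc[other, post].mean(axis=1)
            / res.table.intensities.loc[other, pre].mean(axis=1)
        )
        assert np.allclose(shift, 0.5, atol=0.05)


class TestSpecificGravity:
    def test_worked_identities(self):
        """SG = SGref is the identity; 1.010 doubles; 1.040 halves (vs 1.020)."""
        t = make_table(
            [[100.0, 100.0, 100.0]],
            ["study"] * 3,
            specific_gravity=[1.020, 1.010, 1.040],
        )
        res = normalize_specific_gravity(t, SgParams(sg_ref=1.020))
        out = res.table.intensities.loc["F1"]
        assert out.tolist() == pytest.approx([100.0, 200.0, 50.0])
        assert res.per_sample_factor.tolist() == pytest.approx([1.0, 2.0, 0.5])

    def test_qcs_assigned_reference_pass_through_bit_identical(self, default_run):
        table, _ = default_run
        res = normalize_specific_gravity(table, SgParams(sg_ref=1.020))
        qc = table.qc_ids
        assert np.array_equal(
            res.table.intensities[qc].to_numpy(), table.intensities[qc].to_numpy()
        )

    def test_use_measured_requires_sg_everywhere(self, default_run):
        table, _ = default_run  # QCs carry no SG measurement
        with pytest.raises(ValidationError, match="missing"):
            normalize_specific_gravity(table, SgParams(sg_ref=1.020, qc_policy="use_measured"))

    def test_sg_at_or_below_one_errors(self):
        t = make_table([[1.0, 1.0]], ["study", "study"], specific_gravity=[1.02, 1.01])
        t.samples.loc["study2", "specific_gravity"] = 1.0  # bypass init check
        with pytest.raises(ValidationError, match="study2"):
            normalize_specific_gravity(t, SgParams(sg_ref=1.020))

    def test_default_sg_ref_is_study_median(self):
        t = make_table(
            [[1.0] * 4], ["QC", "study", "study", "study"],
            specific_gravity=[np.nan, 1.010, 1.020, 1.030],
        )
        assert default_sg_ref(t) == pytest.approx(1.020)
        single = make_table([[1.0]], ["study"], specific_gravity=[1.015])
        assert default_sg_ref(single) == pytest.approx(1.015)

    def test_default_sg_ref_near_urine_reference(self, default_run):
        table, _ = default_run
        assert abs(default_sg_ref(table) - 1.020) < 0.002


class TestPqnPaper:
    def test_qc_values_collapse_toward_one(self):
        t = make_table([[100.0, 100.0, 100.0, 40.0]], ["QC", "QC", "QC", "study"])
        res = normalize_pqn_paper(t)
        assert (res.table.intensities.loc["F1", t.qc_ids] == 1.0).all()
        assert res.per_sample_factor is None

    def test_midpoint_quotient_arithmetic(self):
        # ref (QC mean) = 50; 150 / ((150 + 50)/2) = 1.5
        t = make_table([[50.0, 50.0, 50.0, 150.0]], ["QC", "QC", "QC", "study"])
        res = normalize_pqn_paper(t)
        assert res.table.intensities.loc["F1", "study4"] == pytest.approx(1.5)

    def test_zero_stays_zero_and_bounded(self, default_run):
        from urinorm import filter_all_zero_qc_features

        table, _ = default_run
        filtered, _ = filter_all_zero_qc_features(table)
        res = normalize_pqn_paper(filtered)
        out = res.table.intensities.to_numpy()
        zeros = filtered.intensities.to_numpy() == 0
        assert (out[zeros] == 0).all()
        assert (out >= 0).all() and (out < 2).all()

    def test_all_zero_qc_feature_directs_to_filter(self):
        t = make_table([[0.0, 0.0, 0.0, 5.0], [1.0, 1.0, 1.0, 1.0]], ["QC", "QC", "QC", "study"])
        with pytest.raises(ValidationError, match="filter_all_zero_qc"):
            normalize_pqn_paper(t)


class TestPqnClassical:
    def test_uniform_double_dilution_removed_exactly(self):
        rng = np.random.default_rng(0)
        ref = rng.uniform(10, 100, 12)
        x = np.column_stack([ref, ref, ref, 2.0 * ref])
        t = make_table(x, ["QC", "QC", "QC", "study"])
        res = normalize_pqn_classical(t)
        assert res.provenance["dilution_estimates"]["study4"] == pytest.approx(2.0)
        assert np.allclose(res.table.intensities["study4"].to_numpy(), ref)

    def test_qc_equal_to_reference_is_identity(self):
        ref = np.linspace(10, 100, 15)
        x = np.column_stack([ref, ref, ref])
        t = make_table(x, ["QC", "QC", "QC"])
        res = normalize_pqn_classical(t)
        assert np.allclose(res.provenance["dilution_estimates"].to_numpy(), 1.0)
        assert np.allclose(res.table.intensities.to_numpy(), x)

    def test_too_few_quotients_errors(self):
        x = np.ones((5, 4))
        x[:, 3] = 0.0
        x[0, 3] = 1.0
        t = make_table(x, ["QC", "QC", "QC", "study"])
        with pytest.raises(ValidationError, match="quotients"):
            normalize_pqn_classical(t)

    def test_recovers_true_dilution_exactly(self, clean_run):
        table, truth = clean_run
        res = normalize_pqn_classical(table)
        est = res.provenance["dilution_estimates"][truth.dilution.index]
        assert np.max(np.abs(est / truth.dilution - 1.0)) < 0.01


class TestRecovery:
    """All per-sample rescalings recover truth up to one global constant."""

    @pytest.mark.parametrize("method", ["creatinine", "specific_gravity", "pqn_classical"])
    def test_recovery_up_to_global_constant(self, method):
        cfg = SyntheticConfig(
            n_subjects=20, n_features=80, seed=13, noise_cv=0.0,
            drift_amplitude=0.0, zero_rate=0.0, creatinine_phase_log2fc=0.0,
        )
        table, truth = generate(cfg)
        if method == "creatinine":
            res = normalize_creatinine(table, truth.creatinine_feature_id)
        elif method == "specific_gravity":
            res = normalize_specific_gravity(table, SgParams(sg_ref=1.020))
        else:
            res = normalize_pqn_classical(table)
        study = table.samples[table.samples["sample_type"] == "study"].index
        consts = []
        for sid in study:
            ratio = res.table.intensities[sid] / truth_concentrations(truth, sid)
            assert np.allclose(ratio, ratio.iloc[0])  # constant within sample
            consts.append(ratio.iloc[0])
        assert np.allclose(consts, consts[0], rtol=1e-9)  # one constant across samples

    @pytest.mark.parametrize("method", ["creatinine", "specific_gravity", "pqn_classical"])
    def test_within_sample_ratios_preserved(self, default_run, method):
        from urinorm import filter_all_zero_qc_features

        table, truth = default_run
        table, _ = filter_all_zero_qc_features(table)
        positive = table.intensities.to_numpy() > 0
        if method == "creatinine":
            res = normalize_creatinine(table, truth.creatinine_feature_id)
        elif method == "specific_gravity":
            res = normalize_specific_gravity(table, SgParams(sg_ref=1.020))
        else:
            res = normalize_pqn_classical(table)
        before = table.intensities.to_numpy()
        after = res.table.intensities.to_numpy()
        j = 4  # any sample
        rows = np.flatnonzero(positive[:, j])[:20]
        r_before = before[rows[:-1], j] / before[rows[1:], j]
        r_after = after[rows[:-1], j] / after[rows[1:], j]
        assert np.allclose(r_before, r_after, rtol=1e-12)
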