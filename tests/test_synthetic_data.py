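"""Generators: noise model, regulator kinetics, IAP synthesis, planted matrices."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bsignal as b
from bsignal.synthetic_data import cluster_templates

from .conftest import KINASE_GRID
from .oracles import rk4_kinase

GRID6 = np.array([0.0, 15.0, 30.0, 45.0, 60.0, 90.0])


class TestTrueKinaseTimecourse:
    def test_no_feedback_regime_equals_zeroed_parameters(self, p0, feedback_inputs):
        from dataclasses import replace

        pf, nf = feedback_inputs
        a = b.generate_true_kinase_timecourse(p0, pf, nf, regime="no_feedback", grid=KINASE_GRID)
        c = b.generate_true_kinase_timecourse(replace(p0, k4=0.0, k5=0.0), pf, nf, regime="full", grid=KINASE_GRID)
        assert np.array_equal(a.value, c.value)

    def test_no_signal_gives_zero_trajectory(self, p0, feedback_inputs):
        from dataclasses import replace

        pf, nf = feedback_inputs
        tc = b.generate_true_kinase_timecourse(replace(p0, k1=0.0), pf, nf, regime="no_feedback", grid=KINASE_GRID)
        assert np.all(tc.value == 0.0)
        assert np.all(tc.sd == 0.0)

    def test_matches_fine_step_oracle(self, p0, feedback_inputs):
        pf, nf = feedback_inputs
        tc = b.generate_true_kinase_timecourse(p0, pf, nf, regime="full", grid=KINASE_GRID)
        times, active = rk4_kinase(p0, pf, nf, dt=0.001)
        assert np.max(np.abs(tc.value - np.interp(KINASE_GRID, times, active))) < 1e-4

    def test_invalid_regime_lists_valid_names(self, p0, feedback_inputs):
        pf, nf = feedback_inputs
        with pytest.raises(ValueError, match="full, no_positive, no_feedback"):
            b.generate_true_kinase_timecourse(p0, pf, nf, regime="wt", grid=KINASE_GRID)


class TestMeasurementNoise:
    def test_zero_cv_is_identity_with_zero_sd(self, clean_datasets):
        tc = clean_datasets["full"]
        noisy = b.add_measurement_noise(tc, b.NoiseSpec(cv=0.0, n_replicates=2, seed=1))
        assert np.array_equal(noisy.value, tc.value)
        assert np.all(noisy.sd == 0.0)

    def test_seeded_determinism(self, clean_datasets):
        tc = clean_datasets["full"]
        spec = b.NoiseSpec(cv=0.1, n_replicates=2, seed=42)
        a, c = b.add_measurement_noise(tc, spec), b.add_measurement_noise(tc, spec)
        assert np.array_equal(a.value, c.value) and np.array_equal(a.sd, c.sd)

    def test_large_replicate_mean_near_truth(self):
        tc = b.TimeCourse(time=np.array([0.0, 10.0]), value=np.array([1.0, 1.0]))
        noisy = b.add_measurement_noise(tc, b.NoiseSpec(cv=0.1, n_replicates=1000, seed=7))
        se = 0.1 / np.sqrt(1000)
        assert np.all(np.abs(noisy.value - 1.0) < 3 * se)

    def test_negative_cv_rejected(self):
        with pytest.raises(ValueError, match="cv"):
            b.NoiseSpec(cv=-0.1)

    def test_noisy_input_rejected(self, clean_datasets):
        noisy = b.add_measurement_noise(clean_datasets["full"], b.NoiseSpec(cv=0.1, seed=0))
        with pytest.raises(ValueError, match="noiseless"):
            b.add_measurement_noise(noisy, b.NoiseSpec(cv=0.1, seed=1))


class TestRegulatorKinetics:
    @given(peak=st.floats(10.0, 40.0), decay=st.floats(0.005, 0.02))
    @settings(max_examples=30, deadline=None)
    def test_normalized_to_unit_maximum_and_zero_start(self, peak, decay):
        tc = b.generate_regulator_kinetics(peak, decay, GRID6)
        assert tc.value.max() == pytest.approx(1.0)
        assert tc.value[0] == 0.0
        assert np.all(tc.value >= 0.0)

    def test_peak_lands_at_nearest_gridpoint(self):
        grid = np.arange(0.0, 121.0, 15.0)
        tc = b.generate_regulator_kinetics(30.0, 0.02, grid)
        assert grid[np.argmax(tc.value)] == 30.0

    def test_invalid_peak_rejected(self):
        with pytest.raises(ValueError, match="peak_time"):
            b.generate_regulator_kinetics(-5.0, 0.02, GRID6)


class TestIapSynthesis:
    def test_zero_rate_means_nothing_synthesized(self):
        rate = b.TimeCourse(time=GRID6, value=np.zeros_like(GRID6))
        _, _, newly = b.generate_iap_synthesis(rate, degradation=0.02, grid=GRID6)
        assert np.all(newly.value == 0.0)

    def test_linear_accumulation_without_degradation(self):
        r = 0.01
        rate = b.TimeCourse(time=GRID6, value=np.full_like(GRID6, r))
        _, _, newly = b.generate_iap_synthesis(rate, degradation=0.0, grid=GRID6)
        assert np.allclose(newly.value, r * GRID6)

    def test_chx_branch_decays_and_difference_is_monotone(self):
        rate = b.generate_regulator_kinetics(30.0, 0.02, GRID6)
        untreated, chx, newly = b.generate_iap_synthesis(rate, degradation=0.01, grid=GRID6, initial_level=1.0)
        assert np.all(np.diff(chx.value) < 0)  # pure decay
        assert np.all(newly.value >= 0.0)
        assert np.allclose(newly.value, untreated.value - chx.value)

    def test_no_degradation_difference_never_decreases(self):
        rate = b.generate_regulator_kinetics(20.0, 0.01, GRID6)
        _, _, newly = b.generate_iap_synthesis(rate, degradation=0.0, grid=GRID6)
        assert np.all(np.diff(newly.value) >= 0.0)

    def test_mismatched_grid_rejected(self):
        rate = b.TimeCourse(time=GRID6, value=np.ones_like(GRID6))
        with pytest.raises(ValueError, match="grid"):
            b.generate_iap_synthesis(rate, degradation=0.0, grid=GRID6[:-1])


class TestExpressionMatrix:
    def test_shapes_labels_and_determinism(self):
        spec = b.PlantedClusterSpec(n_clusters=4, genes_per_cluster=10, n_null_genes=20, seed=5)
        noise = b.NoiseSpec(cv=0.1, n_replicates=2, seed=5)
        m1, l1 = b.generate_expression_matrix(spec, noise)
        m2, l2 = b.generate_expression_matrix(spec, noise)
        assert m1.df.shape == (60, 12)
        assert l1.value_counts().to_dict() == {0: 20, 1: 10, 2: 10, 3: 10, 4: 10}
        assert m1.df.equals(m2.df) and l1.equals(l2)

    def test_null_genes_time_invariant_in_expectation(self):
        spec = b.PlantedClusterSpec(n_clusters=2, genes_per_cluster=5, n_null_genes=400, seed=2)
        matrix, labels = b.generate_expression_matrix(spec, b.NoiseSpec(cv=0.1, n_replicates=2, seed=2))
        prof = matrix.mean_profiles("WT-BCR", genes=labels.index[labels == 0])
        grand = prof.to_numpy().mean(axis=0)  # average over 400 nulls
        assert np.all(np.abs(grand - spec.baseline) < 0.05)

    def test_templates_start_at_zero_with_unit_peak(self):
        t = cluster_templates(8, GRID6)
        assert t.shape == (8, 6)
        assert np.all(t[:, 0] == 0.0)
        assert np.allclose(np.abs(t).max(axis=1), 1.0)

    def test_tsv_round_trip(self, tmp_path):
        spec = b.PlantedClusterSpec(n_clusters=2, genes_per_cluster=4, n_null_genes=4, seed=1)
        matrix, _ = b.generate_expression_matrix(spec, b.NoiseSpec(cv=0.1, n_replicates=2, seed=1))
        path = tmp_path / "expr.tsv"
        matrix.to_tsv(path)
        back = b.ExpressionMatrix.from_tsv(path)
        assert np.allclose(back.df.to_numpy(), matrix.df.to_numpy())
        assert back.conditions == ["WT-BCR"]
        assert np.array_equal(back.timepoints("WT-BCR"), np.asarray(GRID6))
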