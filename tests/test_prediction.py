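"""Measurement-augmented models and conditional shape prediction."""

import numpy as np
import pytest

import proxhum as px
from proxhum.errors import DataError, MeasurementError
from proxhum.prediction import conditional_mean_oracle, load_augmented_model, save_augmented_model
from proxhum.ssm import pca_from_vectors


@pytest.fixture(scope="module")
def augmented(measured_population):
    aligned, latents, sets = measured_population
    model = px.build_augmented_ssm(aligned, sets, ("max_length", "head_radius"))
    return model, aligned, latents, sets


class TestBuildAugmented:
    def test_mean_block_is_zero(self, augmented):
        model, *_ = augmented
        # standardized measurements have zero mean by construction
        assert np.abs(model.measurement_block(model.mean_vector)).max() < 1e-10

    def test_zero_variance_measurement_keeps_shape_modes(self, humerus):
        rng = np.random.default_rng(2)
        shapes = humerus.vertices[None] + rng.normal(
            0, 2.0, (8, humerus.n_vertices, 3))
        sset = px.CorrespondedShapeSet(humerus.faces, shapes)
        plain = px.build_ssm(sset)
        sets = [px.MeasurementSet(max_length=300.0) for _ in range(8)]
        with pytest.warns(UserWarning, match="zero-variance"):
            aug = px.build_augmented_ssm(sset, sets, ("max_length",))
        k = min(plain.n_modes, aug.n_modes)
        shape_modes = aug.modes[:3 * aug.n_vertices, :k]
        dots = np.abs(np.einsum("ij,ij->j", plain.modes[:, :k], shape_modes))
        assert np.all(dots > 1 - 1e-9)

    def test_training_measurements_reconstructed_at_full_rank(self):
        rng = np.random.default_rng(4)
        m, n_v = 8, 10
        X = rng.standard_normal((m, n_v, 3)) * 10
        sets = [px.MeasurementSet(max_length=float(300 + 20 * rng.standard_normal()),
                                  head_radius=float(24 + 2 * rng.standard_normal()))
                for _ in range(m)]
        sset = px.CorrespondedShapeSet([[0, 1, 2], [1, 2, 3], [2, 3, 4]], X)
        model = px.build_augmented_ssm(sset, sets, ("max_length", "head_radius"))
        assert model.n_modes == m - 1  # full rank: nothing truncated
        M = np.stack([s.values_for(model.measurement_names) for s in sets])
        Z = np.hstack([X.reshape(m, -1),
                       model.measurement_scale * (M - model.measurement_means)
                       / model.measurement_sds])
        coeff = (Z - model.mean_vector) @ model.modes
        recon = model.mean_vector + coeff @ model.modes.T
        assert np.abs(recon - Z).max() < 1e-8

    def test_missing_measurement_is_data_error(self, measured_population):
        aligned, _, sets = measured_population
        broken = list(sets)
        broken[0] = px.MeasurementSet(max_length=300.0)  # radius missing
        with pytest.raises(DataError):
            px.build_augmented_ssm(aligned, broken, ("max_length", "head_radius"))


class TestPredict:
    def test_mean_targets_give_mean_shape(self, augmented):
        model, *_ = augmented
        targets = px.MeasurementSet(
            max_length=float(model.measurement_means[0]),
            head_radius=float(model.measurement_means[1]))
        res = px.predict_from_measurements(model, targets)
        mean_shape = model.shape_block(model.mean_vector).reshape(-1, 3)
        assert np.abs(res.predicted_mesh.vertices - mean_shape).max() < 1e-6
        assert not res.out_of_range

    def test_in_sample_conditioning_is_exact(self, augmented):
        model, _, _, sets = augmented
        res = px.predict_from_measurements(model, px.MeasurementSet(
            max_length=sets[2].max_length, head_radius=sets[2].head_radius))
        assert res.conditioning_residual < 1e-6

    def test_schur_complement_oracle(self):
        # small instance: shape block of 20 vertices + 2 measurements
        rng = np.random.default_rng(7)
        m, n_v, q = 12, 20, 2
        latent = rng.standard_normal((m, 3))
        basis = rng.standard_normal((3, n_v * 3))
        X = 5 + latent @ basis + 0.1 * rng.standard_normal((m, n_v * 3))
        meas = np.column_stack([
            200 + 30 * latent[:, 0] + rng.normal(0, 0.5, m),
            20 + 2 * latent[:, 1] + rng.normal(0, 0.1, m)])
        shapes = px.CorrespondedShapeSet(
            [[0, 1, 2], [1, 2, 3], [2, 3, 4]], X.reshape(m, n_v, 3))
        sets = [px.MeasurementSet(max_length=a, head_radius=b)
                for a, b in meas]
        model = px.build_augmented_ssm(shapes, sets,
                                       ("max_length", "head_radius"))
        targets = np.array([215.0, 21.3])
        res = px.predict_from_measurements(model, px.MeasurementSet(
            max_length=targets[0], head_radius=targets[1]))
        # oracle operates on the raw standardized training vectors
        m_sd = meas.std(axis=0, ddof=1)
        m_mean = meas.mean(axis=0)
        Z = np.hstack([X, model.measurement_scale * (meas - m_mean) / m_sd])
        z_targets = model.measurement_scale * (targets - m_mean) / m_sd
        expected = conditional_mean_oracle(Z, q, z_targets)
        assert np.abs(res.predicted_mesh.vertices.ravel() - expected).max() < 1e-6

    def test_scale_policy_insensitivity(self, measured_population):
        # conditioning constrains the block exactly, so the balance factor
        # should not matter over orders of magnitude
        aligned, _, sets = measured_population
        targets = px.MeasurementSet(max_length=315.0, head_radius=23.5)
        preds = []
        for scale in (0.1, 10.0, 1000.0):
            model = px.build_augmented_ssm(aligned, sets,
                                           ("max_length", "head_radius"),
                                           scale_policy=scale)
            preds.append(px.predict_from_measurements(model, targets)
                         .predicted_mesh.vertices)
        assert np.abs(preds[0] - preds[1]).max() < 1e-4
        assert np.abs(preds[1] - preds[2]).max() < 1e-4

    def test_deterministic_bitwise(self, augmented):
        model, *_ = augmented
        targets = px.MeasurementSet(max_length=312.0, head_radius=24.2)
        a = px.predict_from_measurements(model, targets)
        b = px.predict_from_measurements(model, targets)
        assert np.array_equal(a.predicted_mesh.vertices,
                              b.predicted_mesh.vertices)

    def test_out_of_range_flag(self, augmented):
        model, *_ = augmented
        wild = px.MeasurementSet(max_length=500.0, head_radius=24.0)
        assert px.predict_from_measurements(model, wild).out_of_range

    def test_wrong_target_set_rejected(self, augmented):
        model, *_ = augmented
        with pytest.raises(MeasurementError):
            px.predict_from_measurements(
                model, px.MeasurementSet(max_length=300.0))

    def test_two_factor_parameter_recovery(self, template):
        # measurements are noiseless functions of the two varying factors,
        # so conditioning on both pins the held-out shape
        rng = np.random.default_rng(3)
        shapes, sets = [], []
        for _ in range(40):
            la = template.latent.replace(
                length=template.latent.length + rng.normal(0, 12.0),
                head_radius=template.latent.head_radius + rng.normal(0, 1.5))
            shapes.append(px.instantiate(template, la).vertices)
            sets.append(px.MeasurementSet(max_length=la.length,
                                          head_radius=la.head_radius))
        sset = px.CorrespondedShapeSet(template.mesh.faces, np.stack(shapes))
        model = px.build_augmented_ssm(sset, sets,
                                       ("max_length", "head_radius"))
        held = template.latent.replace(length=318.0, head_radius=23.0)
        truth = px.instantiate(template, held)
        res = px.predict_from_measurements(model, px.MeasurementSet(
            max_length=held.length, head_radius=held.head_radius))
        tf = px.kabsch(res.predicted_mesh.vertices, truth.vertices)
        err = np.linalg.norm(tf.apply(res.predicted_mesh.vertices)
                             - truth.vertices, axis=1)
        assert np.percentile(err, 99) < 0.5


class TestSerializationAndCombinations:
    def test_augmented_round_trip(self, augmented, tmp_path):
        model, *_ = augmented
        path = tmp_path / "aug.npz"
        save_augmented_model(model, path)
        back = load_augmented_model(path)
        assert back.measurement_names == model.measurement_names
        assert np.array_equal(back.modes, model.modes)
        assert np.array_equal(back.measurement_means, model.measurement_means)

    def test_combination_table_schema(self, measured_population, template):
        aligned, latents, sets = measured_population
        rng = np.random.default_rng(11)
        test_meshes, test_sets, hints = [], [], []
        for _ in range(2):
            la = template.latent.replace(
                length=template.latent.length + rng.normal(0, 10.0))
            mesh = px.instantiate(template, la)
            hcs = px.build_hcs(mesh, template.landmarks)
            test_meshes.append(mesh)
            test_sets.append(px.measure_all(mesh, hcs, template.landmarks))
            hints.append(mesh.vertices[template.landmarks.articular_surface]
                         .mean(axis=0))
        table = px.evaluate_combinations(aligned, sets, test_meshes, test_sets,
                                         proximal_hints=hints)
        assert len(table) == 7
        assert set(table.columns) >= {
            "combination", "pct_area_over_2mm_mean", "pct_area_over_2mm_sd",
            "max_deviation_mm_mean", "max_deviation_mm_sd"}
        assert "max_length+head_radius" in set(table.combination)
        assert (table.pct_area_over_2mm_mean >= 0).all()
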