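import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

import wingmorph as wm
from wingmorph.gpa import DegenerateConfigurationError, GeneralizedProcrustes

from conftest import random_similarity

UNIT_SQUARE = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)


class TestCentroidSize:
    def test_unit_square_is_sqrt_two(self):
        assert wm.centroid_size(UNIT_SQUARE) == pytest.approx(
            np.sqrt(2), abs=1e-12)

    @given(st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, max_examples=25)
    def test_homogeneous_of_degree_one(self, factor):
        base = wm.centroid_size(UNIT_SQUARE)
        assert wm.centroid_size(UNIT_SQUARE * factor) == pytest.approx(
            base * factor, rel=1e-12)

    def test_matches_two_step_recomputation_on_wing_template(self):
        # independent oracle: explicit centroid, then root-sum-of-squares
        config = wm.default_wing_template() * 3.7 + [1.0, -2.0]
        centroid = np.array([config[:, 0].sum(), config[:, 1].sum()]) / 18
        total = 0.0
        for point in config:
            total += (point[0] - centroid[0]) ** 2 \
                + (point[1] - centroid[1]) ** 2
        assert wm.centroid_size(config) == pytest.approx(
            np.sqrt(total), abs=1e-12)

    def test_coincident_landmarks_give_zero(self):
        assert wm.centroid_size(np.ones((5, 2))) == 0.0


class TestAlignPair:
    def test_identity(self):
        res = wm.align_pair(UNIT_SQUARE, UNIT_SQUARE)
        assert res.distance == pytest.approx(0, abs=1e-12)
        assert res.angle == pytest.approx(0, abs=1e-12)

    def test_rotation_translation_removed(self, rng):
        target = random_similarity(rng, scale_range=(1.0, 1.0))(UNIT_SQUARE)
        res = wm.align_pair(UNIT_SQUARE, target, scale=True)
        assert res.distance < 1e-10
        np.testing.assert_allclose(res.aligned, UNIT_SQUARE, atol=1e-9)

    def test_distance_matches_rotation_grid_search(self):
        # brute-force oracle: scan the rotation angle at 1e-4 rad steps
        ref = np.array([[0, 0], [1, 0], [0, 1]], dtype=float)
        tgt = np.array([[0, 0], [2, 0], [1, 2]], dtype=float)
        ref_u = (ref - ref.mean(0)) / wm.centroid_size(ref)
        tgt_u = (tgt - tgt.mean(0)) / wm.centroid_size(tgt)
        angles = np.arange(0, 2 * np.pi, 1e-4)
        cos, sin = np.cos(angles), np.sin(angles)
        rx = cos[:, None] * tgt_u[:, 0] - sin[:, None] * tgt_u[:, 1]
        ry = sin[:, None] * tgt_u[:, 0] + cos[:, None] * tgt_u[:, 1]
        rss = ((rx - ref_u[:, 0]) ** 2 + (ry - ref_u[:, 1]) ** 2).sum(axis=1)
        oracle = np.sqrt(rss.min())
        res = wm.align_pair(ref, tgt, scale=True)
        assert res.distance == pytest.approx(oracle, abs=1e-4)

    def test_degenerate_and_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            wm.align_pair(UNIT_SQUARE, UNIT_SQUARE[:3])
        with pytest.raises(DegenerateConfigurationError):
            wm.align_pair(UNIT_SQUARE, np.zeros((4, 2)))


class TestGeneralizedProcrustes:
    def test_duplicated_shape_collapses_to_consensus(self, rng):
        template = wm.default_wing_template()
        coords = np.stack([random_similarity(rng)(template)
                           for _ in range(12)])
        aligned = wm.generalized_procrustes(coords)
        assert aligned.converged
        for cfg in aligned.aligned_coords:
            assert np.abs(cfg - aligned.consensus).max() < 1e-8
        total_var = ((aligned.aligned_coords
                      - aligned.consensus) ** 2).sum()
        assert total_var < 1e-16

    def test_invariance_under_similarity_transforms(self, small_dataset,
                                                    rng):
        dataset, _ = small_dataset
        aligned = wm.generalized_procrustes(dataset)
        coords = np.stack([random_similarity(rng)(cfg)
                           for cfg in dataset.coords])
        aligned2 = wm.generalized_procrustes(coords)
        assert np.abs(aligned2.aligned_coords
                      - aligned.aligned_coords).max() < 1e-6

    def test_aligned_invariants(self, aligned_shapes):
        _, aligned, _ = aligned_shapes
        centroids = aligned.aligned_coords.mean(axis=1)
        assert np.abs(centroids).max() < 1e-9
        sizes = np.sqrt((aligned.aligned_coords ** 2).sum(axis=(1, 2)))
        np.testing.assert_allclose(sizes, 1.0, atol=1e-9)
        assert wm.centroid_size(aligned.consensus) == pytest.approx(
            1.0, abs=1e-9)
        assert np.all(aligned.centroid_sizes > 0)

    def test_two_specimen_distances_split_at_consensus(self, rng):
        # for two shapes, the pair distance equals the sum of their
        # distances to the GPA consensus (to first order, hence the
        # small-noise configuration)
        template = wm.default_wing_template()
        pair = np.stack([template,
                         template + 1e-3 * rng.standard_normal((18, 2))])
        aligned = wm.generalized_procrustes(pair)
        d_pair = wm.procrustes_distance(pair[0], pair[1])
        d_sum = sum(wm.procrustes_distance(cfg, aligned.consensus)
                    for cfg in aligned.aligned_coords)
        assert d_pair == pytest.approx(d_sum, abs=1e-8)

    def test_degenerate_specimen_named(self, small_dataset):
        dataset, _ = small_dataset
        coords = dataset.coords.copy()
        coords[3] = coords[3].mean(axis=0)
        with pytest.raises(DegenerateConfigurationError,
                           match=dataset.specimen_ids[3]):
            wm.generalized_procrustes(
                wm.LandmarkDataset(coords, dataset.meta))

    def test_procrustes_distance_is_pseudometric(self, rng):
        shapes = [wm.default_wing_template()
                  + 0.05 * rng.standard_normal((18, 2)) for _ in range(6)]
        for a in shapes:
            assert wm.procrustes_distance(a, a) == pytest.approx(0, abs=1e-9)
        for a, b, c in zip(shapes, shapes[1:], shapes[2:]):
            dab = wm.procrustes_distance(a, b)
            assert dab == pytest.approx(wm.procrustes_distance(b, a),
                                        abs=1e-9)
            assert dab <= wm.procrustes_distance(a, c) \
                + wm.procrustes_distance(c, b) + 1e-9


class TestTangentProjection:
    def test_consensus_is_fixed_point(self, aligned_shapes):
        _, aligned, _ = aligned_shapes
        fake = wm.AlignedDataset(aligned.consensus[None, :, :],
                                 np.ones(1), aligned.consensus, True, 1)
        projected = wm.tangent_projection(fake)
        np.testing.assert_allclose(projected[0],
                                   aligned.consensus.reshape(-1),
                                   atol=1e-12)

    def test_projection_contracts_toward_consensus(self, aligned_shapes):
        _, aligned, shapes = aligned_shapes
        c = aligned.consensus.reshape(-1)
        raw = aligned.aligned_coords.reshape(len(shapes), -1)
        norm_proj = np.linalg.norm(shapes - c, axis=1)
        norm_raw = np.linalg.norm(raw - c, axis=1)
        assert np.all(norm_proj <= norm_raw + 1e-12)

    def test_tangent_distances_match_procrustes_at_low_noise(self, rng):
        template = wm.default_wing_template()
        coords = np.stack([template + 0.005 * rng.standard_normal((18, 2))
                           for _ in range(8)])
        aligned = wm.generalized_procrustes(coords)
        shapes = wm.tangent_projection(aligned)
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                d_t = np.linalg.norm(shapes[i] - shapes[j])
                d_p = wm.procrustes_distance(coords[i], coords[j])
                assert d_t == pytest.approx(d_p, rel=0.01)


class TestMeanShape:
    def test_overall_mean_is_consensus(self, aligned_shapes):
        _, aligned, _ = aligned_shapes
        np.testing.assert_allclose(wm.mean_shape(aligned),
                                   aligned.consensus, atol=1e-9)

    def test_empty_selection_rejected(self, aligned_shapes):
        _, aligned, _ = aligned_shapes
        with pytest.raises(ValueError, match="empty"):
            wm.mean_shape(aligned, np.zeros(aligned.n_specimens, bool))

    def test_known_landmark_displacement_recovered(self, rng):
        # two groups differing only by +0.05 in x at landmark 5
        template = wm.default_wing_template()
        shifted = template.copy()
        shifted[5, 0] += 0.05
        sigma, n = 0.005, 120
        coords = np.concatenate([
            template + sigma * rng.standard_normal((n, 18, 2)),
            shifted + sigma * rng.standard_normal((n, 18, 2))])
        aligned = wm.generalized_procrustes(coords)
        group = np.repeat([0, 1], n)
        diff = wm.mean_shape(aligned, group == 1) \
            - wm.mean_shape(aligned, group == 0)
        se = sigma * np.sqrt(2.0 / n)
        # the aligned frame is a rotation of the template frame, so test
        # the displacement magnitude and its localization at landmark 5
        assert np.linalg.norm(diff[5]) == pytest.approx(
            0.05 / wm.centroid_size(shifted), abs=3 * se + 0.01)
        assert np.linalg.norm(diff[5]) == np.linalg.norm(diff, axis=1).max()


class TestEstimatorFacade:
    def test_fit_sets_attributes_and_clone_roundtrip(self, small_dataset):
        dataset, _ = small_dataset
        est = GeneralizedProcrustes(tol=1e-9)
        assert clone(est).get_params() == est.get_params()
        est.fit(dataset.coords)
        assert est.converged_ and est.consensus_.shape == (18, 2)
        assert est.centroid_sizes_.shape == (dataset.n_specimens,)

    def test_transform_matches_functional_pipeline(self, small_dataset):
        dataset, _ = small_dataset
        est = GeneralizedProcrustes().fit(dataset.coords)
        shapes_est = est.transform(dataset.coords)
        aligned = wm.generalized_procrustes(dataset)
        shapes_fn = wm.tangent_projection(aligned)
        np.testing.assert_allclose(shapes_est, shapes_fn, atol=1e-10)

    def test_transform_accepts_flat_rows_and_requires_fit(self):
        est = GeneralizedProcrustes()
        with pytest.raises(ValueError, match="not fitted"):
            est.transform(np.zeros((2, 36)))
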