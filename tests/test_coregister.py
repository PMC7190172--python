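"""The five-step automated pipeline, ICP behavior, and the error metric."""

import numpy as np
import pytest

from coregkit.coregister import (CoregConfig, CoregResult,
                                 CoregistrationError, auto_coregister,
                                 evaluate_transform, icp, remove_outliers,
                                 template_fiducials_to_subject)
from coregkit.surface import SurfaceDistanceQuery, deface
from coregkit.synthetic_data import (SubjectSpec, generate_head_surface,
                                     generate_headshape,
                                     sample_ground_truth_transform)
from coregkit.transforms import (DegenerateGeometryError, RigidTransform,
                                 TransformParams, decompose, compose,
                                 fit_landmarks, invert, recompose)

from test_surface import exhaustive_distances


def jittered_estimates(surface, rng, sd=5.0):
    fid = surface.require_fiducials()
    return {k: fid[k] + rng.normal(0, sd, 3) for k in fid}


class TestTemplateFiducials:
    FIDS = {"nasion": np.array([0.0, 84.0, -40.0]),
            "lpa": np.array([-75.0, 0.0, -44.0]),
            "rpa": np.array([75.0, 0.0, -44.0])}

    def test_identity_affine_is_noop(self):
        out = template_fiducials_to_subject(self.FIDS, np.eye(4))
        for k in self.FIDS:
            assert np.array_equal(out[k], self.FIDS[k])

    def test_matches_direct_matrix_vector_products(self, rng):
        aff = np.eye(4)
        aff[:3, :3] = rng.normal(0, 1, (3, 3)) + np.eye(3) * 2  # affine w/ shear
        aff[:3, 3] = rng.normal(0, 20, 3)
        out = template_fiducials_to_subject(self.FIDS, aff)
        for k, pt in self.FIDS.items():
            assert np.allclose(out[k], aff[:3, :3] @ pt + aff[:3, 3],
                               atol=1e-12)

    def test_pure_y_shift_moves_nasion_y(self):
        aff = np.eye(4)
        aff[1, 3] = 10.0
        out = template_fiducials_to_subject(self.FIDS, aff)
        assert out["nasion"][1] == self.FIDS["nasion"][1] + 10.0

    def test_singular_affine_raises(self):
        aff = np.eye(4)
        aff[0, 0] = 0.0
        aff[0, 1] = 0.0
        aff[1, 0] = 0.0  # column/row collapse -> singular linear part
        aff[1, 1] = 0.0
        with pytest.raises(ValueError, match="singular"):
            template_fiducials_to_subject(self.FIDS, aff)


class TestICP:
    def test_fixed_point_at_ground_truth(self, coarse_subject):
        spec, surface, headshape = coarse_subject
        t, trace = icp(headshape.headshape_points, surface,
                       spec.ground_truth, n_iter=5)
        assert trace[0] < 1e-9  # already on-surface
        assert np.abs(t.matrix - spec.ground_truth.matrix).max() < 1e-9

    def test_recovers_small_known_perturbation(self, coarse_subject):
        spec, surface, headshape = coarse_subject
        gt = spec.ground_truth
        bump = recompose(TransformParams(3.0, -2.0, 4.0, 3.0, -2.0, 4.0))
        t, trace = icp(headshape.headshape_points, surface,
                       compose(bump, gt), n_iter=300, tol=1e-12)
        err = decompose(t).as_array() - decompose(gt).as_array()
        assert np.abs(err[:3]).max() < 0.1   # mm
        assert np.abs(err[3:]).max() < 0.1   # degrees
        assert trace[-1] < 0.05

    def test_trace_monotone_nonincreasing(self, coarse_subject,
                                          noisy_subject):
        for spec, surface, headshape in (coarse_subject, noisy_subject):
            bump = recompose(TransformParams(4, 2, -3, 4, 3, -4))
            _, trace = icp(headshape.headshape_points, surface,
                           compose(bump, spec.ground_truth), n_iter=60)
            assert np.all(np.diff(trace) <= 1e-9)

    def test_too_few_points_raise(self, unit_square_surface):
        with pytest.raises(DegenerateGeometryError):
            icp(np.zeros((2, 3)), unit_square_surface,
                RigidTransform.identity())

    def test_coincident_points_raise(self, unit_square_surface):
        with pytest.raises(DegenerateGeometryError):
            icp(np.tile([1.0, 2.0, 3.0], (5, 1)), unit_square_surface,
                RigidTransform.identity())


class TestRemoveOutliers:
    def test_threshold_semantics_exact(self, coarse_subject, rng):
        _, surface, headshape = coarse_subject
        # on-surface points in MRI frame; identity transform keeps them put
        query = SurfaceDistanceQuery(surface)
        pts = headshape.headshape_points.copy()
        pts = invert(
            coarse_subject[0].ground_truth).apply(pts)  # back to MRI frame
        radial = pts / np.linalg.norm(pts, axis=1, keepdims=True)
        pts[0] += 10.0 * radial[0]   # clearly out
        pts[1] += 4.9 * radial[1]    # just inside the 5 mm threshold
        retained = remove_outliers(pts, query, RigidTransform.identity(),
                                   threshold=5.0)
        assert 0 not in retained
        assert 1 in retained
        assert np.all(np.diff(retained) > 0)  # order preserved

    def test_all_on_surface_none_removed(self, coarse_subject):
        spec, surface, headshape = coarse_subject
        retained = remove_outliers(headshape.headshape_points, surface,
                                   spec.ground_truth, threshold=5.0)
        assert len(retained) == headshape.n

    def test_count_matches_exhaustive_oracle(self, noisy_subject):
        spec, surface, headshape = noisy_subject
        pts = invert(spec.ground_truth).apply(headshape.headshape_points)
        d_oracle = exhaustive_distances(pts, surface)
        retained = remove_outliers(headshape.headshape_points, surface,
                                   spec.ground_truth, threshold=5.0)
        assert len(retained) == int(np.sum(d_oracle <= 5.0))

    def test_all_removed_raises(self, unit_square_surface):
        pts = np.tile([0.3, 0.3, 50.0], (4, 1)) + np.eye(4, 3)
        with pytest.raises(CoregistrationError):
            remove_outliers(pts, unit_square_surface,
                            RigidTransform.identity(), threshold=5.0)


class TestAutoCoregister:
    def test_noise_free_recovery(self, coarse_subject, rng):
        spec, surface, headshape = coarse_subject
        result = auto_coregister(headshape, surface,
                                 jittered_estimates(surface, rng))
        assert result.median_error < 0.1
        err = (decompose(result.transform).as_array()
               - decompose(spec.ground_truth).as_array())
        assert np.abs(err[:3]).max() < 0.5
        assert np.abs(err[3:]).max() < 0.5
        assert not result.quality_flag
        assert result.landmark_rms < 15.0

    def test_missing_fiducial_estimate_raises(self, coarse_subject):
        _, surface, headshape = coarse_subject
        with pytest.raises(ValueError, match="lpa"):
            auto_coregister(headshape, surface,
                            {"nasion": np.zeros(3), "rpa": np.ones(3)})

    def test_summaries_are_percentiles_of_distances(self, noisy_subject,
                                                    rng):
        _, surface, headshape = noisy_subject
        result = auto_coregister(headshape, surface,
                                 jittered_estimates(surface, rng))
        d = result.distances_all
        assert result.median_error == np.median(d)
        assert result.iqr_low == np.percentile(d, 25)
        assert result.iqr_high == np.percentile(d, 75)
        assert len(d) == headshape.n == result.n_headshape_points

    def test_noisy_error_matches_halfnormal_simulation(self, rng):
        """With isotropic noise sigma the point-to-surface residuals are
        approximately half-normal; the fitted median error must land within
        20% of a Monte-Carlo estimate of that distribution's median."""
        sigma = 1.0
        gt = sample_ground_truth_transform(rng)
        spec = SubjectSpec(seed=61, ground_truth=gt, noise_sd=sigma,
                           outlier_fraction=0.0, mesh_subdivisions=3)
        surface = generate_head_surface(spec)
        headshape = generate_headshape(surface, spec)
        result = auto_coregister(headshape, surface,
                                 jittered_estimates(surface, rng))
        sims = [np.median(np.abs(rng.normal(0, sigma, headshape.n)))
                for _ in range(100)]
        expected = float(np.mean(sims))
        assert result.median_error == pytest.approx(expected, rel=0.20)

    def test_defaced_error_not_below_intact(self, noisy_subject, rng):
        _, surface, headshape = noisy_subject
        est = jittered_estimates(surface, rng)
        intact = auto_coregister(headshape, surface, est)
        defaced = auto_coregister(headshape, deface(surface), est)
        assert defaced.median_error >= intact.median_error

    def test_outlier_step_noop_on_clean_data(self, coarse_subject, rng):
        spec, surface, headshape = coarse_subject
        est = jittered_estimates(surface, rng)
        with_step = auto_coregister(headshape, surface, est)
        no_step = auto_coregister(headshape, surface, est,
                                  CoregConfig(outlier_threshold=1e9))
        assert len(with_step.outlier_indices) == 0
        assert np.abs(with_step.transform.matrix
                      - no_step.transform.matrix).max() < 1e-6

    def test_deterministic_bit_identical(self, noisy_subject, rng):
        _, surface, headshape = noisy_subject
        est = jittered_estimates(surface, rng)
        r1 = auto_coregister(headshape, surface, est)
        r2 = auto_coregister(headshape, surface, est)
        assert np.array_equal(r1.transform.matrix, r2.transform.matrix)
        assert np.array_equal(r1.distances_all, r2.distances_all)
        assert r1.iteration_trace == r2.iteration_trace


class TestEvaluateTransform:
    def test_ground_truth_on_clean_points_is_zero(self, coarse_subject):
        spec, surface, headshape = coarse_subject
        result = evaluate_transform(headshape, surface, spec.ground_truth)
        assert result.median_error < 1e-9
        assert len(result.outlier_indices) == 0
        assert result.iteration_trace == ()

    def test_gross_misalignment_is_flagged(self):
        gt = RigidTransform.from_rotation_translation(np.eye(3), (0, 0, -70.0))
        spec = SubjectSpec(seed=77, ground_truth=gt, noise_sd=0.0,
                           outlier_fraction=0.0, mesh_subdivisions=3)
        surface = generate_head_surface(spec)
        headshape = generate_headshape(surface, spec)
        result = evaluate_transform(headshape, surface,
                                    RigidTransform.identity())
        # the 70 mm offset leaves the cloud far off-surface: error is an
        # order of magnitude above the 2 mm quality heuristic
        assert result.median_error > 5.0
        assert result.quality_flag

    def test_consistent_with_auto_coregister(self, noisy_subject, rng):
        _, surface, headshape = noisy_subject
        auto = auto_coregister(headshape, surface,
                               jittered_estimates(surface, rng))
        ev = evaluate_transform(headshape, surface, auto.transform)
        assert np.array_equal(ev.distances_all, auto.distances_all)
        assert ev.median_error == auto.median_error


class TestResultSerialization:
    def test_json_roundtrip(self, noisy_subject, rng, tmp_path):
        _, surface, headshape = noisy_subject
        result = auto_coregister(headshape, surface,
                                 jittered_estimates(surface, rng))
        path = tmp_path / "result.json"
        result.to_json(path)
        back = CoregResult.from_json(path)
        assert np.array_equal(back.transform.matrix, result.transform.matrix)
        assert np.array_equal(back.distances_all, result.distances_all)
        assert back.iteration_trace == result.iteration_trace
        assert back.median_error == result.median_error
        assert np.array_equal(back.outlier_indices, result.outlier_indices)


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_icp_initial": 0},
        {"convergence_tol": 0.0},
        {"outlier_threshold": -1.0},
        {"quality_threshold": 0.0},
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CoregConfig(**kwargs)
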