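"""Scapula frames, thorax rotation and YXZ Euler decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

import scapreli as sr
from scapreli.exceptions import DegenerateGeometryError, GimbalLockError, ValidationError
from scapreli.landmark_io import CoordinateSpace

from conftest import random_rotation

CANONICAL = sr.LandmarkTriplet([0, 0, 0], [0, -120, 60], [0, 0, 100])


def _random_triplet(rng):
    while True:
        t = sr.LandmarkTriplet(*rng.normal(scale=60, size=(3, 3)))
        if t.triangle_area() > 50:
            return t


class TestScapulaFrame:
    def test_canonical_configuration_gives_identity(self):
        frame = sr.build_scapula_frame(CANONICAL)
        np.testing.assert_allclose(frame.R, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(frame.origin, [0, 0, 0])

    def test_rotational_equivariance(self, rng):
        for _ in range(20):
            triplet = _random_triplet(rng)
            q = random_rotation(rng)
            base = sr.build_scapula_frame(triplet)
            rotated = sr.build_scapula_frame(triplet.transformed(lambda p: q @ p))
            np.testing.assert_allclose(rotated.R, q @ base.R, atol=1e-9)

    def test_orthonormality_and_determinant(self, rng):
        for _ in range(50):
            R = sr.build_scapula_frame(_random_triplet(rng)).R
            np.testing.assert_allclose(R.T @ R, np.eye(3), atol=1e-9)
            assert abs(np.linalg.det(R) - 1) < 1e-9

    def test_collinear_triplet_rejected(self):
        with pytest.raises(DegenerateGeometryError, match="area"):
            sr.build_scapula_frame(
                sr.LandmarkTriplet([0, 0, 0], [0, 0, 50.001], [0, 0, 100])
            )


class TestMeanLandmarks:
    def test_idempotent_on_identical_records(self):
        recs = [sr.MeasurementRecord("S1", f"o{i}", 1, CANONICAL) for i in range(3)]
        mean = sr.mean_landmarks(recs)
        np.testing.assert_allclose(mean.as_array(), CANONICAL.as_array())

    def test_two_point_mean(self):
        a = sr.MeasurementRecord("S1", "o1", 1, sr.LandmarkTriplet([0, 0, 0], [0, -120, 60], [0, 0, 100]))
        b = sr.MeasurementRecord("S1", "o1", 2, sr.LandmarkTriplet([2, 0, 0], [0, -120, 60], [0, 0, 100]))
        np.testing.assert_allclose(sr.mean_landmarks([a, b]).AA, [1, 0, 0])

    def test_matches_brute_force_column_mean(self, small_dataset):
        dataset, _, _ = small_dataset
        recs = dataset.records_for_scapula("S001")
        mean = sr.mean_landmarks(recs)
        for lm in ("AA", "IA", "TS"):
            expected = np.zeros(3)
            for r in recs:  # independent summation oracle
                expected += getattr(r.landmarks, lm)
            expected /= len(recs)
            np.testing.assert_allclose(getattr(mean, lm), expected, atol=1e-12)

    def test_mixed_spaces_rejected(self):
        a = sr.MeasurementRecord("S1", "o1", 1, CANONICAL)
        b = sr.MeasurementRecord("S1", "o1", 2, CANONICAL, CoordinateSpace.THORAX)
        with pytest.raises(ValidationError, match="mix"):
            sr.mean_landmarks([a, b])


class TestCoordinateReexpression:
    def test_round_trip(self, rng):
        from scapreli.geometry import from_average_cs, to_average_cs

        triplet = _random_triplet(rng)
        frame = sr.build_scapula_frame(_random_triplet(rng))
        rec = sr.MeasurementRecord("S1", "o1", 1, triplet)
        back = from_average_cs(to_average_cs(rec, frame), frame)
        np.testing.assert_allclose(back.landmarks.as_array(), triplet.as_array(), atol=1e-9)

    def test_isometry(self, rng):
        triplet = _random_triplet(rng)
        frame = sr.build_scapula_frame(_random_triplet(rng))
        rec = sr.to_average_cs(sr.MeasurementRecord("S1", "o1", 1, triplet), frame)
        before = np.linalg.norm(triplet.AA - triplet.TS)
        after = np.linalg.norm(rec.landmarks.AA - rec.landmarks.TS)
        assert abs(before - after) < 1e-9

    def test_rigid_pose_invariance_of_average_cs(self, rng):
        """Posing all records of a scapula rigidly changes no average-CS coordinate."""
        cfg = sr.GeneratorConfig(n_scapulae=1, seed=3)
        dataset, _ = sr.generate_dataset(cfg)
        records = dataset.records
        q, t = random_rotation(rng), rng.normal(scale=100, size=3)

        def acs_coords(recs):
            frame = sr.build_scapula_frame(sr.mean_landmarks(recs))
            return np.stack([sr.to_average_cs(r, frame).landmarks.as_array() for r in recs])

        posed = [
            sr.MeasurementRecord(
                r.scapula_id, r.observer_id, r.measure_idx,
                r.landmarks.transformed(lambda p: q @ p + t),
            )
            for r in records
        ]
        np.testing.assert_allclose(acs_coords(records), acs_coords(posed), atol=1e-8)


class TestEulerYXZ:
    def test_identity_round_trip(self):
        frame = sr.euler_yxz_compose(sr.OrientationAngles(0, 0, 0))
        np.testing.assert_allclose(frame.R, np.eye(3), atol=1e-15)
        angles = sr.euler_yxz_extract(frame)
        np.testing.assert_allclose(angles.as_array(), [0, 0, 0], atol=1e-12)

    def test_compose_matches_scipy_intrinsic_yxz(self):
        angles = sr.OrientationAngles(10, 20, 30)
        ours = sr.euler_yxz_compose(angles).R
        oracle = Rotation.from_euler("YXZ", [10, 20, 30], degrees=True).as_matrix()
        np.testing.assert_allclose(ours, oracle, atol=1e-12)

    @pytest.mark.parametrize("e1", [-170.0, -45.0, 0.0, 41.1, 120.0])
    @pytest.mark.parametrize("e2", [-80.0, -30.0, 0.0, 5.4, 80.0])
    @pytest.mark.parametrize("e3", [-150.0, 0.0, 13.5, 60.0])
    def test_extract_compose_identity_on_grid(self, e1, e2, e3):
        angles = sr.OrientationAngles(e1, e2, e3)
        out = sr.euler_yxz_extract(sr.euler_yxz_compose(angles))
        np.testing.assert_allclose(out.as_array(), angles.as_array(), atol=1e-9)

    @settings(derandomize=True, deadline=None, max_examples=100)
    @given(
        e1=st.floats(-179.9, 180.0),
        e2=st.floats(-89.0, 89.0),
        e3=st.floats(-179.9, 180.0),
    )
    def test_round_trip_property(self, e1, e2, e3):
        angles = sr.OrientationAngles(e1, e2, e3)
        frame = sr.euler_yxz_compose(angles)
        out = sr.euler_yxz_extract(frame)
        np.testing.assert_allclose(
            sr.euler_yxz_compose(out).R, frame.R, atol=1e-9
        )

    def test_near_gimbal_raises(self):
        frame = sr.euler_yxz_compose(sr.OrientationAngles(10, 89.9999999999, 5))
        with pytest.raises(GimbalLockError, match="R\\[1,2\\]"):
            sr.euler_yxz_extract(frame)


class TestThoraxRotation:
    def test_zero_pose_is_identity(self):
        frame = sr.thorax_rotation(sr.ThoraxPose(0, 0, 0))
        np.testing.assert_allclose(frame.R, np.eye(3), atol=1e-15)

    def test_default_pose_round_trips_through_extraction(self):
        frame = sr.thorax_rotation(sr.DEFAULT_THORAX_POSE)
        angles = sr.euler_yxz_extract(frame)
        np.testing.assert_allclose(angles.as_array(), [41.1, 5.4, 13.5], atol=1e-12)

    def test_pure_protraction_90_gives_signed_permutation(self):
        R = sr.thorax_rotation(sr.ThoraxPose(90, 0, 0)).R
        np.testing.assert_allclose(R, [[0, 0, 1], [0, 1, 0], [-1, 0, 0]], atol=1e-12)

    def test_apply_preserves_norm_and_matches_oracle(self, rng):
        frame = sr.thorax_rotation(sr.DEFAULT_THORAX_POSE)
        triplet = _random_triplet(rng)
        rec = sr.MeasurementRecord(
            "S1", "o1", 1, triplet, CoordinateSpace.AVERAGE_SCAPULA
        )
        out = sr.apply_thorax_rotation(rec, frame)
        for lm in ("AA", "IA", "TS"):
            p = getattr(triplet, lm)
            q = getattr(out.landmarks, lm)
            assert abs(np.linalg.norm(p) - np.linalg.norm(q)) < 1e-9
            oracle = np.array(  # brute-force 3x3 multiply
                [sum(frame.R[i, j] * p[j] for j in range(3)) for i in range(3)]
            )
            np.testing.assert_allclose(q, oracle, atol=1e-12)


class TestScapularOrientation:
    def test_zero_noise_reproduces_thorax_pose(self, zero_noise_dataset):
        dataset, _, _ = zero_noise_dataset
        _, angles = sr.compute_coordinates_and_orientations(dataset)
        np.testing.assert_allclose(
            angles[["e1_deg", "e2_deg", "e3_deg"]].to_numpy(),
            np.tile([41.1, 5.4, 13.5], (len(angles), 1)),
            atol=1e-9,
        )

    def test_zero_noise_with_null_pose_gives_zero_angles(self, zero_noise_dataset):
        dataset, _, _ = zero_noise_dataset
        _, angles = sr.compute_coordinates_and_orientations(dataset, pose=sr.ThoraxPose(0, 0, 0))
        np.testing.assert_allclose(
            angles[["e1_deg", "e2_deg", "e3_deg"]].to_numpy(), 0, atol=1e-9
        )

    def test_noisy_dataset_matches_straight_line_oracle(self, small_dataset):
        """End-to-end angles equal an independent plain-loop reimplementation."""
        dataset, _, _ = small_dataset
        coords, angles = sr.compute_coordinates_and_orientations(dataset)
        r_tcs = Rotation.from_euler("YXZ", [41.1, 5.4, 13.5], degrees=True).as_matrix()
        for sid in dataset.scapula_ids:
            recs = dataset.records_for_scapula(sid)
            pts = np.stack([r.landmarks.as_array() for r in recs])
            m_aa, m_ia, m_ts = pts.mean(axis=0)

            def frame_of(aa, ia, ts):
                z = (ts - aa) / np.linalg.norm(ts - aa)
                x = np.cross(ts - aa, ia - aa)
                x = x / np.linalg.norm(x)
                return np.column_stack([x, np.cross(z, x), z])

            r_avg = frame_of(m_aa, m_ia, m_ts)
            for rec in recs:
                local = [r_avg.T @ (getattr(rec.landmarks, lm) - m_aa) for lm in ("AA", "IA", "TS")]
                tcs = [r_tcs @ p for p in local]
                expected = Rotation.from_matrix(frame_of(*tcs)).as_euler("YXZ", degrees=True)
                got = angles[
                    (angles.scapula_id == sid)
                    & (angles.observer_id == rec.observer_id)
                    & (angles.measure_idx == rec.measure_idx)
                ][["e1_deg", "e2_deg", "e3_deg"]].to_numpy()[0]
                np.testing.assert_allclose(got, expected, atol=1e-8)

    def test_rigid_pose_invariance_of_angles(self, small_dataset, rng):
        dataset, _, _ = small_dataset
        _, base = sr.compute_coordinates_and_orientations(dataset)
        q, t = random_rotation(rng), rng.normal(scale=200, size=3)
        posed = sr.StudyDataset(
            [
                sr.MeasurementRecord(
                    r.scapula_id, r.observer_id, r.measure_idx,
                    r.landmarks.transformed(lambda p: q @ p + t),
                )
                for r in dataset.records
            ]
        )
        _, moved = sr.compute_coordinates_and_orientations(posed)
        np.testing.assert_allclose(
            base[["e1_deg", "e2_deg", "e3_deg"]].to_numpy(),
            moved[["e1_deg", "e2_deg", "e3_deg"]].to_numpy(),
            atol=1e-8,
        )
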