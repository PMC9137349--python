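import numpy as np
import pytest

from thermotriage import (
    FaceSpec,
    OffsetCalibration,
    VisualLandmarks,
    calibrate_offset,
    detect_rgbmap,
    generate_face,
    map_landmarks,
)
from thermotriage.errors import DegenerateGeometry, InsufficientData
from thermotriage.evaluate import landmark_errors


def pairs_from_transform(points, s=1.0, theta=0.0, dr=0.0, dc=0.0, jitter=0.0, rng=None):
    points = np.asarray(points, dtype=float)
    a = s * np.exp(1j * theta)
    z = points[:, 1] + 1j * points[:, 0]
    w = a * z + complex(dc, dr)
    thermal = np.stack([w.imag, w.real], axis=1)
    if jitter:
        thermal = thermal + rng.normal(0, jitter, size=thermal.shape)
    return [((r, c), (tr, tc)) for (r, c), (tr, tc) in zip(points, thermal)]


class TestCalibrateOffset:
    def test_exact_translation(self):
        pairs = [((10, 10), (15, 7)), ((30, 40), (35, 37)), ((5, 60), (10, 57))]
        cal = calibrate_offset(pairs, "translation")
        assert (cal.dr, cal.dc) == (5.0, -3.0)
        assert cal.residual_rmse == pytest.approx(0.0, abs=1e-12)

    def test_identity_pairs(self):
        pairs = [((r, c), (r, c)) for r, c in [(1, 2), (30, 40)]]
        cal = calibrate_offset(pairs, "translation")
        assert (cal.dr, cal.dc) == (0.0, 0.0)

    def test_noiseless_similarity_recovered_exactly(self):
        rng = np.random.default_rng(0)
        points = rng.uniform(0, 100, size=(8, 2))
        pairs = pairs_from_transform(points, s=0.7, theta=0.2, dr=-3.0, dc=11.0)
        cal = calibrate_offset(pairs, "similarity")
        assert cal.s == pytest.approx(0.7, abs=1e-6)
        assert cal.theta == pytest.approx(0.2, abs=1e-6)
        assert cal.dr == pytest.approx(-3.0, abs=1e-6)
        assert cal.dc == pytest.approx(11.0, abs=1e-6)

    def test_jittered_similarity_parameter_recovery(self):
        rng = np.random.default_rng(3)
        points = rng.uniform(0, 100, size=(10, 2))
        pairs = pairs_from_transform(points, s=0.5, dr=4.0, dc=7.0, jitter=0.3, rng=rng)
        cal = calibrate_offset(pairs, "similarity")
        assert cal.s == pytest.approx(0.5, abs=0.02)
        assert cal.dr == pytest.approx(4.0, abs=0.5)
        assert cal.dc == pytest.approx(7.0, abs=0.5)

    def test_matches_skimage_similarity_estimate(self):
        from skimage.transform import SimilarityTransform

        rng = np.random.default_rng(11)
        points = rng.uniform(0, 120, size=(12, 2))
        pairs = pairs_from_transform(points, s=1.3, theta=-0.4, dr=2.5, dc=-6.0,
                                     jitter=0.5, rng=rng)
        cal = calibrate_offset(pairs, "similarity")
        src = np.array([[c, r] for (r, c), _ in pairs])  # (x, y) order
        dst = np.array([[c, r] for _, (r, c) in pairs])
        if hasattr(SimilarityTransform, "from_estimate"):
            ref = SimilarityTransform.from_estimate(src, dst)
        else:
            ref = SimilarityTransform()
            assert ref.estimate(src, dst)
        assert cal.s == pytest.approx(ref.scale, abs=1e-6)
        assert cal.theta == pytest.approx(ref.rotation, abs=1e-6)
        assert cal.dc == pytest.approx(ref.translation[0], abs=1e-6)
        assert cal.dr == pytest.approx(ref.translation[1], abs=1e-6)

    def test_fit_reproduces_its_own_pairs(self):
        rng = np.random.default_rng(8)
        points = rng.uniform(0, 100, size=(15, 2))
        pairs = pairs_from_transform(points, s=0.9, theta=0.1, dr=5, dc=5,
                                     jitter=0.4, rng=rng)
        cal = calibrate_offset(pairs, "similarity")
        sq = [
            np.sum((np.array(cal.apply(*v)) - np.array(t)) ** 2) for v, t in pairs
        ]
        assert np.sqrt(np.mean(sq)) <= cal.residual_rmse + 1e-9

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientData):
            calibrate_offset([], "translation")
        with pytest.raises(InsufficientData):
            calibrate_offset([((0, 0), (1, 1))], "similarity")

    def test_coincident_points_degenerate(self):
        pairs = [((5, 5), (1, 1)), ((5, 5), (2, 2)), ((5, 5), (3, 3))]
        with pytest.raises(DegenerateGeometry):
            calibrate_offset(pairs, "similarity")

    def test_json_round_trip(self, tmp_path):
        cal = calibrate_offset(
            pairs_from_transform(np.array([[0, 0], [10, 10], [0, 20.0]]), s=0.5, dr=4, dc=7),
            "similarity",
        )
        cal.to_json(tmp_path / "cal.json")
        assert OffsetCalibration.from_json(tmp_path / "cal.json") == cal


class TestMapLandmarks:
    def landmarks(self):
        return VisualLandmarks(
            points={"left_inner_canthus": (10.0, 10.0), "nose_tip": (40.0, 20.0)},
            image_shape=(100, 100),
        )

    def test_identity(self):
        cal = OffsetCalibration("translation", dr=0, dc=0)
        mapped = map_landmarks(self.landmarks(), cal, (100, 100))
        assert (mapped["nose_tip"].row, mapped["nose_tip"].col) == (40, 20)
        assert not mapped["nose_tip"].clamped

    def test_translation_arithmetic(self):
        cal = OffsetCalibration("translation", dr=5, dc=-3)
        mapped = map_landmarks(self.landmarks(), cal, (100, 100))
        assert (mapped["left_inner_canthus"].row, mapped["left_inner_canthus"].col) == (15, 7)

    def test_out_of_frame_clamped_and_flagged(self):
        cal = OffsetCalibration("translation", dr=70, dc=0)
        mapped = map_landmarks(self.landmarks(), cal, (100, 100))
        assert mapped["nose_tip"].clamped
        assert mapped["nose_tip"].row == 99

    def test_round_trip_through_inverse_within_one_pixel(self):
        cal = OffsetCalibration("similarity", dr=4.0, dc=7.0, s=0.8, theta=0.15)
        inv = cal.invert()
        rng = np.random.default_rng(2)
        for r, c in rng.uniform(5, 90, size=(20, 2)):
            fr, fc = cal.apply(r, c)
            br, bc = inv.apply(round(fr), round(fc))
            assert abs(br - r) <= 1.0 and abs(bc - c) <= 1.0

    def test_landmarks_must_include_nose(self):
        with pytest.raises(ValueError):
            VisualLandmarks(points={"left_inner_canthus": (1, 1)}, image_shape=(50, 50))


class TestDetectRgbmap:
    def exact_calibration(self, spec):
        return OffsetCalibration("translation", dr=spec.parallax[0], dc=spec.parallax[1])

    def test_zero_noise_exact_chain(self, clean_spec):
        img, truth = generate_face(clean_spec, seed=5)
        res = detect_rgbmap(
            img, truth.visual_landmarks(), self.exact_calibration(clean_spec), refine_radius=0
        )
        assert landmark_errors(res, truth) == (0.0, 0.0)
        assert res.gradient == pytest.approx(truth.true_gradient, abs=1e-9)
        assert res.algorithm == "rgb-thermal"

    def test_known_offset_maps_within_two_pixels(self):
        spec = FaceSpec(noise_sigma=0.05)
        cal = self.exact_calibration(spec)
        hits = 0
        for seed in range(100):
            img, truth = generate_face(spec, seed=seed)
            res = detect_rgbmap(img, truth.visual_landmarks(), cal, refine_radius=0)
            if max(landmark_errors(res, truth)) <= 2.0:
                hits += 1
        assert hits >= 95

    def test_refinement_corrects_a_biased_calibration(self):
        # calibration off by a fractional pixel: mapping alone misses by ~1 px,
        # snapping to the local thermal extremum recovers the planted spot
        spec = FaceSpec(noise_sigma=0.05)
        biased = OffsetCalibration(
            "translation", dr=spec.parallax[0] + 0.6, dc=spec.parallax[1] + 0.6
        )
        raw, refined = [], []
        for seed in range(100):
            img, truth = generate_face(spec, seed=seed)
            lms = truth.visual_landmarks()
            raw.append(
                max(landmark_errors(detect_rgbmap(img, lms, biased, refine_radius=0), truth))
            )
            refined.append(
                max(landmark_errors(detect_rgbmap(img, lms, biased, refine_radius=3), truth))
            )
        assert np.mean(refined) <= np.mean(raw)
        assert np.mean(refined) < 0.5

    def test_single_canthus_input_still_detects(self, clean_spec):
        img, truth = generate_face(clean_spec, seed=13)
        points = dict(truth.visual_landmarks().points)
        points.pop("right_inner_canthus")
        lms = VisualLandmarks(points=points, image_shape=truth.visual_shape)
        res = detect_rgbmap(img, lms, self.exact_calibration(clean_spec), refine_radius=0)
        assert (res.canthus.row, res.canthus.col) == truth.canthus_left
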