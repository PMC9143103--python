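import numpy as np
import pytest

from mwtrack import (
    ImageGrid,
    PixelMapping,
    ReconstructionImage,
    Scene,
    binarize,
    centroid_mm,
    differential_image,
    normalize_image,
    pixel_pitch_from_reference,
    pixel_to_physical,
    physical_to_pixel,
    simulate_reflection_sweep,
    track_sequence,
)
from mwtrack.errors import (
    DataError,
    DegenerateImageError,
    IncompatibleInputError,
    NoDetectionError,
)


def _img(arr, pitch=1.0, algorithm="DAS", normalized=False):
    arr = np.asarray(arr, dtype=float)
    grid = ImageGrid(arr.shape[0], arr.shape[1], pitch, pitch)
    return ReconstructionImage(grid, arr, algorithm, normalized)


class TestNormalizeImage:
    def test_constant_becomes_one(self):
        out = normalize_image(_img(np.full((4, 4), 5.0)))
        assert np.all(out.intensity == 1.0) and out.normalized

    def test_max_maps_to_exactly_one(self, rng):
        out = normalize_image(_img(rng.random((6, 6))))
        assert out.intensity.max() == 1.0

    def test_ordering_preserved(self, rng):
        raw = rng.random((5, 5))
        out = normalize_image(_img(raw)).intensity
        assert np.array_equal(np.argsort(raw.ravel()), np.argsort(out.ravel()))

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateImageError):
            normalize_image(_img(np.zeros((3, 3))))


class TestDifferentialImage:
    def test_identical_images_degenerate(self):
        a = _img(np.ones((4, 4)))
        with pytest.raises(DegenerateImageError):
            differential_image(a, a)

    def test_zero_previous_gives_normalized_current(self, rng):
        cur = _img(rng.random((5, 5)) + 0.1)
        prev = _img(np.zeros((5, 5)))
        out = differential_image(cur, prev)
        assert np.allclose(out.intensity, cur.intensity / cur.intensity.max())

    def test_negatives_clipped_by_default(self):
        cur = _img([[0.0, 2.0], [0.0, 0.0]])
        prev = _img([[1.0, 0.0], [0.0, 0.0]])
        out = differential_image(cur, prev)
        assert out.intensity[0, 0] == 0.0 and out.intensity[0, 1] == 1.0

    def test_abs_mode_keeps_departed_residue(self):
        cur = _img([[0.0, 2.0], [0.0, 0.0]])
        prev = _img([[1.0, 0.0], [0.0, 0.0]])
        out = differential_image(cur, prev, negatives="abs")
        assert out.intensity[0, 0] == 0.5

    def test_grid_mismatch_rejected(self):
        with pytest.raises(IncompatibleInputError):
            differential_image(_img(np.ones((4, 4))), _img(np.ones((5, 5))))


class TestBinarize:
    def test_threshold_zero_all_white(self, rng):
        img = normalize_image(_img(rng.random((4, 4)) + 0.01))
        assert binarize(img, 0.0).all()

    def test_quoted_rule_at_0_8(self):
        img = _img([[0.9, 0.1], [0.79, 0.80]], normalized=True)
        mask = binarize(img, 0.8)
        assert mask.tolist() == [[True, False], [False, True]]

    def test_threshold_one_keeps_argmax_only(self, rng):
        raw = rng.random((5, 5))
        raw[2, 3] = 2.0
        mask = binarize(normalize_image(_img(raw)), 1.0)
        assert mask.sum() == 1 and mask[2, 3]


class TestCentroid:
    def test_single_pixel_at_origin(self):
        mask = np.zeros((5, 5), bool)
        mask[2, 2] = True
        mapping = PixelMapping(1.0, 1.0, (2, 2))
        assert centroid_mm(mask, mapping) == (0.0, 0.0)

    def test_symmetric_square_centered(self):
        mask = np.zeros((7, 7), bool)
        mask[2:5, 2:5] = True
        mapping = PixelMapping(1.0, 1.0, (3, 3))
        assert centroid_mm(mask, mapping) == (0.0, 0.0)

    def test_largest_component_wins(self):
        mask = np.zeros((10, 12), bool)
        mask[1:2, 1:6] = True            # 5 px component
        mask[6:9, 5:9] = True            # 12 px component
        mapping = PixelMapping(1.0, 1.0, (0, 0))
        x, y = centroid_mm(mask, mapping)
        # hand count: rows 6..8 -> mean 7, cols 5..8 -> mean 6.5
        assert (x, y) == (6.5, -7.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(NoDetectionError):
            centroid_mm(np.zeros((4, 4), bool), PixelMapping(1, 1, (0, 0)))


class TestPixelMapping:
    def test_origin_pixel_maps_to_origin(self):
        m = PixelMapping(0.1922, 0.2255, (650.0, 650.0))
        assert pixel_to_physical(650.0, 650.0, m) == (0.0, 0.0)

    def test_column_pitch(self):
        m = PixelMapping(0.1922, 0.2255, (650.0, 650.0))
        x, y = pixel_to_physical(650.0, 651.0, m)
        assert x == pytest.approx(0.1922) and y == 0.0

    def test_y_grows_upward(self):
        m = PixelMapping(1.0, 1.0, (10.0, 10.0))
        assert pixel_to_physical(9.0, 10.0, m)[1] == 1.0

    def test_round_trip_identity(self, rng):
        m = PixelMapping(0.1922, 0.2255, (650.0, 650.0))
        for x, y in rng.uniform(-100, 100, (10, 2)):
            r, c = physical_to_pixel(x, y, m)
            x2, y2 = pixel_to_physical(r, c, m)
            assert abs(x2 - x) < 1e-9 and abs(y2 - y) < 1e-9

    def test_pitch_from_reference(self):
        assert pixel_pitch_from_reference((100.0, 100.0), (100, 100)) == (1.0, 1.0)

    def test_pitch_scales_inversely(self):
        c1, r1 = pixel_pitch_from_reference((128.0, 170.0), (666, 754))
        c2, r2 = pixel_pitch_from_reference((128.0, 170.0), (1332, 1508))
        assert c1 == pytest.approx(2 * c2) and r1 == pytest.approx(2 * r2)

    def test_cranium_pixel_width_consistency(self):
        # 128 mm at 0.1922 mm/col implies a ~666-px-wide cranium
        assert 128.0 / 0.1922 == pytest.approx(665.97, abs=0.01)

    def test_invalid_reference_rejected(self):
        with pytest.raises(DataError):
            pixel_pitch_from_reference((128.0, 170.0), (0, 754))


@pytest.fixture(scope="module")
def straight_line_sequence(geometry16, sweep):
    """Noiseless 4-step approach with a static tumor, plus empty ref."""
    from mwtrack import rectangle_shape

    path = [(60.0, 50.0), (40.0, 34.0), (20.0, 18.0), (5.0, 6.0)]
    tumor = rectangle_shape((0, 26), 25, 25, 1.0)
    empty = simulate_reflection_sweep(Scene(label="empty"), geometry16, sweep)
    meas = []
    for x, y in path:
        scene = Scene(shapes=[tumor], label=f"({x},{y})")
        scene.add_point(x, y, 1.0)
        meas.append(simulate_reflection_sweep(scene, geometry16, sweep))
    return path, empty, meas


class TestTrackSequence:
    def test_identical_measurements_no_detection(self, point_measurement):
        m = point_measurement([(30.0, 30.0, 1.0)])
        grid = ImageGrid.from_extent(100, 100, 2.0)
        est = track_sequence([m, m], point_measurement([]), grid=grid)
        assert est[0].status == "no-prior"
        assert est[1].status == "no-detection"

    def test_straight_line_approach(self, geometry16, straight_line_sequence):
        path, empty, meas = straight_line_sequence
        grid = ImageGrid.from_extent(160, 160, 1.0)
        for alg in ("DAS", "DMAS"):
            est = track_sequence(meas, empty, algorithm=alg, grid=grid)
            det = [e.detected_xy for e in est if e.detected]
            assert len(det) == 3
            xs = [p[0] for p in det]
            ys = [p[1] for p in det]
            assert xs == sorted(xs, reverse=True), "x must decrease inward"
            assert ys == sorted(ys, reverse=True), "y must decrease inward"
            final_err = np.hypot(det[-1][0] - path[-1][0], det[-1][1] - path[-1][1])
            assert final_err <= 5.0

    def test_static_tumor_absent_from_estimates(self, straight_line_sequence):
        path, empty, meas = straight_line_sequence
        grid = ImageGrid.from_extent(160, 160, 1.0)
        est = track_sequence(meas, empty, algorithm="DAS", grid=grid)
        for e, true in zip([e for e in est if e.detected], path[1:]):
            err = np.hypot(e.detected_xy[0] - true[0], e.detected_xy[1] - true[1])
            d_tumor = np.hypot(e.detected_xy[0] - 0.0, e.detected_xy[1] - 26.0)
            assert d_tumor > err

    def test_global_amplitude_scale_invariance(self, straight_line_sequence):
        from mwtrack import SweepMeasurement

        path, empty, meas = straight_line_sequence
        grid = ImageGrid.from_extent(160, 160, 2.0)
        scaled = [
            SweepMeasurement(m.geometry, m.sweep, 7.5 * m.spectra) for m in meas
        ]
        e1 = track_sequence(meas, empty, grid=grid)
        e2 = track_sequence(scaled, empty, grid=grid)
        for a, b in zip(e1, e2):
            assert a.status == b.status
            if a.detected:
                assert a.detected_xy == pytest.approx(b.detected_xy, abs=1e-9)

    def test_needs_two_measurements(self, point_measurement):
        m = point_measurement([(0.0, 0.0, 1.0)])
        with pytest.raises(DataError):
            track_sequence([m], m)
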