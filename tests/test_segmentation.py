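import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scratchkin.errors import DegenerateInputError, ValidationError
from scratchkin.plate_io import ImageStack, SegmentationParams
from scratchkin.segmentation import (
    ObjectMap,
    compute_illumination_function,
    extract_features,
    identify_primary_objects,
    otsu_threshold,
    segment_series,
    subtract_background,
)
from scratchkin.synthetic import PlateSpec, render_frame

PARAMS = SegmentationParams(block_size=10, min_diameter=4, max_diameter=24)


def otsu_variance_curve(image: np.ndarray, nbins: int = 256):
    """Exhaustive between-class variance at every candidate split.

    Returns (bin centers, variance per split index i, splitting bins
    [0..i] from [i+1..]).  Computed with direct sums, independently of any
    cumulative-sum shortcut.
    """
    counts, edges = np.histogram(image.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2.0
    total = counts.sum()
    var = np.full(nbins - 1, -np.inf)
    for i in range(nbins - 1):
        w0 = counts[: i + 1].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[: i + 1] * centers[: i + 1]).sum() / w0
        mu1 = (counts[i + 1 :] * centers[i + 1 :]).sum() / w1
        var[i] = w0 * w1 * (mu0 - mu1) ** 2
    return centers, var


def assert_attains_max_between_class_variance(image: np.ndarray, threshold: float):
    """The threshold must sit at a split whose between-class variance equals
    the exhaustive maximum (empty bins between the modes make the maximizer
    a plateau, so the objective value, not the split index, is compared)."""
    centers, var = otsu_variance_curve(image)
    i = int(np.argmin(np.abs(centers[:-1] - threshold)))
    assert var[i] >= var.max() * (1 - 1e-10)


class TestIllumination:
    def test_constant_image_unchanged(self):
        img = np.full((30, 30), 7.0)
        out = compute_illumination_function(img, block_size=5)
        np.testing.assert_allclose(out, 7.0)

    def test_quadrant_minima_before_smoothing(self):
        rng = np.random.default_rng(1)
        img = rng.uniform(0, 100, size=(20, 20))
        out = compute_illumination_function(img, block_size=10, sigma=0)
        # brute-force per-quadrant minimum
        for r in (0, 1):
            for c in (0, 1):
                q = img[r * 10 : (r + 1) * 10, c * 10 : (c + 1) * 10]
                np.testing.assert_allclose(
                    out[r * 10 : (r + 1) * 10, c * 10 : (c + 1) * 10], q.min()
                )

    def test_recovers_ramp_under_sparse_spots(self):
        h, w = 60, 80
        ramp = np.linspace(0, 50, h)[:, None] * np.ones((1, w))
        img = ramp.copy()
        for r, c in [(15, 20), (40, 60), (30, 10)]:
            img[r - 1 : r + 2, c - 1 : c + 2] += 500.0  # 3-px-wide bright spots
        out = compute_illumination_function(img, block_size=12)
        assert np.max(np.abs(out - ramp)) < 50.0  # spots (500) absent

    def test_never_exceeds_image_maximum(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 1000, size=(40, 40))
        out = compute_illumination_function(img, block_size=8)
        assert out.max() <= img.max() + 1e-9

    def test_block_larger_than_image_rejected(self):
        with pytest.raises(ValidationError):
            compute_illumination_function(np.zeros((10, 10)), block_size=11)


class TestSubtractBackground:
    def test_equal_inputs_give_zero(self):
        img = np.random.default_rng(0).uniform(0, 10, (5, 5))
        np.testing.assert_array_equal(subtract_background(img, img), 0.0)

    def test_elementwise_difference_and_clamp(self):
        img = np.array([[10.0, 3.0]])
        illum = np.array([[3.0, 10.0]])
        np.testing.assert_array_equal(
            subtract_background(img, illum), [[7.0, 0.0]]
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            subtract_background(np.zeros((3, 3)), np.zeros((4, 4)))


class TestOtsu:
    def test_separates_two_populations(self):
        img = np.concatenate([np.full(50, 10.0), np.full(50, 200.0)]).reshape(10, 10)
        t = otsu_threshold(img)
        assert 10 < t < 200
        assert np.array_equal(img > t, img == 200.0)

    def test_binary_image_mask(self):
        img = np.tile(np.array([0.0, 1.0]), (8, 4))
        t = otsu_threshold(img)
        np.testing.assert_array_equal(img > t, img == 1.0)

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateInputError):
            otsu_threshold(np.full((5, 5), 3.0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        # bimodal mixture
        img = np.concatenate(
            [rng.normal(50, 10, 300), rng.normal(180, 20, 200)]
        ).reshape(25, 20)
        assert_attains_max_between_class_variance(img, otsu_threshold(img))

    def test_shift_invariant_classification(self):
        rng = np.random.default_rng(3)
        img = np.concatenate([rng.normal(40, 5, 128), rng.normal(150, 10, 128)]).reshape(16, 16)
        t0 = otsu_threshold(img)
        t1 = otsu_threshold(img + 100.0)
        np.testing.assert_array_equal(img > t0, (img + 100.0) > t1)


def _spot_frame(positions, h=200, w=260, diameter=12, seed=0, noise=5.0,
                density=0.003):
    from scratchkin.kinetics import GompertzParams
    from scratchkin.scratch import ScratchBand

    spec = PlateSpec(
        n_wells=1,
        height=h,
        width=w,
        band=ScratchBand(y_low=h // 3, y_high=2 * h // 3, bin_height=1),
        nucleus_diameter=diameter,
        density_outside=density,
        truth=[GompertzParams(100, 2, 30)],
        noise_sd=noise,
        background=(100.0, 0.0),
        seed=seed,
    )
    return render_frame(positions, spec, seed=seed)


class TestIdentifyObjects:
    def test_blank_image_zero_objects(self):
        out = identify_primary_objects(np.zeros((30, 30)), PARAMS)
        assert out.n_objects == 0

    def test_disjoint_spots_all_found(self):
        rng = np.random.default_rng(4)
        # 50 spots on a jittered grid, spacing 26 px
        pts = []
        for r in range(5):
            for c in range(10):
                pts.append(
                    [20 + 26 * r + rng.uniform(-3, 3), 14 + 26 * c + rng.uniform(-3, 3)]
                )
        pts = np.array(pts[:50])
        img = _spot_frame(pts, h=160, w=280)
        out = identify_primary_objects(img, PARAMS)
        assert out.n_objects == 50

    def test_touching_pair_declumped(self):
        pts = np.array([[50.0, 60.0], [50.0, 73.0]])  # centers ~1 diameter apart
        img = _spot_frame(pts, h=100, w=140, noise=0.0)
        out = identify_primary_objects(img, PARAMS)
        assert out.n_objects == 2

    def test_oversized_object_filtered(self):
        # one center-bright blob whose thresholded mask has equivalent
        # diameter ~2x the upper bound; the band-pass must drop it
        img = _spot_frame(np.array([[60.0, 60.0]]), h=120, w=120,
                          diameter=60, noise=0.0, density=1e-4)
        out = identify_primary_objects(img, PARAMS)
        assert out.n_objects == 0

    def test_labels_consecutive(self):
        rng = np.random.default_rng(5)
        pts = np.array([[30, 30], [30, 90], [80, 50]], dtype=float)
        img = _spot_frame(pts, h=110, w=130)
        out = identify_primary_objects(img, PARAMS)
        present = np.unique(out.labels)
        np.testing.assert_array_equal(present, np.arange(out.n_objects + 1))


class TestExtractFeatures:
    def test_square_centroid_and_area(self):
        labels = np.zeros((6, 6), dtype=np.int32)
        labels[0:3, 0:3] = 1
        img = np.full((6, 6), 42.0)
        (rec,) = extract_features(ObjectMap(labels, 1), img, frame_index=2)
        assert (rec.centroid_row, rec.centroid_col) == (1.0, 1.0)
        assert rec.area == 9
        assert rec.mean_intensity == 42.0
        assert rec.frame_index == 2

    def test_disc_eccentricity_near_zero(self):
        labels = np.zeros((40, 40), dtype=np.int32)
        rr, cc = np.mgrid[0:40, 0:40]
        labels[(rr - 20) ** 2 + (cc - 20) ** 2 < 12**2] = 1
        (rec,) = extract_features(ObjectMap(labels, 1), np.ones((40, 40)), 0)
        assert rec.eccentricity < 0.1


class TestSegmentSeries:
    def test_identical_frames_identical_features(self):
        pts = np.array([[40.0, 50.0], [80.0, 100.0]])
        frame = _spot_frame(pts, h=120, w=150)
        stack = ImageStack(frames=np.stack([frame, frame]))
        a, b = segment_series(stack, PARAMS)
        assert len(a) == len(b) == 2
        assert [
            (r.centroid_row, r.centroid_col, r.area) for r in a
        ] == [(r.centroid_row, r.centroid_col, r.area) for r in b]

    def test_all_black_stack_yields_empty_lists(self):
        stack = ImageStack(frames=np.zeros((3, 20, 20)))
        assert segment_series(stack, PARAMS) == [[], [], []]

    def test_planted_nuclei_recovered_on_dense_frame(self):
        from scipy.spatial import cKDTree

        from scratchkin.kinetics import GompertzParams
        from scratchkin.scratch import ScratchBand
        from scratchkin.synthetic import plant_monolayer

        spec = PlateSpec(
            n_wells=1, height=300, width=400,
            band=ScratchBand(y_low=110, y_high=210, bin_height=1),
            truth=[GompertzParams(100, 2, 30)], seed=9,
        )
        rng = np.random.default_rng(9)
        pts = plant_monolayer(spec, rng)
        assert len(pts) > 200
        frame = render_frame(pts, spec, seed=9)
        stack = ImageStack(frames=np.stack([frame, frame]))
        (recs, _) = segment_series(stack, spec.seg_params)
        det = np.array([[r.centroid_row, r.centroid_col] for r in recs])
        d, _ = cKDTree(det).query(pts)
        tol = spec.seg_params.min_diameter / 2
        recall = float(np.mean(d <= tol))
        d2, _ = cKDTree(pts).query(det)
        precision = float(np.mean(d2 <= tol))
        assert recall >= 0.95 and precision >= 0.95
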