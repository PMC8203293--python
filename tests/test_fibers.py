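import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mechanoscape.fibers import (
    SHGImage,
    TracerParams,
    architecture_summary,
    crosslink_fluorescence,
    curvature_ratio,
    orientation_cv,
    packed_fiber_fraction,
    shg_positive_mask,
    trace_fibers,
)
from mechanoscape.synthetic import FiberRenderSpec, gen_fiber_image, gen_sirius_red_image

finite_coord = st.floats(min_value=-100, max_value=100)


def random_path(seed, n=50):
    rng = np.random.default_rng(seed)
    path = np.cumsum(rng.normal(0, 1, (n, 2)), axis=0)
    if np.linalg.norm(path[-1] - path[0]) == 0:
        path[-1] += 1.0
    return path


class TestCurvatureRatio:
    def test_straight_segment_is_one(self):
        assert curvature_ratio([[0, 0], [5, 5]]) == 1.0

    def test_semicircle_is_half_pi(self):
        theta = np.linspace(0, np.pi, 20000)
        arc = np.column_stack([np.cos(theta), np.sin(theta)])
        assert curvature_ratio(arc) == pytest.approx(np.pi / 2, abs=1e-3)

    def test_matches_per_segment_oracle(self):
        path = random_path(42)
        total = 0.0
        for a, b in zip(path[:-1], path[1:]):
            total += float(np.hypot(*(b - a)))
        expected = total / float(np.linalg.norm(path[-1] - path[0]))
        assert curvature_ratio(path) == pytest.approx(expected, rel=1e-12)

    @given(st.integers(min_value=0, max_value=10_000))
    def test_at_least_one_for_any_polyline(self, seed):
        assert curvature_ratio(random_path(seed)) >= 1.0

    @given(
        st.integers(min_value=0, max_value=1000),
        st.floats(min_value=0, max_value=2 * np.pi),
        finite_coord,
        finite_coord,
    )
    def test_rigid_motion_invariance(self, seed, angle, tx, ty):
        path = random_path(seed)
        rot = np.array(
            [[np.cos(angle), -np.sin(angle)], [np.sin(angle), np.cos(angle)]]
        )
        moved = path @ rot.T + [tx, ty]
        assert curvature_ratio(moved) == pytest.approx(curvature_ratio(path), rel=1e-9)

    def test_closed_fiber_rejected(self):
        with pytest.raises(ValueError, match="closed"):
            curvature_ratio([[0, 0], [1, 1], [0, 0]])


class TestOrientationCV:
    def test_identical_angles_give_zero(self):
        assert orientation_cv([45.0, 45.0, 45.0]) == 0.0

    def test_two_angle_hand_value(self):
        # sample SD of {30, 90} is 42.426, mean 60
        assert orientation_cv([30.0, 90.0]) == pytest.approx(0.70711, abs=1e-5)

    def test_matches_sd_over_mean_oracle(self):
        angles = np.random.default_rng(9).uniform(1, 179, 100)
        mean = sum(angles) / len(angles)
        var = sum((a - mean) ** 2 for a in angles) / (len(angles) - 1)
        assert orientation_cv(angles) == pytest.approx(var**0.5 / mean, rel=1e-12)

    @given(st.lists(st.floats(min_value=0.1, max_value=179.9), min_size=2, max_size=30))
    def test_zero_iff_identical(self, angles):
        cv = orientation_cv(angles)
        if len(set(angles)) == 1:
            assert cv == 0.0
        else:
            assert cv > 0.0

    def test_errors(self):
        with pytest.raises(ValueError, match="two fibers"):
            orientation_cv([10.0])
        with pytest.raises(ValueError, match="rotate"):
            orientation_cv([0.0, 0.0])


class TestTracer:
    def test_blank_image_yields_no_fibers(self):
        image = SHGImage(np.zeros((64, 64)), 0.5)
        assert len(trace_fibers(image)) == 0

    def test_single_straight_fiber_recovery(self):
        spec = FiberRenderSpec(
            n_fibers=1,
            width_um_range=(5.0, 5.0),
            length_um_range=(80.0, 80.0),
            alignment_kappa=200.0,
            seed=1,
        )
        image, truth = gen_fiber_image(spec)
        traced = trace_fibers(image)
        assert len(traced) == 1
        fiber = traced.fibers[0]
        true = truth.fibers[0]
        d = abs(fiber.orientation_deg - true.orientation_deg)
        assert min(d, 180 - d) < 2.0
        assert fiber.curvature_ratio < 1.01
        assert fiber.width_um == pytest.approx(5.0, rel=0.10)
        assert fiber.length_um == pytest.approx(true.length_um, rel=0.10)

    def test_batch_count_and_length_recovery(self, fiber_recovery_batch):
        pairs, counts = fiber_recovery_batch
        assert all(traced == true for true, traced in counts)
        rel_len = [abs(g.length_um - f.length_um) / f.length_um for f, g in pairs]
        assert np.median(rel_len) <= 0.10

    def test_missing_pixel_size_rejected(self):
        with pytest.raises(ValueError, match="pixel_size"):
            SHGImage(np.ones((8, 8)), 0.0)


class TestArchitectureSummary:
    def test_singleton_passthrough(self):
        image, truth = gen_fiber_image(
            FiberRenderSpec(n_fibers=1, width_um_range=(5, 5), length_um_range=(80, 80), seed=2)
        )
        s = architecture_summary(truth)
        assert s.n_fibers == 1
        assert s.mean_width_um == truth.fibers[0].width_um
        assert s.mean_length_um == truth.fibers[0].length_um

    def test_means_match_oracle(self):
        _, truth = gen_fiber_image(FiberRenderSpec(n_fibers=5, seed=3))
        s = architecture_summary(truth)
        widths = [f.width_um for f in truth]
        lengths = [f.length_um for f in truth]
        assert s.mean_width_um == pytest.approx(sum(widths) / len(widths), rel=1e-12)
        assert s.mean_length_um == pytest.approx(sum(lengths) / len(lengths), rel=1e-12)
        assert s.n_fibers == len(s.width_distribution) == 5

    def test_empty_set_rejected(self):
        from mechanoscape.fibers import FiberSet

        with pytest.raises(ValueError, match="no fibers"):
            architecture_summary(FiberSet([]))


class TestSiriusRed:
    def test_pure_red_and_pure_green(self):
        red = np.zeros((8, 8, 3))
        red[..., 0] = 1.0
        assert packed_fiber_fraction(red) == 100.0
        green = np.zeros((8, 8, 3))
        green[..., 1] = 1.0
        assert packed_fiber_fraction(green) == 0.0

    def test_known_coverage_recovered(self):
        img, true_pct = gen_sirius_red_image(coverage=0.30, seed=5)
        assert packed_fiber_fraction(img) == pytest.approx(true_pct, abs=1.0)

    @given(st.floats(min_value=0.2, max_value=5.0))
    def test_invariant_to_common_rescaling(self, factor):
        img, _ = gen_sirius_red_image(coverage=0.2, size_px=64, seed=6)
        assert packed_fiber_fraction(img * factor) == packed_fiber_fraction(img)

    def test_grayscale_rejected(self):
        with pytest.raises(ValueError, match="RGB"):
            packed_fiber_fraction(np.ones((8, 8)))


class TestSHGMaskAndCrosslinks:
    def test_binary_image_split(self):
        img = np.zeros((10, 10))
        img[3:6, 3:6] = 100.0
        mask = shg_positive_mask(SHGImage(img, 1.0))
        assert np.array_equal(mask, img == 100.0)

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            shg_positive_mask(SHGImage(np.zeros((8, 8)), 1.0))

    def test_bimodal_matches_exhaustive_cut(self):
        rng = np.random.default_rng(2)
        img = np.where(rng.random((40, 40)) < 0.5, rng.normal(20, 2, (40, 40)), rng.normal(200, 5, (40, 40)))
        img = np.clip(img, 0, None)
        shg = SHGImage(img, 1.0)
        mask = shg_positive_mask(shg)
        from skimage.filters import threshold_otsu

        cut = threshold_otsu(img[img > 0])
        assert np.array_equal(mask, img > cut)

    def test_uniform_signal_background_subtraction(self):
        fluor = np.full((6, 6), 100.0)
        mask = np.zeros((6, 6), bool)
        mask[2:4, 2:4] = True
        assert crosslink_fluorescence(fluor, mask, background=20.0) == 80.0
        assert crosslink_fluorescence(fluor, mask) == 100.0

    def test_masked_mean_matches_loop_oracle(self):
        rng = np.random.default_rng(8)
        fluor = rng.uniform(0, 50, (20, 20))
        mask = rng.random((20, 20)) < 0.3
        mask[0, 0] = True
        total, count = 0.0, 0
        for r in range(20):
            for c in range(20):
                if mask[r, c]:
                    total += fluor[r, c]
                    count += 1
        assert crosslink_fluorescence(fluor, mask, 5.0) == pytest.approx(
            total / count - 5.0, rel=1e-12
        )

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty mask"):
            crosslink_fluorescence(np.ones((4, 4)), np.zeros((4, 4), bool))


class TestTracerParams:
    def test_min_length_filter(self):
        # two fibers, one long and one short; raising min_length drops the short one
        spec = FiberRenderSpec(
            n_fibers=2,
            width_um_range=(4, 4),
            length_um_range=(30, 100),
            seed=12,
        )
        image, truth = gen_fiber_image(spec)
        lengths = sorted(f.length_um for f in truth)
        cut = (lengths[0] + lengths[1]) / 2
        n_all = len(trace_fibers(image, TracerParams(min_length_um=20.0)))
        n_cut = len(trace_fibers(image, TracerParams(min_length_um=cut)))
        assert n_all >= n_cut
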