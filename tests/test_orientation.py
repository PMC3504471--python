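"""Skeleton-based neurite orientation analysis and axial circular statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cortexclock import (
    KAPPA_CAP,
    GolgiSimSpec,
    OrientationSample,
    RasterImage,
    SegmentSet,
    bootstrap_kappa_ci,
    compare_regions,
    extract_segments,
    fit_von_mises,
    fit_with_ci,
    gen_axial_angles,
    gen_golgi_image,
    segment_polar_angles,
    skeletonize,
    value_histogram,
)
from cortexclock.errors import InsufficientDataError, InvalidInputError
from cortexclock.orientation import kappa_from_rbar


def _segments(pairs):
    return SegmentSet(segments=tuple(pairs), min_length_px=1.0)


class TestSkeletonize:
    def test_blank_image_gives_empty_skeleton(self):
        img = RasterImage(np.full((64, 64), 0.9))
        assert skeletonize(img).sum() == 0

    def test_bar_skeleton_length_close_to_bar_length(self):
        img = np.full((64, 128), 0.9)
        img[30:35, 10:110] = 0.1  # 5-px-wide, 100-px-long horizontal bar
        sk = skeletonize(RasterImage(img))
        assert sk.sum() == pytest.approx(100, rel=0.10)

    def test_polarity_flag_restores_skeleton(self):
        spec = GolgiSimSpec(image_size=(128, 128), n_segments=20, kappa=1.0, seed=4)
        image, _ = gen_golgi_image(spec)
        sk = skeletonize(image)
        sk_inv = skeletonize(RasterImage(1.0 - image.pixels), dark_foreground=False)
        assert np.array_equal(sk, sk_inv)

    def test_non_finite_image_rejected(self):
        with pytest.raises(InvalidInputError):
            RasterImage(np.array([[np.nan, 1.0], [0.0, 1.0]]))


class TestExtractSegments:
    def test_empty_skeleton(self):
        assert len(extract_segments(np.zeros((32, 32), bool))) == 0

    def test_single_straight_line_recovered(self):
        spec = GolgiSimSpec(
            image_size=(256, 256), n_segments=1, mu_deg=30.0, kappa=1e6,
            length_px=(120.0, 120.0), seed=3,
        )
        image, truth = gen_golgi_image(spec)
        sample = segment_polar_angles(extract_segments(skeletonize(image)))
        assert sample.n >= 1
        # all pieces of one straight stroke share its generating angle
        diffs = np.minimum(
            np.abs(sample.angles_deg - truth.angles_deg[0]),
            180 - np.abs(sample.angles_deg - truth.angles_deg[0]),
        )
        assert np.all(diffs < 2.0)

    def test_crossing_lines_yield_both_angles(self):
        img = np.full((200, 200), 0.9)
        rr = np.arange(30, 170)
        img[rr, rr] = 0.1  # 45 degrees
        img[rr, 200 - rr] = 0.1  # 135 degrees
        sample = segment_polar_angles(
            extract_segments(skeletonize(RasterImage(img)), min_length_px=20)
        )
        assert sample.n >= 2
        near45 = np.abs(sample.angles_deg - 45) < 3
        near135 = np.abs(sample.angles_deg - 135) < 3
        assert near45.any() and near135.any()
        assert (near45 | near135).all()

    def test_short_pieces_discarded(self):
        sk = np.zeros((32, 32), bool)
        sk[5, 5:10] = True  # 4-px chord
        assert len(extract_segments(sk, min_length_px=10)) == 0

    def test_curved_branch_subdivided(self):
        # quarter circle: a single chord would deviate far beyond 2 px
        sk = np.zeros((128, 128), bool)
        t = np.linspace(0, np.pi / 2, 400)
        rr = np.clip((100 - 80 * np.sin(t)).astype(int), 0, 127)
        cc = np.clip((20 + 80 * np.cos(t)).astype(int), 0, 127)
        sk[rr, cc] = True
        segs = extract_segments(sk, min_length_px=5, max_deviation_px=2.0)
        assert len(segs) >= 3


class TestPolarAngles:
    @pytest.mark.parametrize(
        ("p0", "p1", "radial_axis", "expected"),
        [
            ((0, 0), (10, 0), "vertical", 0.0),  # along rows = radial
            ((0, 0), (0, 10), "vertical", 90.0),
            ((0, 0), (0, 10), "horizontal", 0.0),
            ((10, 10), (0, 10), "vertical", 0.0),  # reversed direction folds
        ],
    )
    def test_reference_directions(self, p0, p1, radial_axis, expected):
        sample = segment_polar_angles(_segments([(p0, p1)]), radial_axis=radial_axis)
        assert sample.angles_deg[0] == pytest.approx(expected)

    def test_fold_identifies_theta_and_theta_plus_180(self):
        fwd = segment_polar_angles(_segments([((0, 0), (7, 3))]))
        rev = segment_polar_angles(_segments([((7, 3), (0, 0))]))
        assert fwd.angles_deg[0] == pytest.approx(rev.angles_deg[0])

    def test_zero_length_segment_excluded(self):
        sample = segment_polar_angles(_segments([((3, 3), (3, 3)), ((0, 0), (5, 0))]))
        assert sample.n == 1


class TestVonMisesFit:
    def test_uniform_sample_has_tiny_kappa(self):
        sample = gen_axial_angles(0.0, 0.0, 10_000, seed=0)
        assert fit_von_mises(sample).kappa < 0.05

    @pytest.mark.parametrize("kappa", [0.5, 1.41, 2.08, 3.0])
    def test_recovers_generating_kappa(self, kappa):
        sample = gen_axial_angles(40.0, kappa, 5000, seed=13)
        fit = fit_von_mises(sample)
        assert abs(fit.kappa - kappa) / kappa < 0.10
        assert abs(fit.mu_deg - 40.0) < 5.0

    def test_degenerate_sample_capped(self):
        fit = fit_von_mises(OrientationSample(np.full(50, 33.0)))
        assert fit.kappa == KAPPA_CAP
        assert fit.capped

    def test_below_floor_raises(self):
        with pytest.raises(InsufficientDataError):
            fit_von_mises(gen_axial_angles(0.0, 1.0, 5, seed=0))

    def test_matches_scipy_oracle(self):
        """Hand-authored Bessel-ratio inversion vs scipy's Von Mises MLE."""
        from scipy.stats import vonmises

        sample = gen_axial_angles(25.0, 1.8, 3000, seed=21)
        doubled = 2.0 * np.radians(sample.angles_deg)
        kappa_scipy, _, _ = vonmises.fit(doubled, fscale=1)
        assert fit_von_mises(sample).kappa == pytest.approx(kappa_scipy, rel=0.01)

    def test_kappa_monotone_in_resultant_length(self):
        rbars = np.linspace(0.0, 0.999, 200)
        kappas = kappa_from_rbar(rbars)
        assert np.all(np.diff(kappas) >= 0)

    def test_rotation_equivariance(self):
        spec = GolgiSimSpec(image_size=(512, 512), n_segments=200, mu_deg=20.0,
                            kappa=2.0, seed=8)
        image, _ = gen_golgi_image(spec)

        def fit_image(px):
            segs = extract_segments(skeletonize(RasterImage(px)))
            return fit_von_mises(segment_polar_angles(segs))

        base = fit_image(image.pixels)
        rot = fit_image(np.rot90(image.pixels))
        shift = (rot.mu_deg - base.mu_deg) % 180.0
        assert abs(shift - 90.0) < 5.0
        assert rot.kappa == pytest.approx(base.kappa, rel=0.15)


class TestBootstrap:
    def test_same_seed_identical_interval(self):
        sample = gen_axial_angles(10.0, 1.41, 500, seed=3)
        assert bootstrap_kappa_ci(sample, 1000, seed=5) == bootstrap_kappa_ci(
            sample, 1000, seed=5
        )

    def test_interval_contains_generating_kappa(self):
        sample = gen_axial_angles(10.0, 1.41, 500, seed=3)
        low, high = bootstrap_kappa_ci(sample, 1000, seed=5)
        assert low < 1.41 < high

    def test_interval_brackets_point_estimate(self):
        sample = gen_axial_angles(10.0, 2.0, 400, seed=6)
        fit = fit_with_ci(sample, n_boot=1000, seed=7)
        assert fit.ci_95[0] <= fit.kappa <= fit.ci_95[1]

    def test_too_few_replicates_rejected(self):
        sample = gen_axial_angles(10.0, 1.0, 100, seed=0)
        with pytest.raises(InvalidInputError):
            bootstrap_kappa_ci(sample, n_boot=50)


class TestCompareRegions:
    def test_disjoint_intervals_flagged(self):
        a = fit_with_ci(gen_axial_angles(0.0, 2.08, 2000, seed=1), seed=2)
        b = fit_with_ci(gen_axial_angles(0.0, 0.7, 2000, seed=3), seed=4)
        cmp = compare_regions(a, b)
        assert cmp["kappa_diff"] > 0
        assert cmp["ci_disjoint"]

    def test_identical_fits_not_disjoint(self):
        a = fit_with_ci(gen_axial_angles(0.0, 1.5, 1000, seed=1), seed=2)
        cmp = compare_regions(a, a)
        assert cmp["kappa_diff"] == 0.0
        assert not cmp["ci_disjoint"]

    def test_missing_ci_rejected(self):
        a = fit_von_mises(gen_axial_angles(0.0, 1.5, 1000, seed=1))
        with pytest.raises(InvalidInputError):
            compare_regions(a, a)


class TestHistogram:
    def test_small_example(self):
        edges, counts = value_histogram([0.1, 0.1, 0.9], bin_width=0.5)
        assert counts.tolist() == [2, 1]
        assert edges[0] == pytest.approx(0.1)

    @given(
        values=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=200),
        bin_width=st.floats(0.01, 0.7),
    )
    def test_counts_conserved(self, values, bin_width):
        _, counts = value_histogram(values, bin_width)
        assert counts.sum() == len(values)

    def test_empty_input(self):
        edges, counts = value_histogram([], 0.1)
        assert edges.size == 0 and counts.size == 0

    def test_uniform_sample_near_flat(self):
        rng = np.random.default_rng(0)
        _, counts = value_histogram(rng.uniform(0, 1, 100_000), 0.1, vmin=0, vmax=1)
        assert counts.min() > 0.9 * counts.mean()
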