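"""Wavelet bandpass, colocalization statistics and vesicle counts."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from srphos import coloc, synthetic


def full_roi(shape=(8, 8)):
    return np.ones(shape, dtype=bool)


class TestAtrous:
    def test_constant_image_has_zero_detail(self):
        img = np.full((64, 64), 3.7)
        planes, smooth = coloc.atrous_decompose(img, 3)
        for p in planes:
            np.testing.assert_allclose(p, 0.0, atol=1e-12)
        out = coloc.atrous_bandpass(img, 3)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_exact_reconstruction(self, rng):
        for _ in range(5):
            img = rng.random((70, 90))
            planes, smooth = coloc.atrous_decompose(img, 4)
            recon = np.sum(planes, axis=0) + smooth
            assert np.abs(recon - img).max() < 1e-9

    def test_impulse_energy_in_finest_plane(self):
        img = np.zeros((64, 64))
        img[32, 32] = 1.0
        planes, _ = coloc.atrous_decompose(img, 4)
        peak_per_plane = [p[32, 32] for p in planes]
        assert peak_per_plane[0] == max(peak_per_plane)
        # dropping the finest plane attenuates the impulse
        out = coloc.atrous_bandpass(img, 4, drop_finest=1)
        assert out[32, 32] < img[32, 32]

    def test_finest_plane_matches_direct_convolution(self):
        """w_1 = img - img * B3 (separable), computed independently."""
        rng = np.random.default_rng(4)
        img = rng.random((40, 40))
        planes, _ = coloc.atrous_decompose(img, 2)
        from scipy.ndimage import convolve1d

        k = np.array([1, 4, 6, 4, 1]) / 16.0
        smooth = convolve1d(convolve1d(img, k, axis=0, mode="mirror"),
                            k, axis=1, mode="mirror")
        np.testing.assert_allclose(planes[0], img - smooth, atol=1e-12)

    def test_too_small_image_rejected(self):
        with pytest.raises(ValueError, match="support"):
            coloc.atrous_decompose(np.zeros((16, 16)), 4)


class TestNormalize01:
    @pytest.mark.parametrize("value, expected", [(255, 1.0), (0, 0.0), (51, 0.2)])
    def test_eight_bit_mapping(self, value, expected):
        out = coloc.normalize01(np.array([[value]], dtype=np.uint8))
        assert out[0, 0] == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            coloc.normalize01(np.array([[300]]), bit_depth=8)


class TestExpressionAndOverlapFraction:
    def test_expression_fraction_hand_counts(self):
        ch = np.zeros((3, 4))
        ch[0, :3] = 0.5  # 3 positive of 12
        assert coloc.expression_fraction(ch, full_roi((3, 4))) == 0.25
        assert coloc.expression_fraction(np.ones((3, 4)), full_roi((3, 4))) == 1.0
        half = np.zeros((2, 4))
        half[0] = 1.0
        assert coloc.expression_fraction(half, full_roi((2, 4))) == 0.5

    def test_overlap_fraction_four_pixel_example(self):
        """A positive on pixels {1,2}, B on {2,3} -> product positive on 1
        of 4 ROI pixels."""
        a = np.array([[0.0, 0.4, 0.6, 0.0]])
        b = np.array([[0.0, 0.0, 0.5, 0.7]])
        assert coloc.overlap_fraction(a, b, full_roi((1, 4))) == 0.25

    def test_overlap_fraction_extremes_and_symmetry(self, rng):
        a = rng.random((6, 6)) + 0.1
        assert coloc.overlap_fraction(a, a, full_roi((6, 6))) == 1.0
        b = np.zeros_like(a)
        b[:3] = a[:3]
        a2 = a.copy()
        a2[:3] = 0.0
        assert coloc.overlap_fraction(a2, b, full_roi((6, 6))) == 0.0
        c = rng.random((6, 6)) * (rng.random((6, 6)) > 0.5)
        assert coloc.overlap_fraction(a, c, full_roi((6, 6))) == coloc.overlap_fraction(
            c, a, full_roi((6, 6))
        )

    def test_scaling_leaves_of_unchanged(self, rng):
        a = rng.random((6, 6)) * (rng.random((6, 6)) > 0.4)
        b = rng.random((6, 6)) * (rng.random((6, 6)) > 0.4)
        roi = full_roi((6, 6))
        assert coloc.overlap_fraction(a, b, roi) == coloc.overlap_fraction(
            3.2 * a, 0.5 * b, roi
        )

    def test_validation(self):
        with pytest.raises(ValueError, match="empty ROI"):
            coloc.expression_fraction(np.ones((2, 2)), np.zeros((2, 2)))
        with pytest.raises(ValueError, match="shapes differ"):
            coloc.overlap_fraction(np.ones((2, 2)), np.ones((3, 3)), full_roi((2, 2)))


class TestCostes:
    def test_identical_channels_thresholds_fall_to_min_positive(self):
        rng = np.random.default_rng(0)
        a = np.zeros((40, 40))
        idx = rng.random((40, 40)) > 0.7
        a[idx] = rng.uniform(0.2, 1.0, size=idx.sum())
        t_a, t_b = coloc.costes_threshold(a, a, full_roi((40, 40)))
        min_pos = a[a > 0].min()
        assert t_a <= min_pos + 1 / 255 + 1e-9

    def test_anticorrelated_channels_stop_at_first_step(self):
        rng = np.random.default_rng(1)
        a = rng.random((30, 30))
        b = 1.0 - a
        t_a, _ = coloc.costes_threshold(a, b, full_roi((30, 30)))
        assert t_a == pytest.approx(min(a.max(), 1.0))

    def test_independent_noise_classifies_almost_all_as_background(self):
        rng = np.random.default_rng(2)
        a = rng.random((80, 80))
        b = rng.random((80, 80))
        t_a, t_b = coloc.costes_threshold(a, b, full_roi((80, 80)))
        coloc_frac = ((a > t_a) & (b > t_b)).mean()
        assert 1.0 - coloc_frac >= 0.95

    def test_constant_channel_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            coloc.costes_threshold(
                np.ones((10, 10)), np.random.default_rng(0).random((10, 10)),
                full_roi((10, 10)),
            )


class TestManders:
    def test_worked_example(self):
        a = np.array([[0.5, 0.5]])
        b = np.array([[0.5, 0.0]])
        m1, m2 = coloc.manders(a, b, full_roi((1, 2)), 0.0, 0.0)
        assert m1 == pytest.approx(0.5)
        assert m2 == pytest.approx(1.0)

    def test_identical_and_disjoint(self, rng):
        a = rng.random((5, 5)) + 0.1
        assert coloc.manders(a, a, full_roi((5, 5)), 0, 0) == (1.0, 1.0)
        b = np.zeros_like(a)
        b[:2] = 1.0
        a2 = a.copy()
        a2[:2] = 0.0
        assert coloc.manders(a2, b, full_roi((5, 5)), 0, 0) == (0.0, 0.0)

    def test_swap_symmetry(self, rng):
        a = rng.random((6, 6)) * (rng.random((6, 6)) > 0.3)
        b = rng.random((6, 6)) * (rng.random((6, 6)) > 0.3)
        roi = full_roi((6, 6))
        m1, m2 = coloc.manders(a, b, roi, 0.1, 0.2)
        m2s, m1s = coloc.manders(b, a, roi, 0.2, 0.1)
        assert m1 == pytest.approx(m1s) and m2 == pytest.approx(m2s)

    def test_scaling_with_matched_thresholds(self, rng):
        a = rng.random((6, 6))
        b = rng.random((6, 6))
        roi = full_roi((6, 6))
        m = coloc.manders(a, b, roi, 0.3, 0.4)
        ms = coloc.manders(2.0 * a, 5.0 * b, roi, 0.6, 2.0)
        assert m == pytest.approx(ms)

    def test_zero_denominator_defined_as_zero(self):
        z = np.zeros((3, 3))
        assert coloc.manders(z, z, full_roi((3, 3)), 0, 0) == (0.0, 0.0)


class TestMeasuredAgainstGeneratorTruth:
    def test_noiseless_images_recover_truth(self):
        img, roi, truth = synthetic.gen_coloc_images(
            overlap_target=0.5, noise_sd=0.0, seed=5
        )
        a = coloc.normalize01(img[0])
        b = coloc.normalize01(img[1])
        m1, m2 = coloc.manders(a, b, roi, 0.0, 0.0)
        assert abs(m1 - truth.true_m1) < 0.02
        assert abs(m2 - truth.true_m2) < 0.02
        of = coloc.overlap_fraction(a, b, roi)
        assert abs(of - truth.true_overlap_fraction) < 0.02

    def test_noisy_images_with_bandpass_and_costes(self):
        img, roi, truth = synthetic.gen_coloc_images(
            overlap_target=0.5, noise_sd=0.1, seed=5
        )
        a = np.clip(coloc.atrous_bandpass(coloc.normalize01(img[0])), 0, None)
        b = np.clip(coloc.atrous_bandpass(coloc.normalize01(img[1])), 0, None)
        t_a, t_b = coloc.costes_threshold(a, b, roi)
        m1, m2 = coloc.manders(a, b, roi, t_a, t_b)
        assert abs(m1 - truth.true_m1) < 0.05
        assert abs(m2 - truth.true_m2) < 0.05


class TestTripleOverlap:
    def test_identical_channels_give_one(self, rng):
        a = rng.random((40, 40)) + 0.1
        out = coloc.triple_overlap(a, a, a, full_roi((40, 40)), use_costes=False)
        assert out == pytest.approx(1.0)

    def test_disjoint_green_gives_zero(self, rng):
        r = np.zeros((40, 40))
        r[:20] = rng.random((20, 40)) + 0.1
        g = np.zeros((40, 40))
        g[20:] = rng.random((20, 40)) + 0.1
        out = coloc.triple_overlap(r, r, g, full_roi((40, 40)), use_costes=False)
        assert out == 0.0

    def test_half_overlap_fixture(self):
        """50% of the R*F puncta share centres with G."""
        img, roi, _ = synthetic.gen_coloc_images(
            shape=(192, 192), n_puncta=60, overlap_target=0.5,
            noise_sd=0.0, seed=6,
        )
        r = coloc.normalize01(img[0])
        g = coloc.normalize01(img[1])
        out = coloc.triple_overlap(r, r, g, roi, use_costes=False)
        assert abs(out - 0.5) < 0.05


class TestVesiclesAndTrafficking:
    def test_blob_counting_and_ratio(self):
        img = np.zeros((32, 32), dtype=np.uint8)
        img[2:4, 2:4] = 200
        img[10:12, 10:13] = 120
        img[20, 20] = 60
        out = coloc.count_vesicles(img, nuclei_count=2)
        assert out["n_objects"] == 3
        assert out["ratio_per_nucleus"] == 1.5

    def test_blank_image_and_boundary_intensity(self):
        assert coloc.count_vesicles(np.zeros((8, 8)), 1)["n_objects"] == 0
        at50 = np.full((8, 8), 50, dtype=np.uint8)
        assert coloc.count_vesicles(at50, 1)["n_objects"] == 0  # strict >

    def test_min_size_filter_and_validation(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        img[0, 0] = 255  # single-pixel object
        img[8:11, 8:11] = 255
        assert coloc.count_vesicles(img, 1, min_size=2)["n_objects"] == 1
        with pytest.raises(ValueError, match="nuclei"):
            coloc.count_vesicles(img, 0)

    def test_trafficking_percentages(self):
        counts = pd.DataFrame(
            {
                "timepoint_min": [0, 40, 120],
                "positive": [80, 50, 0],
                "nuclei": [100, 100, 90],
            }
        )
        out = coloc.trafficking_percentages(counts)
        assert out.loc[0, "relative_pct"] == 100.0
        assert out.loc[1, "relative_pct"] == pytest.approx(62.5)
        assert out.loc[2, "relative_pct"] == 0.0

    def test_trafficking_validation(self):
        bad = pd.DataFrame(
            {"timepoint_min": [0], "positive": [5], "nuclei": [0]}
        )
        with pytest.raises(ValueError, match="nuclei"):
            coloc.trafficking_percentages(bad)
        no_t0 = pd.DataFrame(
            {"timepoint_min": [40], "positive": [5], "nuclei": [10]}
        )
        with pytest.raises(ValueError, match="time"):
            coloc.trafficking_percentages(no_t0)


@settings(max_examples=50, deadline=None)
@given(
    a=arrays(np.float64, (6, 6), elements=st.floats(0, 1)),
    b=arrays(np.float64, (6, 6), elements=st.floats(0, 1)),
    t_a=st.floats(0, 1),
    t_b=st.floats(0, 1),
)
def test_coefficients_always_in_unit_interval(a, b, t_a, t_b):
    roi = np.ones((6, 6), dtype=bool)
    of = coloc.overlap_fraction(a, b, roi)
    m1, m2 = coloc.manders(a, b, roi, t_a, t_b)
    ef = coloc.expression_fraction(a, roi)
    for v in (of, m1, m2, ef):
        assert 0.0 <= v <= 1.0
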