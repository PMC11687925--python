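"""Histograms, the Kapur objective and threshold-based segmentation."""

import numpy as np
import pytest

from kapurseg import (
    BitDepthMismatchError,
    GrayHistogram,
    GrayImage,
    KapurObjective,
    MixtureSpec,
    ThresholdSet,
    compute_histogram,
    generate_synthetic_image,
    kapur_entropy,
    rebin_histogram,
    remap_bit_depth,
    render_segmented,
    segment_image,
)


def naive_kapur(probs, thresholds, levels):
    """Direct double-loop reference for the Kapur objective."""
    edges = [0, *thresholds, levels]
    total = 0.0
    for k in range(len(edges) - 1):
        cls = probs[edges[k]:edges[k + 1]]
        w = cls.sum()
        if w == 0:
            continue
        h = 0.0
        for p in cls:
            if p > 0:
                h -= (p / w) * np.log(p / w)
        total += h
    return total


class TestComputeHistogram:
    def test_small_example(self):
        img = GrayImage(pixels=np.array([[0, 0], [1, 3]]), bit_depth=2)
        hist = compute_histogram(img)
        assert hist.counts.tolist() == [2, 1, 0, 1]
        assert hist.probs.tolist() == [0.5, 0.25, 0.0, 0.25]

    def test_constant_image_single_bin(self):
        img = GrayImage(pixels=np.full((5, 4), 7), bit_depth=4)
        hist = compute_histogram(img)
        assert hist.probs[7] == 1.0
        assert hist.probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_bit_depth_mismatch_rejected(self):
        with pytest.raises(BitDepthMismatchError):
            GrayImage(pixels=np.array([[0, 4]]), bit_depth=2)

    def test_matches_mixture_density_within_binomial_bands(self):
        # empirical mass per coarse bin vs the generator's analytic mixture,
        # +/- 3 sigma binomial bands at 65536 samples (64 bins keeps the
        # expected number of chance 3-sigma excursions well below one)
        spec = MixtureSpec(
            modes=((1000.0, 150.0, 0.5), (3000.0, 150.0, 0.5)), seed=42
        )
        img = generate_synthetic_image(spec)
        hist = rebin_histogram(compute_histogram(img), 64)
        analytic = spec.analytic_bin_probs().reshape(64, -1).sum(axis=1)
        n = img.pixels.size
        sigma = np.sqrt(analytic * (1 - analytic) / n)
        assert np.all(np.abs(hist.probs - analytic) <= 3 * sigma + 1e-12)


class TestRemapBitDepth:
    @pytest.mark.parametrize(
        "value,source,target,expected",
        [(255, 8, 12, 4080), (0, 8, 12, 0), (100, 8, 8, 100)],
    )
    def test_left_shift(self, value, source, target, expected):
        img = GrayImage(pixels=np.array([[value]]), bit_depth=source)
        out = remap_bit_depth(img, target)
        assert out.pixels[0, 0] == expected
        assert out.bit_depth == target

    def test_downscale_rejected(self):
        img = GrayImage(pixels=np.array([[0]]), bit_depth=12)
        with pytest.raises(ValueError):
            remap_bit_depth(img, 8)


class TestKapurEntropy:
    @pytest.mark.parametrize("n_thresholds", [1, 3, 7])
    def test_uniform_equal_split_closed_form(self, uniform_hist_64, n_thresholds):
        # equal classes of m bins give entropy ln(m) each
        step = 64 // (n_thresholds + 1)
        ts = ThresholdSet(tuple(step * (i + 1) for i in range(n_thresholds)), 64)
        expected = (n_thresholds + 1) * np.log(64 / (n_thresholds + 1))
        assert kapur_entropy(uniform_hist_64, ts) == pytest.approx(expected, abs=1e-10)

    def test_point_mass_is_zero(self):
        counts = np.zeros(16, dtype=int)
        counts[5] = 10
        hist = GrayHistogram(counts=counts, levels=16)
        for th in [(1,), (5,), (3, 9), (1, 5, 12)]:
            assert kapur_entropy(hist, ThresholdSet(th, 16)) == 0.0

    def test_matches_double_loop_reference(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            counts = rng.integers(0, 50, size=16)
            counts[rng.integers(0, 16)] += 1  # ensure non-empty
            hist = GrayHistogram(counts=counts, levels=16)
            n = rng.integers(1, 5)
            th = tuple(sorted(rng.choice(np.arange(1, 16), size=n, replace=False)))
            ts = ThresholdSet(th, 16)
            assert kapur_entropy(hist, ts) == pytest.approx(
                naive_kapur(hist.probs, th, 16), abs=1e-10
            )

    def test_objective_vectorised_agrees_with_scalar(self, bimodal_hist_64):
        obj = KapurObjective(bimodal_hist_64)
        batch = np.array([[10, 30], [20, 40], [5, 60]])
        vals = obj.evaluate_many(batch)
        for row, v in zip(batch, vals):
            assert v == kapur_entropy(bimodal_hist_64, ThresholdSet(tuple(row), 64))

    def test_non_negative_and_finite_for_degenerate_placements(self, bimodal_hist_64):
        # adjacent thresholds create near-empty classes; objective stays finite
        v = kapur_entropy(bimodal_hist_64, ThresholdSet((1, 2, 3, 63), 64))
        assert np.isfinite(v) and v >= 0


class TestSegmentImage:
    def test_single_threshold(self):
        img = GrayImage(pixels=np.array([[0, 3], [5, 7]]), bit_depth=3)
        labels = segment_image(img, ThresholdSet((4,), 8))
        assert labels.tolist() == [[0, 0], [1, 1]]

    def test_constant_zero_image(self):
        img = GrayImage(pixels=np.zeros((3, 3), dtype=int), bit_depth=3)
        assert segment_image(img, ThresholdSet((1,), 8)).max() == 0

    def test_interval_convention(self):
        # class k covers [th_k, th_{k+1} - 1]
        img = GrayImage(pixels=np.array([[3, 4, 8, 9, 15]]), bit_depth=4)
        labels = segment_image(img, ThresholdSet((4, 9), 16))
        assert labels.tolist() == [[0, 1, 1, 2, 2]]


class TestRenderSegmented:
    def test_constant_image_identity_under_class_mean(self):
        img = GrayImage(pixels=np.full((4, 4), 6), bit_depth=3)
        out = render_segmented(img, ThresholdSet((4,), 8), mode="class_mean")
        assert np.array_equal(out.pixels, img.pixels)

    def test_class_mean_round_half_up(self):
        img = GrayImage(pixels=np.array([[0, 3], [5, 7]]), bit_depth=3)
        out = render_segmented(img, ThresholdSet((4,), 8), mode="class_mean")
        assert out.pixels.tolist() == [[2, 2], [6, 6]]

    def test_class_midpoint(self):
        img = GrayImage(pixels=np.array([[0, 15]]), bit_depth=4)
        out = render_segmented(img, ThresholdSet((8,), 16), mode="class_midpoint")
        assert out.pixels.tolist() == [[4, 12]]

    def test_segment_render_idempotent(self, small_image_8bit):
        ts = ThresholdSet((40, 120, 200), 256)
        rendered = render_segmented(small_image_8bit, ts)
        labels_orig = segment_image(small_image_8bit, ts)
        labels_again = segment_image(rendered, ts)
        assert np.array_equal(labels_orig, labels_again)

    def test_unknown_mode_rejected(self, small_image_8bit):
        with pytest.raises(ValueError):
            render_segmented(small_image_8bit, ThresholdSet((128,), 256), mode="nope")
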