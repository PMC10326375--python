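"""Spot-detection pipeline: filtering, thresholding, labeling, accuracy."""

import numpy as np
import pytest
from scipy import ndimage

from aggrekit.detect import (
    DetectionParams,
    counting_accuracy,
    detect_spots,
    kernel_convolve,
    morphological_clean,
    threshold_mask,
    tophat_background_suppress,
)
from aggrekit.sim.diffraction import DLSimParams, simulate_dl


def _gauss_dot(size, cx, cy, sigma, amp):
    yy, xx = np.mgrid[0:size, 0:size]
    return amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))


class TestTophat:
    def test_constant_frame_maps_to_zero(self):
        out = tophat_background_suppress(np.full((64, 64), 123.0), radius=10)
        assert np.allclose(out, 0.0)

    def test_bright_dot_preserved(self):
        frame = 100.0 + _gauss_dot(64, 32, 32, 2.0, 500.0)
        out = tophat_background_suppress(frame, radius=10)
        assert abs(out.max() - 500.0) / 500.0 < 0.01

    def test_smooth_gradient_suppressed(self):
        # a wide linear ramp has no structure smaller than the element
        frame = np.tile(np.linspace(0, 1000, 128), (128, 1))
        out = tophat_background_suppress(frame, radius=10)
        assert out.max() < 0.2 * 1000

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            tophat_background_suppress(np.zeros((8, 8)), radius=0)


class TestKernelConvolve:
    def test_delta_impulse_reproduces_kernel(self):
        frame = np.zeros((33, 33))
        frame[16, 16] = 1.0
        out = kernel_convolve(frame, DetectionParams(kernel="gaussian"))
        # the response is the (flipped, symmetric) kernel: unit total mass
        assert abs(out.sum() - 1.0) < 1e-9
        assert np.unravel_index(np.argmax(out), out.shape) == (16, 16)

    def test_ricker_zero_sum_on_white_noise(self, rng):
        frame = rng.normal(0, 1, (64, 64))
        out = kernel_convolve(frame, DetectionParams(kernel="ricker"))
        assert abs(out.mean()) < 0.05

    def test_matched_filter_peaks_at_dot_centre(self):
        frame = _gauss_dot(32, 15, 17, 1.5, 100.0)
        out = kernel_convolve(frame, DetectionParams(kernel="ricker", kernel_width=1.5))
        y, x = np.unravel_index(np.argmax(out), out.shape)
        assert (y, x) == (17, 15)

    def test_against_bruteforce_convolution(self, rng):
        # direct O(n^2 k^2) convolution oracle on a small frame
        from aggrekit.detect import _ricker_kernel

        frame = rng.normal(0, 1, (20, 20))
        kern = _ricker_kernel(1.5)
        out = kernel_convolve(frame, DetectionParams(kernel="ricker", kernel_width=1.5))
        kh = kern.shape[0] // 2
        padded = np.pad(frame, kh, mode="symmetric")  # edge-repeating reflection
        expect = np.empty_like(frame)
        for y in range(20):
            for x in range(20):
                patch = padded[y:y + 2 * kh + 1, x:x + 2 * kh + 1]
                expect[y, x] = np.sum(patch * kern[::-1, ::-1])
        assert np.allclose(out, expect, atol=1e-10)

    def test_unknown_kernel_rejected(self):
        with pytest.raises(ValueError):
            kernel_convolve(np.zeros((8, 8)), DetectionParams(kernel="boxcar"))


class TestThresholdMask:
    def test_constant_frame_empty_mask(self):
        assert not threshold_mask(np.full((16, 16), 5.0), 2.0).any()

    def test_single_outlier_pixel_isolated(self):
        frame = np.zeros((50, 50))
        frame[25, 25] = 1000.0
        mask = threshold_mask(frame, 2.0)
        assert mask.sum() == 1 and mask[25, 25]

    def test_monotone_in_k(self, rng):
        frame = rng.normal(0, 1, (64, 64))
        m1 = threshold_mask(frame, 1.0)
        m2 = threshold_mask(frame, 2.0)
        m3 = threshold_mask(frame, 3.0)
        assert (m2 <= m1).all() and (m3 <= m2).all()


class TestMorphologicalClean:
    def test_isolated_pixel_removed(self):
        mask = np.zeros((16, 16), dtype=bool)
        mask[8, 8] = True
        assert not morphological_clean(mask, 1).any()

    def test_large_block_unchanged(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True
        assert np.array_equal(morphological_clean(mask, 1), mask)

    def test_zero_size_is_identity(self, rng):
        mask = rng.random((16, 16)) > 0.5
        assert np.array_equal(morphological_clean(mask, 0), mask)


def _floodfill_labels(mask):
    """Oracle: 8-connected components by explicit BFS flood fill."""
    labels = np.zeros(mask.shape, dtype=int)
    current = 0
    for y0, x0 in np.argwhere(mask):
        if labels[y0, x0]:
            continue
        current += 1
        stack = [(y0, x0)]
        labels[y0, x0] = current
        while stack:
            y, x = stack.pop()
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < mask.shape[0] and 0 <= nx < mask.shape[1] \
                            and mask[ny, nx] and not labels[ny, nx]:
                        labels[ny, nx] = current
                        stack.append((ny, nx))
    return labels, current


class TestDetectSpots:
    def test_pure_noise_frame_counts_zero(self):
        _, noisy, _ = simulate_dl(DLSimParams(n_dots=0, seed=21))
        assert detect_spots(noisy).count == 0

    def test_single_dot_found_at_centre(self):
        p = DLSimParams(n_dots=1, image_size=512, seed=2)
        _, noisy, truth = simulate_dl(p, centers=np.array([[256.0, 256.0]]))
        ps = detect_spots(noisy)
        assert ps.count == 1
        cx, cy = ps.particles[0].centroid
        assert abs(cx - 256.0) < 1.0 and abs(cy - 256.0) < 1.0

    def test_edge_particles_excluded(self):
        # a dot whose centroid lies inside the 5-px margin must be dropped
        p = DLSimParams(n_dots=2, image_size=512, seed=2, baseline_sd=50.0)
        centers = np.array([[3.0, 256.0], [256.0, 256.0]])
        _, noisy, _ = simulate_dl(p, centers=centers)
        ps = detect_spots(noisy)
        assert ps.count == 1
        assert abs(ps.particles[0].centroid[0] - 256.0) < 2

    def test_fractional_edge_margin_mode(self):
        params = DetectionParams(edge_margin_mode="fraction")
        from aggrekit.detect import _edge_margin
        assert _edge_margin(params, 512) == int(np.ceil(0.02 * 512))

    def test_label_conservation(self):
        _, noisy, _ = simulate_dl(DLSimParams(n_dots=40, image_size=256, seed=31))
        ps = detect_spots(noisy)
        from aggrekit.detect import (
            kernel_convolve as kc,
            morphological_clean as mc,
            threshold_mask as tm,
            tophat_background_suppress as th,
        )
        d = DetectionParams()
        mask = mc(tm(kc(th(noisy, 10), d), d.threshold_k), d.erosion_size)
        assert sum(p.area for p in ps.particles) <= mask.sum()

    def test_labels_match_floodfill_oracle(self, rng):
        for _ in range(5):
            mask = ndimage.binary_opening(rng.random((48, 48)) > 0.6)
            labels, n = ndimage.label(mask, structure=np.ones((3, 3), bool))
            oracle, n_o = _floodfill_labels(mask)
            assert n == n_o
            # identical partitions up to label renaming
            pairs = set(zip(labels[mask], oracle[mask]))
            assert len(pairs) == n == len({a for a, _ in pairs}) == len({b for _, b in pairs})

    def test_snr_monotonicity_on_matched_seeds(self):
        from aggrekit.detect import counting_accuracy
        from aggrekit.sim.diffraction import snr_to_peak_mean

        accs = {}
        for snr in (0.25, 4.0):
            vals = []
            for seed in (60, 61):
                p = DLSimParams(n_dots=300, peak_mean=snr_to_peak_mean(snr),
                                snr_mask=True, seed=seed)
                _, noisy, truth = simulate_dl(p)
                vals.append(counting_accuracy(detect_spots(noisy).count, truth.true_count))
            accs[snr] = np.mean(vals)
        assert accs[4.0] >= accs[0.25]


class TestCountingAccuracy:
    @pytest.mark.parametrize("measured,true,expect", [
        (300, 300, 100.0),
        (270, 300, 90.0),
        (330, 300, 90.0),   # symmetric over-count
        (600, 300, 0.0),
        (700, 300, pytest.approx(-100 / 3, abs=1e-9)),
    ])
    def test_formula(self, measured, true, expect):
        assert counting_accuracy(measured, true) == pytest.approx(expect)

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            counting_accuracy(5, 0)
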