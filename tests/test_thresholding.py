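"""Renyi-entropy thresholding against an exhaustive-scan oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ciliaq import (
    Histogram,
    ImageStack,
    apply_threshold,
    max_project,
    renyi_entropy_threshold,
    segment_marker,
)
from ciliaq.thresholding import DegenerateHistogramError, renyi_entropy_level

from conftest import renyi_oracle


class TestMaxProject:
    def test_single_slice_is_identity(self, calibration):
        rng = np.random.default_rng(0)
        plane = rng.integers(0, 100, size=(1, 8, 8))
        stack = ImageStack(plane[None, None], calibration)
        np.testing.assert_array_equal(max_project(stack, 0), plane[0])

    def test_constant_slices_project_to_constant(self, calibration):
        stack = ImageStack(np.full((1, 1, 5, 4, 4), 7.0), calibration)
        np.testing.assert_array_equal(max_project(stack, 0), np.full((4, 4), 7.0))

    def test_matches_per_pixel_loop_oracle(self, calibration):
        rng = np.random.default_rng(1)
        vol = rng.integers(0, 255, size=(4, 8, 8))
        stack = ImageStack(vol[None, None], calibration)
        projected = max_project(stack, 0)
        for y in range(8):
            for x in range(8):
                assert projected[y, x] == max(vol[z, y, x] for z in range(4))

    def test_invalid_channel_raises(self, two_channel_stack):
        with pytest.raises(IndexError):
            max_project(two_channel_stack, 5)


class TestRenyiEntropyThreshold:
    def test_two_point_histogram_separates_the_modes(self):
        counts = np.zeros(256, dtype=int)
        counts[0] = counts[255] = 1000
        hist = Histogram(counts, np.arange(257, dtype=float))
        threshold = renyi_entropy_threshold(hist)
        assert 0 < threshold < 255  # strictly between the occupied bins

    def test_bimodal_mixture_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(123)
        samples = np.concatenate(
            [rng.normal(50, 10, 1000), rng.normal(200, 10, 1000)]
        )
        hist = Histogram.from_image(samples)
        level = renyi_entropy_level(hist.counts)
        assert level == renyi_oracle(hist.counts)
        threshold = renyi_entropy_threshold(hist)
        assert hist.bin_edges[0] < threshold < hist.bin_edges[-1]
        # threshold separates the two modes
        assert 80 < threshold < 170

    def test_uniform_histogram_matches_oracle(self):
        counts = np.full(256, 10, dtype=int)
        hist = Histogram(counts, np.arange(257, dtype=float))
        assert renyi_entropy_level(counts) == renyi_oracle(counts)

    @pytest.mark.parametrize("seed", range(20))
    def test_seeded_random_histograms_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        kind = seed % 3
        if kind == 0:  # bimodal gaussian mixture
            mus = rng.uniform(20, 235, size=2)
            samples = np.concatenate(
                [rng.normal(mus[0], rng.uniform(3, 20), 800),
                 rng.normal(mus[1], rng.uniform(3, 20), 800)]
            )
            counts, _ = np.histogram(np.clip(samples, 0, 255), bins=256, range=(0, 255))
        elif kind == 1:  # background-dominated with a bright tail
            dark = rng.poisson(15, 5000)
            bright = rng.normal(180, 30, 100)
            counts, _ = np.histogram(
                np.concatenate([dark, np.clip(bright, 0, 255)]),
                bins=256, range=(0, 255),
            )
        else:  # arbitrary sparse counts
            counts = rng.integers(0, 50, size=256)
        if (counts > 0).sum() < 2:
            pytest.skip("degenerate draw")
        assert renyi_entropy_level(counts) == renyi_oracle(counts)

    def test_single_occupied_bin_is_an_error(self):
        counts = np.zeros(256, dtype=int)
        counts[42] = 10
        with pytest.raises(DegenerateHistogramError):
            renyi_entropy_level(counts)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_depends_only_on_histogram_shape(self, seed):
        """Permuting pixel positions never changes the threshold."""
        rng = np.random.default_rng(seed)
        image = rng.integers(0, 256, size=200)
        h1 = Histogram.from_image(image)
        h2 = Histogram.from_image(rng.permutation(image))
        if (h1.counts > 0).sum() < 2:
            return
        assert renyi_entropy_threshold(h1) == renyi_entropy_threshold(h2)

    @pytest.mark.parametrize("seed", range(10))
    def test_well_separated_modes_threshold_lies_between(self, seed):
        rng = np.random.default_rng(100 + seed)
        lo = rng.integers(10, 80)
        hi = lo + rng.integers(60, 150)
        counts = np.zeros(256, dtype=int)
        for mode in (lo, hi):
            for offset in range(-3, 4):
                counts[mode + offset] += rng.integers(50, 300)
        hist = Histogram(counts, np.arange(257, dtype=float))
        threshold = renyi_entropy_threshold(hist)
        assert lo < threshold < hi


class TestApplyThreshold:
    def test_threshold_at_max_gives_empty_foreground(self, two_channel_stack):
        top = float(two_channel_stack.channel(0).max())
        mask = apply_threshold(two_channel_stack, 0, top)
        assert mask.n_foreground == 0  # strict inequality at the boundary

    def test_threshold_below_min_gives_all_foreground(self, two_channel_stack):
        mask = apply_threshold(two_channel_stack, 0, -1.0)
        assert mask.foreground.all()

    def test_matches_elementwise_loop(self, calibration):
        rng = np.random.default_rng(3)
        vol = rng.integers(0, 50, size=(3, 6, 6))
        stack = ImageStack(vol[None, None], calibration)
        mask = apply_threshold(stack, 0, 25.0)
        for z in range(3):
            for y in range(6):
                for x in range(6):
                    assert mask.foreground[z, y, x] == (vol[z, y, x] > 25.0)


class TestSegmentMarker:
    def test_bright_tubes_on_dark_background(self):
        # synthetic ground truth: two tubes, modest noise, no optical blur
        from ciliaq import SyntheticSpec, generate_cilium_field

        spec = SyntheticSpec(n_cilia=2, seed=14, noise_gaussian_sd=3.0)
        stack, truth = generate_cilium_field(spec)
        mask = segment_marker(stack)
        covered = sum(
            mask.foreground[c.voxel_footprint[:, 0], c.voxel_footprint[:, 1],
                            c.voxel_footprint[:, 2]].mean()
            for c in truth.cilia
        ) / len(truth)
        assert covered > 0.95  # tubes essentially fully covered
        footprint = {tuple(v) for c in truth.cilia for v in c.voxel_footprint}
        false_fg = mask.n_foreground - sum(
            mask.foreground[v] for v in map(tuple, footprint)
        )
        assert false_fg < 0.01 * mask.foreground.size  # background stays dark

    def test_all_zero_stack_is_degenerate(self, calibration):
        stack = ImageStack(np.zeros((1, 1, 4, 8, 8)), calibration)
        with pytest.raises(DegenerateHistogramError):
            segment_marker(stack)

    def test_affine_intensity_rescaling_keeps_the_mask(self, calibration):
        rng = np.random.default_rng(6)
        vol = rng.integers(0, 128, size=(4, 16, 16)).astype(float)
        vol[1, 4:6, 2:14] = 120.0
        stack = ImageStack(vol[None, None], calibration)
        doubled = ImageStack((vol * 2)[None, None], calibration)
        np.testing.assert_array_equal(
            segment_marker(stack).foreground, segment_marker(doubled).foreground
        )

    def test_foreground_monotone_in_threshold(self, two_channel_stack):
        counts = [
            apply_threshold(two_channel_stack, 0, t).n_foreground
            for t in np.linspace(0, 200, 9)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_manual_threshold_escape_hatch(self, two_channel_stack):
        mask = segment_marker(two_channel_stack, manual_threshold=150.0)
        assert mask.threshold_used == 150.0
        assert mask.foreground.sum() == 2 * 3 * 12  # exactly the planted bar
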