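"""Corner sampling, foreground oversampling, and window extraction."""

import numpy as np
import pytest
from scipy import stats

from axonseg import (
    AXON,
    Corner,
    SamplerConfig,
    VolumeSample,
    axon_corner_list,
    draw_corner,
    extract_sample,
    sample_generator,
    valid_corner_bounds,
)


class TestValidCornerBounds:
    def test_padded_cube_gives_124_range(self):
        assert valid_corner_bounds((188, 188, 188), 64) == ((0, 124),) * 3

    def test_exact_fit_gives_single_placement(self):
        assert valid_corner_bounds((64, 64, 64), 64) == ((0, 0),) * 3

    def test_undersized_cube_rejected(self):
        with pytest.raises(ValueError):
            valid_corner_bounds((63, 64, 64), 64)


class TestDrawCorner:
    BOUNDS = ((0, 20), (0, 20), (0, 20))

    def test_p1_with_list_always_returns_list_member(self, rng):
        corners = np.array([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        members = {tuple(c) for c in corners}
        for _ in range(50):
            c = draw_corner(rng, self.BOUNDS, corners, 1.0)
            assert (c.z, c.y, c.x) in members

    def test_p0_corner_distribution_uniform(self):
        """Chi-square goodness of fit per axis over 10,000 uniform draws."""
        rng = np.random.default_rng(7)
        draws = np.array(
            [draw_corner(rng, self.BOUNDS, None, 0.0).as_array() for _ in range(10_000)]
        )
        for axis in range(3):
            observed = np.bincount(draws[:, axis], minlength=21)
            _, p = stats.chisquare(observed)
            assert p > 0.01

    def test_empty_list_falls_back_to_uniform(self, rng):
        c = draw_corner(rng, self.BOUNDS, np.empty((0, 3), dtype=int), 1.0)
        assert 0 <= c.z <= 20

    def test_in_bounds_always(self, rng):
        corners = np.array([[20, 20, 20]])
        for _ in range(200):
            c = draw_corner(rng, self.BOUNDS, corners, 0.5)
            assert all(0 <= v <= 20 for v in (c.z, c.y, c.x))


class TestAxonCornerList:
    def test_out_of_range_axon_voxels_clamped(self):
        labels = np.zeros((10, 10, 10), dtype=np.uint8)
        labels[9, 9, 9] = AXON
        labels[2, 3, 4] = AXON
        corners = axon_corner_list(labels, ((0, 5), (0, 5), (0, 5)))
        assert {tuple(c) for c in corners} == {(5, 5, 5), (2, 3, 4)}

    def test_no_axons_gives_empty_list(self):
        labels = np.zeros((6, 6, 6), dtype=np.uint8)
        assert len(axon_corner_list(labels, ((0, 2),) * 3)) == 0


class TestExtractSample:
    def test_margin_14_gives_36_target(self):
        cfg = SamplerConfig(input_size=64, margin=14)
        image = np.zeros((64, 64, 64), dtype=np.uint16)
        labels = np.zeros((64, 64, 64), dtype=np.uint8)
        s = extract_sample(image, labels, Corner(0, 0, 0), cfg)
        assert s.input.shape == (64, 64, 64)
        assert s.target.shape == (36, 36, 36)

    def test_zero_margin_target_equals_label_window(self, rng):
        cfg = SamplerConfig(input_size=8, margin=0)
        image = rng.integers(0, 100, (12, 12, 12)).astype(np.uint16)
        labels = rng.integers(0, 5, (12, 12, 12)).astype(np.uint8)
        s = extract_sample(image, labels, Corner(2, 1, 3), cfg)
        assert np.array_equal(s.target, labels[2:10, 1:9, 3:11])
        assert np.array_equal(s.input, image[2:10, 1:9, 3:11])

    def test_target_concentric_with_input(self, rng):
        cfg = SamplerConfig(input_size=12, margin=3)
        image = rng.integers(0, 100, (20, 20, 20)).astype(np.uint16)
        labels = rng.integers(0, 5, (20, 20, 20)).astype(np.uint8)
        s = extract_sample(image, labels, Corner(4, 4, 4), cfg)
        assert np.array_equal(s.target, labels[7:13, 7:13, 7:13])

    def test_constant_image_gives_constant_window(self):
        cfg = SamplerConfig(input_size=8, margin=2)
        image = np.full((10, 10, 10), 7, dtype=np.uint16)
        s = extract_sample(image, np.zeros_like(image, dtype=np.uint8), Corner(1, 1, 1), cfg)
        assert (s.input == 7).all()

    def test_out_of_bounds_corner_rejected(self):
        cfg = SamplerConfig(input_size=8, margin=2)
        image = np.zeros((10, 10, 10), dtype=np.uint16)
        with pytest.raises(ValueError):
            extract_sample(image, image.astype(np.uint8), Corner(3, 0, 0), cfg)


class TestSampleGenerator:
    def test_samples_per_cube_times_cubes(self, small_phantom):
        _, image, dense = small_phantom
        cfg = SamplerConfig(input_size=16, margin=4, samples_per_cube=5, seed=0)
        samples = list(sample_generator([(image, dense)] * 3, cfg))
        assert len(samples) == 15
        for s in samples:
            assert s.input.shape == (16, 16, 16)
            assert s.target.shape == (8, 8, 8)

    def test_target_voxels_outside_labeled_core_are_unlabeled(self):
        """With a padded image, windows at the rim read label 0 for voxels
        beyond the labeled central cube."""
        image = np.zeros((16, 16, 16), dtype=np.uint16)
        labels = np.full((8, 8, 8), 2, dtype=np.uint8)  # labeled core, pad 4
        cfg = SamplerConfig(input_size=16, margin=2, samples_per_cube=1, seed=0)
        # bounds force the corner to the origin; target anchor (2) < pad (4)
        s = next(iter(sample_generator([(image, labels)], cfg)))
        assert s.target.shape == (12, 12, 12)
        assert (s.target[:2] == 0).all() and (s.target[-2:] == 0).all()
        assert (s.target[2:10, 2:10, 2:10] == 2).all()

    def test_deterministic_under_fixed_seed(self, small_phantom):
        _, image, dense = small_phantom
        cfg = SamplerConfig(input_size=16, margin=4, samples_per_cube=4, seed=9)
        a = list(sample_generator([(image, dense)], cfg))
        b = list(sample_generator([(image, dense)], cfg))
        for x, y in zip(a, b):
            assert np.array_equal(x.input, y.input)
            assert np.array_equal(x.target, y.target)


class TestSamplerConfig:
    def test_window_arithmetic_enforced(self):
        with pytest.raises(ValueError):
            SamplerConfig(input_size=8, margin=4)
        with pytest.raises(ValueError):
            SamplerConfig(oversample_p=1.5)
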