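"""Temporal Sobel gradient and entropy: oracles, analytic cases, invariants."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dcegrad.gradient_entropy import (
    DERIVATIVE_FILTER,
    SMOOTHING_FILTER,
    GradientVolume,
    entropy_table,
    slice_entropy,
    sobel_temporal_kernel,
    temporal_gradient,
)
from dcegrad.io_formats import DceSeries
from dcegrad.phantom import LesionSpec, PhantomSpec, generate_phantom
from dcegrad.preprocessing import build_chest_mask, extract_breast
from dcegrad.selection import select_acquisition


def sobel_full_oracle(data: np.ndarray) -> np.ndarray:
    """Brute-force triple-sum correlation with the 3x3x3 kernel.

    The kernel spans (y, x, t); replicate padding on those axes; slices
    are independent. Independent of the scipy-based implementation.
    """
    kernel = sobel_temporal_kernel()
    t_len, z_len, y_len, x_len = data.shape
    padded = np.pad(data.astype(float), ((1, 1), (0, 0), (1, 1), (1, 1)), mode="edge")
    out = np.zeros(data.shape)
    for t in range(t_len):
        for z in range(z_len):
            for y in range(y_len):
                for x in range(x_len):
                    acc = 0.0
                    for i in (-1, 0, 1):
                        for j in (-1, 0, 1):
                            for k in (-1, 0, 1):
                                acc += kernel[i + 1, j + 1, k + 1] * padded[
                                    t + k + 1, z, y + i + 1, x + j + 1
                                ]
                    out[t, z, y, x] = abs(acc)
    return out


def entropy_oracle(image, n_levels=256, value_range=None) -> float:
    """Independent histogram-and-sum entropy (Counter + math.log2)."""
    flat = [float(v) for v in np.asarray(image).ravel()]
    vmin = min(flat) if value_range is None else value_range[0]
    vmax = max(flat) if value_range is None else value_range[1]
    if vmax <= vmin:
        return 0.0
    levels = [
        min(n_levels - 1, max(0, math.floor((v - vmin) / (vmax - vmin) * n_levels)))
        for v in flat
    ]
    counts = Counter(levels)
    n = len(flat)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


class TestKernel:
    def test_entries_sum_to_zero(self):
        assert sobel_temporal_kernel().sum() == 0

    def test_leading_time_plane_is_16_sum_triangle(self):
        kernel = sobel_temporal_kernel()
        assert np.array_equal(kernel[:, :, 0], [[1, 2, 1], [2, 4, 2], [1, 2, 1]])
        assert kernel[:, :, 0].sum() == 16
        assert np.array_equal(kernel[:, :, 1], np.zeros((3, 3)))
        assert np.array_equal(kernel[:, :, 2], -kernel[:, :, 0])

    def test_separability(self):
        kernel = sobel_temporal_kernel()
        for i in range(3):
            for j in range(3):
                for k in range(3):
                    assert kernel[i, j, k] == (
                        SMOOTHING_FILTER[i] * SMOOTHING_FILTER[j] * DERIVATIVE_FILTER[k]
                    )


class TestTemporalGradient:
    def test_time_constant_series_has_zero_gradient(self, rng):
        frame = rng.uniform(0, 50, size=(3, 6, 7))
        series = DceSeries(np.broadcast_to(frame, (5, 3, 6, 7)).copy())
        for mode in ("replicate", "reflect"):
            assert np.allclose(temporal_gradient(series, boundary_mode=mode).data, 0.0)
        # zero padding introduces artificial edges; the interior is still zero
        grad = temporal_gradient(series, boundary_mode="zero").data
        assert np.allclose(grad[1:-1, :, 1:-1, 1:-1], 0.0)

    def test_linear_ramp_interior_magnitude_is_32c(self):
        c = 1.75
        t_len = 6
        data = c * np.arange(t_len)[:, None, None, None] * np.ones((t_len, 2, 5, 5))
        oracle = sobel_full_oracle(data)
        assert np.allclose(oracle[1:-1], 32 * c)
        series = DceSeries(data)
        for method in ("separable", "full"):
            grad = temporal_gradient(series, method=method).data
            assert np.allclose(grad[1:-1], 32 * c)
            assert np.array_equal(grad, oracle)

    def test_matches_triple_sum_oracle_on_random_volume(self, rng):
        data = rng.integers(0, 40, size=(5, 2, 4, 6)).astype(float)
        oracle = sobel_full_oracle(data)
        series = DceSeries(data)
        assert np.array_equal(temporal_gradient(series, method="full").data, oracle)
        assert np.array_equal(temporal_gradient(series, method="separable").data, oracle)

    def test_separable_equals_full_on_random_integer_volumes(self, rng):
        for _ in range(100):
            data = rng.integers(0, 200, size=(6, 8, 8, 8)).astype(float)
            series = DceSeries(data)
            sep = temporal_gradient(series, method="separable").data
            full = temporal_gradient(series, method="full").data
            assert np.array_equal(sep, full)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(
        data=arrays(np.float64, (5, 2, 6, 6),
                    elements=st.floats(0, 1e3, allow_nan=False, width=32)),
        scale=st.floats(0.1, 10.0),
    )
    def test_linearity_and_offset_invariance(self, data, scale):
        base = temporal_gradient(DceSeries(data + 1.0)).data
        scaled = temporal_gradient(DceSeries(scale * (data + 1.0))).data
        assert np.allclose(scaled, scale * base, rtol=1e-9, atol=1e-9)
        shifted = temporal_gradient(DceSeries(data + 101.0)).data
        assert np.allclose(shifted, base, rtol=1e-9, atol=1e-6)

    def test_rejects_bad_arguments(self, rng):
        series = DceSeries(rng.uniform(1, 2, (4, 2, 4, 4)))
        with pytest.raises(ValueError, match="boundary"):
            temporal_gradient(series, boundary_mode="wrap")
        with pytest.raises(ValueError, match="method"):
            temporal_gradient(series, method="fft")


class TestSliceEntropy:
    def test_constant_image_has_zero_entropy(self):
        assert slice_entropy(np.full((16, 16), 7.0)) == 0.0

    def test_two_equiprobable_levels_give_one_bit(self):
        image = np.zeros((16, 16))
        image[:8] = 255.0
        assert slice_entropy(image) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_256_level_histogram_gives_eight_bits(self):
        image = np.tile(np.arange(256.0), (256, 1))
        assert slice_entropy(image) == pytest.approx(8.0, abs=1e-12)

    def test_matches_independent_oracle_on_random_images(self, rng):
        for _ in range(20):
            image = rng.uniform(0, 1000, size=(24, 24))
            assert slice_entropy(image) == pytest.approx(entropy_oracle(image), abs=1e-12)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        image=arrays(np.float64, (8, 8), elements=st.floats(0, 100, width=32)),
        seed=st.integers(0, 2**16),
    )
    def test_permutation_invariance_and_bounds(self, image, seed):
        e = slice_entropy(image)
        assert 0.0 <= e <= 8.0
        shuffled = np.random.default_rng(seed).permutation(image.ravel()).reshape(image.shape)
        assert slice_entropy(shuffled) == pytest.approx(e, abs=1e-12)

    def test_rejects_non_finite(self):
        image = np.ones((4, 4))
        image[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            slice_entropy(image)


class TestEntropyTable:
    def test_zero_gradient_gives_zero_table_with_warning(self):
        grad = GradientVolume(np.zeros((3, 4, 5, 5)))
        with pytest.warns(UserWarning, match="degenerate"):
            table = entropy_table(grad)
        assert table.values.shape == (3, 4)
        assert np.array_equal(table.values, np.zeros((3, 4)))

    def test_global_normalization_uses_volume_wide_range(self, rng):
        data = rng.uniform(0, 1, size=(2, 3, 16, 16))
        data[1] *= 100.0  # acquisition 1 dominates the global range
        table = entropy_table(GradientVolume(data), normalization="global_minmax")
        vmin, vmax = data.min(), data.max()
        expected = entropy_oracle(data[0, 0], value_range=(vmin, vmax))
        assert table.values[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_lesion_slices_carry_the_entropy_maximum(self):
        # lesion of radius 2 at slice 20 enhances slices 18-22 only
        spec = PhantomSpec(seed=5, noise_sigma=0.0, bpe_fraction=0.15,
                           lesion=LesionSpec(center=(20, 30, 17)))
        series, _ = generate_phantom(spec)
        grad = temporal_gradient(extract_breast(series, build_chest_mask(series)))
        table = entropy_table(grad)
        t_star, _, _ = select_acquisition(table)
        assert 18 <= int(np.argmax(table.values[t_star])) <= 22
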