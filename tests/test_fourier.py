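"""Fourier operators: unitarity, oracle agreement, undersampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refdip import (
    ComplexImage,
    KSpaceGrid,
    forward_fft,
    inverse_fft,
    make_variable_density,
    undersample,
    zero_fill,
)
from refdip.masks import SamplingMask


def naive_centered_dft(x: np.ndarray) -> np.ndarray:
    """O(N⁴) double-loop centered orthonormal DFT — the independent oracle."""
    n = x.shape[0]
    c = n // 2
    out = np.zeros((n, n), complex)
    for ky in range(n):
        for kx in range(n):
            acc = 0.0 + 0.0j
            for iy in range(n):
                for ix in range(n):
                    phase = -2j * np.pi * (
                        (ky - c) * (iy - c) + (kx - c) * (ix - c)
                    ) / n
                    acc += x[iy, ix] * np.exp(phase)
            out[ky, kx] = acc / n
    return out


def full_mask(n):
    return SamplingMask(np.ones((n, n), bool), "cartesian", 1.0, 0)


def empty_mask(n):
    return SamplingMask(np.zeros((n, n), bool), "cartesian", 0.01, 0)


class TestForwardInverse:
    def test_constant_image_concentrates_at_dc(self):
        g = forward_fft(ComplexImage(np.ones((8, 8), complex)))
        assert g.data[4, 4] == pytest.approx(8.0)
        off_dc = g.data.copy()
        off_dc[4, 4] = 0
        assert np.abs(off_dc).max() < 1e-12

    def test_dc_only_grid_inverts_to_constant(self):
        k = np.zeros((8, 8), complex)
        k[4, 4] = 8.0
        img = inverse_fft(KSpaceGrid(k))
        np.testing.assert_allclose(img.data, np.ones((8, 8)), atol=1e-12)

    def test_matches_naive_dft_oracle(self, random_image):
        x = random_image(16)
        expected = naive_centered_dft(x.data)
        np.testing.assert_allclose(forward_fft(x).data, expected, rtol=0, atol=1e-8)
        # inverse oracle: conjugate route
        grid = KSpaceGrid(expected)
        np.testing.assert_allclose(inverse_fft(grid).data, x.data, atol=1e-8)

    def test_parseval_and_round_trip(self, random_image):
        x = random_image(32)
        g = forward_fft(x)
        assert np.linalg.norm(g.data) == pytest.approx(x.norm(), rel=1e-10)
        np.testing.assert_allclose(
            inverse_fft(g).data, x.data, rtol=1e-10, atol=1e-12
        )
        np.testing.assert_allclose(
            forward_fft(inverse_fft(g)).data, g.data, rtol=1e-10, atol=1e-12
        )

    def test_linearity(self, random_image):
        x, y = random_image(16), random_image(16)
        a, b = 2.3 - 0.7j, -1.1 + 0.4j
        lhs = forward_fft(ComplexImage(a * x.data + b * y.data)).data
        rhs = a * forward_fft(x).data + b * forward_fft(y).data
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10, atol=1e-12)

    @pytest.mark.parametrize(
        "bad", [np.ones((8, 12)), np.ones((4, 4)), np.full((8, 8), np.nan)]
    )
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            forward_fft(np.asarray(bad, complex))


class TestUndersample:
    def test_full_mask_keeps_every_entry(self, random_image):
        x = random_image(16)
        g = forward_fft(x)
        meas = undersample(g, full_mask(16))
        np.testing.assert_array_equal(meas.data, g.data)
        assert meas.n_samples == 256

    def test_empty_mask_flagged_invalid(self, random_image):
        meas = undersample(forward_fft(random_image(16)), empty_mask(16))
        assert not meas.is_valid
        assert meas.n_samples == 0

    def test_shape_mismatch_rejected(self, random_image):
        with pytest.raises(ValueError):
            undersample(forward_fft(random_image(16)), full_mask(32))

    def test_adjoint_identity(self, rng):
        """⟨F_u x, y⟩ = ⟨x, F_uᴴ y⟩ for a 20% mask (numerical check)."""
        n = 16
        mask = make_variable_density(n, 0.2, seed=5)
        x = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
        y = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
        y = np.where(mask.data, y, 0)
        fu_x = undersample(forward_fft(ComplexImage(x)), mask).data
        fuh_y = inverse_fft(KSpaceGrid(y)).data  # adjoint of unitary masked DFT
        lhs = np.vdot(y, fu_x)
        rhs = np.vdot(fuh_y, x)
        assert abs(lhs - rhs) / abs(lhs) < 1e-8


class TestZeroFill:
    def test_full_mask_recovers_image(self, random_image):
        x = random_image(16)
        meas = undersample(forward_fft(x), full_mask(16))
        np.testing.assert_allclose(zero_fill(meas).data, x.data, rtol=1e-10, atol=1e-12)

    def test_equals_masked_fft_route(self, random_image):
        x = random_image(32)
        mask = make_variable_density(32, 0.5, seed=2)
        meas = undersample(forward_fft(x), mask)
        direct = inverse_fft(KSpaceGrid(forward_fft(x).data * mask.data)).data
        np.testing.assert_allclose(zero_fill(meas).data, direct, atol=1e-12)

    def test_empty_measurement_gives_zero_image(self, random_image):
        meas = undersample(forward_fft(random_image(16)), empty_mask(16))
        assert np.abs(zero_fill(meas).data).max() == 0.0


class TestProperties:
    """Hypothesis-driven invariants over random images and masks."""

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.sampled_from([8, 16, 32]))
    def test_unitarity_and_round_trip_hold_for_random_images(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, n)) + 1j * rng.normal(size=(n, n))
        g = forward_fft(ComplexImage(x))
        assert np.linalg.norm(g.data) == pytest.approx(np.linalg.norm(x), rel=1e-10)
        np.testing.assert_allclose(inverse_fft(g).data, x, rtol=1e-10, atol=1e-12)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), rate=st.floats(0.1, 0.9))
    def test_undersampling_preserves_measured_entries(self, seed, rate):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(16, 16)) + 1j * rng.normal(size=(16, 16))
        mask = make_variable_density(16, rate, seed=seed)
        g = forward_fft(ComplexImage(x))
        meas = undersample(g, mask)
        np.testing.assert_array_equal(meas.data[mask.data], g.data[mask.data])
        assert np.all(meas.data[~mask.data] == 0)
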