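"""Reconstruction pipeline: data-consistency contracts and optimization sanity."""

import numpy as np
import pytest

from refdip import (
    ComplexImage,
    NetworkSpec,
    ReconConfig,
    data_correct,
    fit_dip,
    forward_fft,
    inverse_fft,
    make_cartesian,
    make_phantom_pair,
    reconstruct,
    simulate_acquisition,
    undersample,
)
from refdip.fourier import KSpaceMeasurement
from refdip.masks import SamplingMask


def small_spec(seed=0):
    return NetworkSpec(depth=2, nd=(8, 16), nu=(8, 16), ns=(4, 4), seed=seed)


@pytest.fixture(scope="module")
def phantom():
    return make_phantom_pair(32, n_structures=4, jitter_px=0.75, jitter_intensity=0.05, seed=0)


def full_mask(n):
    return SamplingMask(np.ones((n, n), bool), "cartesian", 1.0, 0)


class TestDataCorrect:
    def test_full_mask_ignores_network_output(self, phantom, rng):
        meas = undersample(forward_fft(phantom.target), full_mask(32))
        junk = ComplexImage(rng.normal(size=(32, 32)) + 0j)
        corrected = data_correct(junk, meas)
        np.testing.assert_array_equal(corrected.data, meas.data)

    def test_empty_mask_keeps_network_kspace(self, phantom, rng):
        mask = SamplingMask(np.zeros((32, 32), bool), "cartesian", 0.01, 0)
        meas = KSpaceMeasurement(mask, np.zeros((32, 32), complex))
        out = ComplexImage(rng.normal(size=(32, 32)) + 0j)
        corrected = data_correct(out, meas)
        np.testing.assert_array_equal(corrected.data, forward_fft(out).data)

    def test_elementwise_split_between_mask_and_complement(self, phantom, rng):
        mask = make_cartesian(32, 0.2, seed=1)
        meas = undersample(forward_fft(phantom.target), mask)
        out = ComplexImage(rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32)))
        corrected = data_correct(out, meas).data
        np.testing.assert_array_equal(corrected[mask.data], meas.data[mask.data])
        k_out = forward_fft(out).data
        np.testing.assert_array_equal(corrected[~mask.data], k_out[~mask.data])

    def test_shape_mismatch_rejected(self, phantom):
        meas = undersample(forward_fft(phantom.target), full_mask(32))
        with pytest.raises(ValueError):
            data_correct(ComplexImage(np.zeros((16, 16), complex)), meas)


class TestFitDip:
    def test_full_sampling_loss_decreases(self, phantom):
        meas = undersample(forward_fft(phantom.target), full_mask(32))
        cfg = ReconConfig(iterations=200, learning_rate=0.01, seed=0)
        _, _, trace, _ = fit_dip(meas, phantom.reference, small_spec(), cfg)
        assert trace[-1][1] < trace[0][1]

    def test_iteration_bounds(self, phantom):
        meas = undersample(forward_fft(phantom.target), full_mask(32))
        with pytest.raises(ValueError):
            ReconConfig(iterations=0)
        cfg = ReconConfig(iterations=1)
        _, _, trace, _ = fit_dip(meas, phantom.reference, small_spec(), cfg)
        assert len(trace) == 1

    def test_empty_mask_rejected(self, phantom):
        mask = SamplingMask(np.zeros((32, 32), bool), "cartesian", 0.01, 0)
        meas = KSpaceMeasurement(mask, np.zeros((32, 32), complex))
        with pytest.raises(ValueError, match="empty"):
            fit_dip(meas, phantom.reference, small_spec(), ReconConfig(iterations=5))

    def test_noise_mode_uses_fixed_seeded_input(self, phantom):
        meas = undersample(forward_fft(phantom.target), full_mask(32))
        cfg = ReconConfig(iterations=3, input_mode="noise", seed=9)
        _, out1, _, _ = fit_dip(meas, phantom.reference, small_spec(seed=1), cfg)
        _, out2, _, _ = fit_dip(meas, phantom.reference, small_spec(seed=1), cfg)
        np.testing.assert_array_equal(out1.data, out2.data)


class TestReconstruct:
    def test_full_sampling_recovers_target_regardless_of_network(self, phantom):
        meas = undersample(forward_fft(phantom.target), full_mask(32))
        cfg = ReconConfig(iterations=2, seed=0)
        res = reconstruct(meas, phantom.reference, small_spec(), cfg)
        err = np.linalg.norm(res.image.data - phantom.target.data)
        assert err / np.linalg.norm(phantom.target.data) < 1e-10

    def test_exact_data_consistency_at_sampled_locations(self, phantom):
        mask = make_cartesian(32, 0.3, seed=2)
        meas = simulate_acquisition(phantom.target, mask)
        cfg = ReconConfig(iterations=20, seed=0)
        res = reconstruct(meas, phantom.reference, small_spec(), cfg)
        k = forward_fft(res.image).data
        resid = np.linalg.norm(k[mask.data] - meas.data[mask.data])
        assert resid / np.linalg.norm(meas.data[mask.data]) < 1e-10

    def test_data_correct_idempotent_on_final_image(self, phantom):
        mask = make_cartesian(32, 0.3, seed=2)
        meas = simulate_acquisition(phantom.target, mask)
        cfg = ReconConfig(iterations=10, seed=0)
        res = reconstruct(meas, phantom.reference, small_spec(), cfg)
        again = inverse_fft(data_correct(res.image, meas))
        np.testing.assert_allclose(
            again.data, res.image.data, rtol=0, atol=1e-12 * np.abs(res.image.data).max() + 1e-13
        )

    def test_deterministic_given_seeds(self, phantom):
        mask = make_cartesian(32, 0.3, seed=2)
        meas = simulate_acquisition(phantom.target, mask)
        cfg = ReconConfig(iterations=10, seed=3)
        r1 = reconstruct(meas, phantom.reference, small_spec(seed=3), cfg)
        r2 = reconstruct(meas, phantom.reference, small_spec(seed=3), cfg)
        np.testing.assert_array_equal(r1.image.data, r2.image.data)

    def test_metric_trace_recorded_against_truth(self, phantom):
        mask = make_cartesian(32, 0.3, seed=2)
        meas = simulate_acquisition(phantom.target, mask)
        cfg = ReconConfig(iterations=20, eval_every=10, seed=0)
        res = reconstruct(
            meas, phantom.reference, small_spec(), cfg, ground_truth=phantom.target
        )
        assert res.metric_trace is not None
        iters = [t[0] for t in res.metric_trace]
        assert iters == [10, 20]
        assert all(np.isfinite(t[1]) and np.isfinite(t[2]) for t in res.metric_trace)
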